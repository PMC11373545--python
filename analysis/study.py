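"""Shared locations and settings for the analysis drivers.

The synthetic study (expression matrix, per-protein pQTL files, outcome
GWAS) lives under scratch/ — it is bulky, regenerable data; the drivers'
result tables go under results/.
"""

from pathlib import Path

from protmr.synthetic import simulate_study_bundle

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

STUDY_SEED = 7
EXPOSURE_P_MAX = 1e-4  # simulated pQTL discovery threshold


def ensure_study() -> dict:
    """Generate the synthetic study bundle if absent; return its paths."""
    marker = SCRATCH / "outcome.tsv"
    if not marker.exists():
        SCRATCH.mkdir(parents=True, exist_ok=True)
        return simulate_study_bundle(SCRATCH, seed=STUDY_SEED)
    return {
        "expression_matrix": str(SCRATCH / "expression.tsv"),
        "groups": str(SCRATCH / "groups.tsv"),
        "exposure_dir": str(SCRATCH / "exposures"),
        "outcome": str(SCRATCH / "outcome.tsv"),
        "causal_protein": "prot0001",
        "theta_causal": 0.3,
    }
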