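"""Synthetic datasets with known ground truth for every pipeline stage.

The MR generator follows the standard two-sample summary-data structural
model: true instrument effects gamma_j ~ Normal(0, gamma_sd²) truncated away
from zero, observed exposure effects beta_Xj ~ Normal(gamma_j, se_x²);
invalid instruments receive a pleiotropic effect alpha_j ~ Normal(pleio_mean,
pleio_sd²) and outcome effects are beta_Yj ~ Normal(theta·gamma_j + alpha_j,
se_y²). Balanced pleiotropy has pleio_mean = 0; directional pleiotropy a
nonzero mean. Variants get non-palindromic allele pairs and EAF ~ U(0.05,
0.5) unless configured otherwise.

The mediation generator builds three consistent dataset pairs (exposure →
mediator, mediator → outcome, exposure → outcome) whose total effect is
theta_dir + theta_em·theta_mo, recording the true proportion mediated.

The protein-array generator emulates the study's 640-cytokine × 64-sample
serum panel: log2 intensities Normal(baseline, noise_sd²), with the case
group shifted by an assigned log2 fold change for the spiked proteins
(33 by default, to match the screen the panel is modelled on).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from protmr.core_io import ExpressionMatrix, SummaryStats, VariantAssociation
from protmr.instruments import HarmonizedSet

# non-palindromic effect/other pairs only: strand ambiguity is opt-in
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"), ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

# instrument effects are truncated away from zero at this fraction of their SD
GAMMA_TRUNCATION = 0.1


@dataclass(frozen=True)
class MRSimConfig:
    """Structural-model parameters for one simulated exposure→outcome pair.

    ``theta`` is the true causal effect (log-odds per exposure SD);
    ``gamma_sd`` the spread of true instrument effects; ``se_x``/``se_y`` the
    per-variant sampling SEs (scalar or per-variant); ``prop_invalid`` the
    fraction of instruments carrying a pleiotropic effect drawn from
    Normal(pleio_mean, pleio_sd²). Default sample sizes mirror a
    pQTL-discovery cohort (n≈5,343) and a large binary-outcome GWAS
    (n≈184,305).
    """

    n_snp: int = 5
    theta: float = 0.0
    gamma_sd: float = 0.3
    se_x: float | tuple = 0.02
    se_y: float | tuple = 0.02
    prop_invalid: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    seed: int | None = None
    n_exp: int = 5343
    n_out: int = 184305
    palindromic: bool = False
    gamma_positive: bool = False  # orient all true instrument effects > 0
    gamma_floor: float | None = None  # absolute |gamma| floor; default 0.1*gamma_sd
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >=1")
        if not (0 <= self.prop_invalid <= 1):
            raise ValueError("prop_invalid must lie in [0, 1]")
        if np.any(np.asarray(self.se_x) <= 0) or np.any(np.asarray(self.se_y) <= 0):
            raise ValueError("se_x and se_y must be positive")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")


def _draw_structural(cfg: MRSimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = cfg.n_snp
    gamma = rng.normal(0.0, cfg.gamma_sd, size=n)
    # truncate away from zero so no instrument is degenerate
    floor = cfg.gamma_floor if cfg.gamma_floor is not None else GAMMA_TRUNCATION * cfg.gamma_sd
    small = np.abs(gamma) < floor
    while small.any():
        gamma[small] = rng.normal(0.0, cfg.gamma_sd, size=int(small.sum()))
        small = np.abs(gamma) < floor
    if cfg.gamma_positive:
        gamma = np.abs(gamma)
    se_x = np.broadcast_to(np.asarray(cfg.se_x, dtype=float), (n,)).copy()
    se_y = np.broadcast_to(np.asarray(cfg.se_y, dtype=float), (n,)).copy()
    invalid = rng.random(n) < cfg.prop_invalid
    alpha = np.where(invalid, rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=n), 0.0)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.theta * gamma + alpha, se_y)
    eaf = rng.uniform(0.05, 0.5, size=n)
    return {
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "beta_x": beta_x,
        "beta_y": beta_y,
        "se_x": se_x,
        "se_y": se_y,
        "eaf": eaf,
    }


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, np.nextafter(0, 1))


def simulate_mr_dataset(cfg: MRSimConfig) -> tuple[SummaryStats, SummaryStats, pd.DataFrame]:
    """One exposure/outcome summary-statistics pair plus its ground truth.

    The two SummaryStats share variant ids, positions and alleles (already
    strand-consistent); the truth table records (gamma, alpha, invalid,
    theta) per variant. Bit-reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    d = _draw_structural(cfg, rng)
    n = cfg.n_snp
    pairs = _PALINDROMIC_PAIRS if cfg.palindromic else _ALLELE_PAIRS
    pair_idx = rng.integers(0, len(pairs), size=n)
    positions = 1_000_000 + 1_000_000 * np.arange(n)

    def _assocs(beta, se, nsamp):
        out = []
        pv = _pvals(beta, se)
        for i in range(n):
            ea, oa = pairs[pair_idx[i]]
            out.append(
                VariantAssociation(
                    variant_id=f"rs{i + 1:05d}",
                    chrom="1",
                    pos=int(positions[i]),
                    effect_allele=ea,
                    other_allele=oa,
                    eaf=float(d["eaf"][i]),
                    beta=float(beta[i]),
                    se=float(se[i]),
                    pval=float(pv[i]),
                    n=nsamp,
                )
            )
        return out

    exposure = SummaryStats(
        trait_name=cfg.exposure_name,
        associations=_assocs(d["beta_x"], d["se_x"], cfg.n_exp),
        trait_type="continuous",
    )
    outcome = SummaryStats(
        trait_name=cfg.outcome_name,
        associations=_assocs(d["beta_y"], d["se_y"], cfg.n_out),
        trait_type="binary",
    )
    truth = pd.DataFrame(
        {
            "variant_id": [a.variant_id for a in exposure.associations],
            "gamma": d["gamma"],
            "alpha": d["alpha"],
            "invalid": d["invalid"],
            "theta": cfg.theta,
        }
    )
    return exposure, outcome, truth


def simulate_harmonized(cfg: MRSimConfig) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Directly build the HarmonizedSet a simulation implies (fast path for
    Monte-Carlo studies; identical structural draw as simulate_mr_dataset)."""
    rng = np.random.default_rng(cfg.seed)
    d = _draw_structural(cfg, rng)
    h = HarmonizedSet.from_arrays(
        beta_exp=d["beta_x"],
        se_exp=d["se_x"],
        beta_out=d["beta_y"],
        se_out=d["se_y"],
        exposure_name=cfg.exposure_name,
        outcome_name=cfg.outcome_name,
        variant_ids=[f"rs{i + 1:05d}" for i in range(cfg.n_snp)],
    )
    truth = pd.DataFrame(
        {
            "variant_id": h.variant_ids,
            "gamma": d["gamma"],
            "alpha": d["alpha"],
            "invalid": d["invalid"],
            "theta": cfg.theta,
        }
    )
    return h, truth


@dataclass(frozen=True)
class MediationSimConfig:
    """Three-leg mediation generator: exposure→mediator (theta_em),
    mediator→outcome (theta_mo), and a direct exposure→outcome path
    (theta_dir). True proportion mediated =
    theta_em·theta_mo / (theta_dir + theta_em·theta_mo)."""

    theta_em: float = 0.1
    theta_mo: float = 0.5
    theta_dir: float = 0.05
    leg_template: MRSimConfig = field(default_factory=lambda: MRSimConfig(n_snp=5))
    seed: int | None = None

    @property
    def total_effect(self) -> float:
        return self.theta_dir + self.theta_em * self.theta_mo

    @property
    def pm_true(self) -> float:
        return self.theta_em * self.theta_mo / self.total_effect

    def __post_init__(self) -> None:
        if self.total_effect == 0:
            raise ValueError("zero total effect: proportion mediated undefined")


def simulate_mediation_trio(
    cfg: MediationSimConfig,
) -> tuple[dict[str, tuple[SummaryStats, SummaryStats, pd.DataFrame]], dict[str, float]]:
    """Three independent dataset pairs consistent with the mediation model.

    Returns legs keyed ``em`` (exposure→mediator), ``mo`` (mediator→outcome)
    and ``total`` (exposure→outcome, causal effect theta_dir +
    theta_em·theta_mo), plus the truth record with the true PM.
    """
    seeds = np.random.SeedSequence(cfg.seed).generate_state(3) % (2**31)
    legs = {}
    spec = [
        ("em", cfg.theta_em, "exposure", "mediator"),
        ("mo", cfg.theta_mo, "mediator", "outcome"),
        ("total", cfg.total_effect, "exposure", "outcome"),
    ]
    for (key, theta, xn, yn), s in zip(spec, seeds):
        leg_cfg = replace(
            cfg.leg_template, theta=theta, seed=int(s), exposure_name=xn, outcome_name=yn
        )
        legs[key] = simulate_mr_dataset(leg_cfg)
    truth = {
        "theta_em": cfg.theta_em,
        "theta_mo": cfg.theta_mo,
        "theta_dir": cfg.theta_dir,
        "total": cfg.total_effect,
        "pm": cfg.pm_true,
    }
    return legs, truth


@dataclass(frozen=True)
class ProteinSimConfig:
    """Protein-array generator settings.

    Defaults mirror the serum panel the screen targets: 640 proteins over 33
    cases and 31 controls, log2-scale within-group noise 0.5, and 33 spiked
    proteins at |log2FC| = 1 (16 up, 17 down) when ``dep_log2fc`` is not
    given explicitly.
    """

    n_proteins: int = 640
    n_case: int = 33
    n_control: int = 31
    dep_log2fc: Mapping[str, float] | None = None
    n_dep: int = 33
    dep_effect: float = 1.0
    noise_sd: float = 0.5
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("both groups need >=2 samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.dep_log2fc is None and self.n_dep > self.n_proteins:
            raise ValueError("n_dep exceeds n_proteins")


def default_dep_assignment(cfg: ProteinSimConfig) -> dict[str, float]:
    """Spiked-protein map used when the config does not name DEPs: the first
    ``n_dep`` proteins, alternating signs starting up, at |log2FC| =
    ``dep_effect``."""
    return {
        f"prot{i + 1:04d}": (cfg.dep_effect if i % 2 == 0 else -cfg.dep_effect)
        for i in range(cfg.n_dep)
    }


def simulate_protein_matrix(cfg: ProteinSimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Protein-array intensities with spiked case/control differences.

    log2 intensities are Normal(baseline_p, noise_sd²); case samples of a
    spiked protein are shifted by its assigned log2FC. Returns the matrix
    (linear-scale intensities) and a truth table (protein_id, true_log2fc,
    is_dep).
    """
    rng = np.random.default_rng(cfg.seed)
    protein_ids = [f"prot{i + 1:04d}" for i in range(cfg.n_proteins)]
    deps = dict(cfg.dep_log2fc) if cfg.dep_log2fc is not None else default_dep_assignment(cfg)
    unknown = set(deps) - set(protein_ids)
    if unknown:
        raise ValueError(f"dep ids not in protein set: {sorted(unknown)[:5]}")
    n_samp = cfg.n_case + cfg.n_control
    sample_ids = [f"case{i + 1:02d}" for i in range(cfg.n_case)] + [
        f"ctrl{i + 1:02d}" for i in range(cfg.n_control)
    ]
    group = ["case"] * cfg.n_case + ["control"] * cfg.n_control
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins)
    log2v = rng.normal(baseline[:, None], cfg.noise_sd, size=(cfg.n_proteins, n_samp))
    fc = np.array([deps.get(p, 0.0) for p in protein_ids])
    log2v[:, : cfg.n_case] += fc[:, None]
    matrix = ExpressionMatrix(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        values=2.0**log2v,
        group=group,
    )
    truth = pd.DataFrame(
        {"protein_id": protein_ids, "true_log2fc": fc, "is_dep": fc != 0.0}
    )
    return matrix, truth


def simulate_study_bundle(
    out_dir,
    seed: int | None = None,
    protein_cfg: ProteinSimConfig | None = None,
    mr_template: MRSimConfig | None = None,
    causal_protein: str = "prot0001",
    theta_causal: float = 0.3,
    n_instrumented: int = 17,
) -> dict:
    """Write a full synthetic study to ``out_dir`` ready for the pipeline.

    Generates the protein-array matrix with its spiked DEPs, an exposure
    summary-statistics file for the first ``n_instrumented`` spiked proteins
    (emulating the subset of DEPs with available pQTLs), and one combined
    outcome file. Exactly one protein (``causal_protein``) has a true causal
    effect ``theta_causal``; the rest are null. Returns the file paths plus
    the truth record.
    """
    from pathlib import Path

    from protmr.core_io import write_expression, write_sumstats

    out = Path(out_dir)
    (out / "exposures").mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    s_prot, *s_mr = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(1 + n_instrumented)]

    protein_cfg = protein_cfg or ProteinSimConfig()
    protein_cfg = replace(protein_cfg, seed=s_prot)
    matrix, prot_truth = simulate_protein_matrix(protein_cfg)
    write_expression(matrix, out / "expression.tsv", out / "groups.tsv")

    spiked = [p for p in prot_truth.loc[prot_truth.is_dep, "protein_id"]]
    instrumented = spiked[:n_instrumented]
    if causal_protein not in instrumented:
        raise ValueError(f"causal protein {causal_protein} not among instrumented DEPs")

    # instrument strength floor set so simulated pQTLs span F ~ 40-5600,
    # the strength range of the instruments the study design assumes
    mr_template = mr_template or MRSimConfig(
        n_snp=5, gamma_sd=0.3, se_x=0.02, se_y=0.03, gamma_floor=0.13
    )
    outcome_assocs = []
    for k, (prot, s) in enumerate(zip(instrumented, s_mr)):
        theta = theta_causal if prot == causal_protein else 0.0
        cfg_k = replace(mr_template, theta=theta, seed=s, exposure_name=prot, outcome_name="disease")
        exp, outc, _ = simulate_mr_dataset(cfg_k)
        # distinct ids and chromosomes per protein so the merged outcome file
        # stays variant-unique and LD windows never straddle proteins
        rename = {a.variant_id: f"rs{k:03d}{i:04d}" for i, a in enumerate(exp.associations)}
        exp = SummaryStats(
            trait_name=prot,
            associations=[
                replace(a, variant_id=rename[a.variant_id], chrom=str(k + 1))
                for a in exp.associations
            ],
            trait_type="continuous",
        )
        outcome_assocs.extend(
            replace(a, variant_id=rename[a.variant_id], chrom=str(k + 1))
            for a in outc.associations
        )
        write_sumstats(exp, out / "exposures" / f"{prot}.tsv")
    outcome = SummaryStats(trait_name="disease", associations=outcome_assocs, trait_type="binary")
    write_sumstats(outcome, out / "outcome.tsv")
    return {
        "expression_matrix": str(out / "expression.tsv"),
        "groups": str(out / "groups.tsv"),
        "exposure_dir": str(out / "exposures"),
        "outcome": str(out / "outcome.tsv"),
        "causal_protein": causal_protein,
        "theta_causal": theta_causal,
        "instrumented": instrumented,
    }
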