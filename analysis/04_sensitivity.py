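"""Sensitivity suite for the FDR-significant protein: leave-one-out IVW,
MR-Egger intercept (horizontal pleiotropy), MR-PRESSO global/outlier tests,
and funnel-plot data.
"""

from pathlib import Path

from protmr.core_io import read_sumstats
from protmr.instruments import select_and_harmonize
from protmr.sensitivity import funnel_data, leave_one_out, pleiotropy_report, presso
from study import EXPOSURE_P_MAX, RESULTS, STUDY_SEED, ensure_study

paths = ensure_study()
RESULTS.mkdir(exist_ok=True)
prot = paths["causal_protein"]

exposure = read_sumstats(Path(paths["exposure_dir"]) / f"{prot}.tsv", trait_name=prot)
outcome = read_sumstats(paths["outcome"], trait_type="binary")
_, h = select_and_harmonize(exposure, outcome, p_max=EXPOSURE_P_MAX)

loo = leave_one_out(h)
loo.round(5).to_csv(RESULTS / f"loo_{prot}.tsv", sep="\t", index=False)
funnel_data(h).round(5).to_csv(RESULTS / f"funnel_{prot}.tsv", sep="\t", index=False)
intercept = pleiotropy_report(h)
pres = presso(h, n_sim=1000, seed=STUDY_SEED)

spread = loo.loc[loo.excluded != "none", "beta"]
print(f"sensitivity for {prot} ({len(h)} instruments)")
print(f"  leave-one-out IVW range: {spread.min():.3f} to {spread.max():.3f}")
print(f"  Egger intercept: {intercept.value:.4f} (se {intercept.se:.4f}, p={intercept.pval:.2f})")
print(f"  MR-PRESSO global test: p={pres.global_p:.3f}; outliers: {pres.outlier_ids or 'none'}")
print(f"tables: loo_{prot}.tsv, funnel_{prot}.tsv in {RESULTS}")
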