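"""Generate the synthetic study: a 640-protein x 64-sample serum array with
33 spiked differentially expressed proteins, pQTL summary statistics for 17
of them (instrument F-statistics spanning ~40-5600), and a combined binary-
outcome GWAS in which exactly one protein (prot0001) has a true causal
effect of 0.3 log-odds per SD.
"""

import pandas as pd

from study import SCRATCH, ensure_study

paths = ensure_study()
exposures = sorted(p.stem for p in (SCRATCH / "exposures").glob("*.tsv"))
outcome = pd.read_csv(paths["outcome"], sep="\t", comment="#")
print(f"study bundle in {SCRATCH}")
print(f"  expression matrix: 640 proteins x 64 samples (33 cases / 31 controls)")
print(f"  instrumented proteins: {len(exposures)} ({', '.join(exposures[:4])}, ...)")
print(f"  outcome GWAS variants: {len(outcome)}")
print(f"  planted causal protein: {paths['causal_protein']} (theta = {paths['theta_causal']})")
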