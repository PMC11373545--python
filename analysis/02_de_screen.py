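"""Differential-expression screen of the serum panel: Welch tests on log2
intensities, DEP calls at p<0.05 and |log2FC|>0.263, volcano table.
"""

import pandas as pd

from protmr.core_io import read_expression
from protmr.de_screen import screen, volcano_table
from study import RESULTS, ensure_study

paths = ensure_study()
RESULTS.mkdir(exist_ok=True)

matrix = read_expression(paths["expression_matrix"], paths["groups"])
results = screen(matrix)
df = pd.DataFrame(
    [
        {"protein_id": r.protein_id, "log2fc": round(r.log2fc, 4), "pval": f"{r.pval:.3e}",
         "qval": f"{r.qval:.3e}", "de_class": r.de_class}
        for r in results
    ]
)
df.to_csv(RESULTS / "de_results.tsv", sep="\t", index=False)
volcano_table(results).round(4).to_csv(RESULTS / "volcano.tsv", sep="\t", index=False)

n_up = (df.de_class == "up").sum()
n_down = (df.de_class == "down").sum()
print(f"screened {len(df)} proteins: {n_up} up, {n_down} down ({n_up + n_down} DEPs)")
print(f"tables: {RESULTS / 'de_results.tsv'}, {RESULTS / 'volcano.tsv'}")
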