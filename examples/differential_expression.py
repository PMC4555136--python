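"""Count-based differential expression with the NB exact test.

Builds a small negative-binomial count table with ten planted effects,
runs the full DE chain (CPM filter -> TMM -> common dispersion -> exact
test -> BH FDR -> 1.5-fold / FDR<0.05 calls) and prints the top table.
"""

import numpy as np
import pandas as pd

from secribo.diffexpr import CountTable, de_analysis, top_table

rng = np.random.default_rng(11)
n_genes = 300
mu = rng.lognormal(5, 1.2, size=n_genes)
fold = np.ones(n_genes)
fold[:6] = 4.0   # up in condition B
fold[6:10] = 0.25  # down in condition B
r = 1 / 0.05     # dispersion 0.05

counts = np.column_stack([
    rng.negative_binomial(r, r / (r + mu * (fold if j >= 2 else 1.0)))
    for j in range(4)
])
df = pd.DataFrame(counts, columns=["A_rep1", "A_rep2", "B_rep1", "B_rep2"],
                  index=[f"gene{i:03d}" for i in range(n_genes)])
table = CountTable(df, {"A_rep1": "A", "A_rep2": "A",
                        "B_rep1": "B", "B_rep2": "B"})

res = de_analysis(table, numerator="B", denominator="A")
print(f"common dispersion estimate: {res.attrs['dispersion']:.4f} "
      "(simulated with 0.05)")
print(f"{int(res['is_de'].sum())} of {len(res)} genes called DE "
      "(|fold| > 1.5, FDR < 0.05)\n")
print(top_table(res, n=6).round(4).to_string())
print("\nsigned_fold is the normalized CPM ratio (negative = down in B); "
      "the ten planted genes (gene000-gene009) dominate both lists and "
      "null genes stay below the FDR threshold.")
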