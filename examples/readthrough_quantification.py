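"""Estimate UGA-Sec readthrough efficiency from 3'/5' RPKM ratios.

Simulates a one-condition grid in which each gene carries a different
planted readthrough probability, runs the full pipeline, and compares the
per-gene 3'/5' RPKM ratio against the planted value.
"""

import pandas as pd

from secribo.datasets import readthrough_grid_config
from secribo.pipeline import RunConfig, run_pipeline

sim = readthrough_grid_config(
    rhos=(0.1, 0.3, 0.5, 0.7, 0.9), seed=5, library_size=60_000)
cfg = RunConfig(outdir="example_output/readthrough", seed=5,
                run_rnaseq=False, numerator="grid", denominator="grid")
result = run_pipeline(cfg, sim_config=sim)

truth = pd.Series({g: c["grid"] for g, c in sim.readthrough.items()},
                  name="planted_rho")
est = result.readthrough.set_index("gene")["readthrough"]
table = pd.concat([truth, est.rename("estimated")], axis=1)
table["error"] = table["estimated"] - table["planted_rho"]
print(table.round(3).to_string())
print("\nThe 3'/5' RPKM ratio estimates the probability that a ribosome "
      "reaching the UGA-Sec codon incorporates selenocysteine and "
      "continues; under uniform elongation it is unbiased, and the error "
      "column is pure counting noise at this sequencing depth.")
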