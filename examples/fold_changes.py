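"""Dietary fold changes in selenoprotein translation (3'-of-Sec RPKMs).

Runs the full synthetic two-diet experiment at reduced depth and prints the
per-gene fold change in footprint RPKM downstream of the UGA-Sec codon
(supplemented over deficient diet), with propagation-of-error SDs.
"""

from secribo.pipeline import RunConfig, make_figure_tables, run_pipeline

cfg = RunConfig(outdir="example_output/folds", seed=9, library_size=200_000,
                min_window_count=25)
result = run_pipeline(cfg)
tables = make_figure_tables(result)

print("3'-of-Sec footprint RPKM fold changes (0.1 ppm Se / 0 ppm Se):\n")
print(tables["fp_3prime_fold"].round(2).to_string(index=False))
print("\nStress-related selenoproteins (Gpx1, Sepx1, Sepw1) respond "
      "strongly to dietary selenium, while housekeeping Gpx4 changes "
      "~1.9-fold; C-terminal-Sec genes (e.g. Txnrd1) have no 3' window and "
      "are absent.  fold_sd is the first-order propagation-of-error SD of "
      "the ratio of replicate means.")
print(f"\nA-site offset used: {result.offset_used} nt "
      "(inferred from the metagene)")
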