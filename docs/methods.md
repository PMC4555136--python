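# Methods

## Coordinate conventions

Everything is transcript-space: nucleotides are 0-based half-open, codon
indices 0-based from the start codon, the stop codon is the last CDS codon.
"First 15 codons excluded" means codon indices 0–14 are excluded; the
"last 3 codons" include the stop triplet.  Multiple UGA-Sec codons (Sepp1)
default to the 5′-most for the 5′/3′ split — the first UGA dominates
ribosome loss — and the choice is exposed as a parameter (`which_sec`).

## Quantification model

A footprint is assigned to a window iff the first nucleotide of its offset
A-site codon lies inside the window (point assignment, not any-overlap), so
the CDS-core, 5′-of-Sec and 3′-of-Sec windows are disjoint and additive.
RPKM uses the per-sample count of uniquely aligned reads as "total mapped".
No pseudocounts anywhere: zero denominators are flagged
(`denominator_zero`, `not_analyzable`) rather than smoothed, matching the
practice of reporting only analyzable genes.

Under uniform elongation the expected A-site density is constant upstream
of the UGA-Sec and ρ-times that downstream, so E[3′/5′ RPKM ratio] = ρ;
the estimator inherits only counting noise (verified by grid recovery in
the tests).  Replicate SDs use divisor n−1 — the only defensible estimator
at n = 2 — and ratio SDs use first-order (delta-method) propagation with no
covariance term (replicates are independent animals).  The delta method is
exact to O(cv²); it understates the Monte-Carlo SD of a raw ratio once the
denominator cv approaches ~0.3, which is why the tests validate it by
Monte-Carlo only in the low-cv regime and by closed form elsewhere.

An RPKM fold change is a *relative* quantity: it carries a composition
factor W₀/W₁, the ratio of total mapped output between conditions.  With a
genome-wide reference the factor is ≈1; on a small panel it is not, so the
bundled panel gives ~94 % of the library to unchanging background mRNAs and
derives its supplemented-diet ρ values by inverting the measurement model
(a fixed point in the composition factor), making the expected *measured*
fold equal the declared target.  This is a closed-form consequence of the
declared parameter table, computed at import time — not a fit to data.

## A-site offset and phasing

The start-anchored metagene (window −50…+70 nt, transcripts with CDS >
400 nt) shows a 3-nt comb whose onset is the 5′ end of initiating-ribosome
footprints: the P site holds the start codon, the A site is codon 1 (nt
+3), so onset = 3 − offset and offset = −onset + 3; canonical geometry
gives 16 nt.  The detector requires a dominant frame fraction > 1/3 + 0.1,
then takes the first position whose comb values (4 points, 3 nt apart)
exceed 2× the median of the profile upstream of it and dominate both
off-frame neighbours.  A single global offset is applied to all footprint
lengths (a per-length table can be supplied); RNA reads are shifted by the
same offset when compared against footprints — immaterial for window RPKMs
under uniform fragmentation, but kept for symmetry of treatment.  Phasing
fractions are computed modulo 3 relative to the CDS start, also for UTRs
("codon position" relative to the CDS frame).

## Read processing

Adapter trimming cuts at the first internal full-adapter match or a
terminal adapter-prefix match of ≥5 nt; inserts <15 nt are discarded (both
thresholds are documented defaults, configurable — the processing chain's
source protocol does not pin them).  rRNA depletion removes reads with any
alignment to the rRNA reference at ≤2 mismatches.  The internal aligner is
exhaustive and exact: a 14-mer dictionary drives the exact-match path, and
the pigeonhole principle (three read chunks; one must match exactly at ≤2
mismatches) drives the inexact path with full Hamming verification.
"Unique" means a single hit within the minimal-mismatch stratum; ties in
worse strata do not disqualify.  Only the forward strand is searched
(stranded libraries).  Footprint libraries are length-filtered to 26–36 nt
after trimming (the gel-excision window); RNA libraries are not.
Transcript-space SAM/BAM import (header-checked, NM-tag mismatches) is the
scale path for externally aligned data.

## Synthetic data generator

Per-codon Poisson placement of A-sites at rate ∝ θ_g,c, multiplied by
ρ_g,c for codons 3′ of the first UGA-Sec (a single Bernoulli branch at the
first Sec; no pausing model).  The 5′ end sits offset nt upstream with
probability φ, else jittered ±1 nt; lengths are drawn from a 26–36 nt
distribution peaked at 30–31 nt.  RNA fragments are uniform along the full
transcript (random fragmentation), with no phasing or Sec asymmetry.
Every sample has its own RNG stream keyed by (seed, library kind,
condition, replicate), making outputs byte-reproducible and samples
independent.  SimTruth records θ, ρ and the realized pre-jitter window
counts, which the downstream chain recounts exactly when φ = 1 and
contamination = 0 (jitter moves boundary reads between adjacent equal-rate
codons, so window expectations are unchanged at φ < 1).

Defaults are the study conditions: two diets (0Se, 0.1Se) × two biological
replicates, 10⁶ footprints/sample, φ = 0.8, offset 16 nt, 10 % rRNA
contamination.  The bundled panel has 24 selenoprotein genes + Gapdh with
liver-style relative abundances and Sec placements (C-terminal-Sec genes
included precisely because they are unanalyzable downstream), plus 14
abundant background mRNAs carrying most of the library.  The 10⁶ depth is
chosen so the lowest-coverage headline gene (Sepx1: ρ₀ = 0.075) still
collects ~900 baseline 3′-window counts, keeping fold-change noise below
the recovery tolerance.  What the generator does *not* emulate — sequencing
errors, ligation/sequence bias, codon-level pausing, isoform mixtures,
UMIs — bounds what passing tests show about real data: they validate the
estimators under the stated model, not robustness to those artifacts.

The synthetic rRNA reference is seeded random sequence (labelled synthetic;
it is not mouse rRNA): the pipeline only needs a reference that planted
contaminants match and mRNA-derived reads do not.

## Differential expression

CPM > 1 in ≥3 samples; TMM normalization (30 % M-trim, 5 % A-trim,
precision weights, reference = sample with upper-quartile closest to the
mean; factors geometric-mean-centred) — verified against the reference
implementation of the cited method to ~10⁻⁴ on a frozen fixture.  One
common NB dispersion is estimated by conditional maximum likelihood on
pseudo-counts equalized to the geometric-mean effective library size;
linear scaling is used for equalization (the simplest choice preserving
expected proportions — the quantile-based alternative differs negligibly
at these depths, and the frozen-fixture dispersion agrees within 0.2 %).
The exact test conditions one group's total on the grand total (negative
hypergeometric; binomial in the dispersion→0 limit) with two-sided
p-values by the minimum-likelihood rule.  Calls require |fold| > 1.5 (both
directions) and BH FDR < 0.05.  Common, not tagwise, dispersion: tagwise
estimation is unstable at two replicates per group.

## Numerical and reporting choices

- Dispersion is maximized on log φ over [10⁻⁶, 10] (bounded scalar
  minimization, xatol 10⁻⁴); a flat likelihood at the lower bound reports
  "effectively Poisson".
- Exact-test pmfs are computed in log space with a normalizing
  log-sum-exp; probability ties use a 10⁻¹⁰ relative tolerance.
- Longest-isoform reduction breaks length ties toward the smaller
  accession (deterministic, idempotent).
- Fold-change tables flag windows whose baseline-condition mean count is
  below 100 (`low_coverage`, configurable): RPKM ratios from a handful of
  counts are shot-noise; the floor plays the role the CPM filter plays for
  DE.  Flagged and unanalyzable genes stay in the full tables and manifest.
- Alignment output is emitted sorted, so results are invariant to read
  input order; per-stage read counts must reconcile exactly
  (raw = trimmed-away + rRNA + aligned + multi + unaligned) and the
  manifest records the check.

## Limitations

Transcript space only (no spliced/genomic alignment), single-end reads, no
quality-aware scoring, no pause-site or dwell-time modelling, no
molar synthesis rates.  The readthrough estimator assumes uniform
elongation within windows; strong pausing near the Sec codon would bias it
— which is precisely why the flanking codons (5 upstream, 1 downstream of
the UGA-Sec) are excluded from both windows.
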