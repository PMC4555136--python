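"""Windowed RPKM quantification, fold changes, and the readthrough ratio.

RPKM here is reads per kilobase of *window* per million total mapped reads,
with "total mapped" the number of uniquely aligned reads in the sample
(against the reduced reference set).  A read belongs to a window iff the
first nucleotide of its offset A-site codon lies inside the window, so the
three windows are additive and disjoint.

The Sec-incorporation (readthrough) proxy for a selenoprotein is the ratio
of the 3'-of-Sec RPKM to the 5'-of-Sec RPKM: ribosomes lost to termination
at the UGA-Sec depress downstream density by exactly the readthrough
efficiency under uniform elongation, so in expectation the ratio recovers
rho.

Condition fold changes are ratios of replicate means; their standard
deviations use first-order (delta-method) propagation of error,

    sd(fold) = fold * sqrt((sd_num/mean_num)^2 + (sd_den/mean_den)^2),

with the sample SD (divisor n-1) over biological replicates and no
covariance term (replicates are independent animals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiling import SiteProfile
from .transcriptome import (
    CodonWindow,
    NotAnalyzableError,
    TranscriptModel,
    make_cds_core_window,
    make_sec_windows,
)


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class RegionQuant:
    gene: str
    sample_id: str
    label: str
    count: int
    length_nt: int
    total_mapped: int
    rpkm: float


@dataclass(frozen=True)
class FoldChange:
    gene: str
    label: str
    mean_num: float
    sd_num: float
    mean_den: float
    sd_den: float
    fold: float          # nan when undefined (denominator mean 0)
    fold_sd: float
    defined: bool


def total_mapped(alignments: Sequence) -> int:
    """Number of uniquely aligned reads in a sample (RPKM denominator)."""
    n = len(alignments)
    if n == 0:
        raise QuantError("no aligned reads: RPKM undefined")
    return n


def window_rpkm(profile: SiteProfile, window: CodonWindow,
                transcript: TranscriptModel, total: int,
                sample_id: str = "sample",
                gene: str | None = None) -> RegionQuant:
    """Sum A-site counts in a codon window and convert to RPKM."""
    if total <= 0:
        raise QuantError("total mapped reads must be positive")
    if profile.transcript_id != transcript.id:
        raise QuantError("profile/transcript mismatch")
    s, e = window.nt_span(transcript)
    count = int(profile.counts[s:e].sum())
    rpkm = count / (window.length_nt / 1000.0) / (total / 1e6)
    return RegionQuant(gene or transcript.gene, sample_id,
                       window.label, count, window.length_nt, total, rpkm)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def fold_change(gene: str, label: str,
                numerator: Sequence[float],
                denominator: Sequence[float]) -> FoldChange:
    """Ratio of condition means with delta-method error propagation.

    ``numerator``/``denominator`` are per-replicate RPKMs for the two
    conditions (numerator conventionally the supplemented diet).  A zero
    denominator mean yields an undefined (flagged) fold change.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.size == 0 or den.size == 0:
        raise QuantError(f"{gene}/{label}: need >=1 replicate per condition")
    m1, m0 = float(num.mean()), float(den.mean())
    s1, s0 = _sd(num), _sd(den)
    if m0 == 0.0:
        return FoldChange(gene, label, m1, s1, m0, s0,
                          math.nan, math.nan, False)
    fold = m1 / m0
    rel1 = (s1 / m1) ** 2 if m1 != 0 else 0.0
    rel0 = (s0 / m0) ** 2
    fold_sd = fold * math.sqrt(rel1 + rel0)
    return FoldChange(gene, label, m1, s1, m0, s0, fold, fold_sd, True)


def readthrough_ratio(five: RegionQuant, three: RegionQuant) -> float:
    """3'/5' RPKM ratio: the Sec readthrough-efficiency estimator."""
    if five.rpkm == 0.0:
        raise QuantError(
            f"{five.gene}: 5'-of-Sec RPKM is zero; readthrough undefined")
    return three.rpkm / five.rpkm


def quantify_sample(profiles: Mapping[str, SiteProfile],
                    transcripts: Sequence[TranscriptModel],
                    total: int,
                    sample_id: str,
                    which_sec: int | None = None) -> pd.DataFrame:
    """Per-gene window quantification table for one sample.

    One row per (gene, window); windows that are not analyzable for a gene
    (no UGA-Sec, C-terminal Sec, short CDS) appear with ``analyzable=False``
    and NaN quantities, so nothing silently disappears.
    """
    rows = []

    def add(gene, label, rq: RegionQuant | None):
        if rq is None:
            rows.append((gene, sample_id, label, np.nan, np.nan, total,
                         np.nan, False))
        else:
            rows.append((gene, sample_id, label, rq.count, rq.length_nt,
                         total, rq.rpkm, True))

    for t in transcripts:
        prof = profiles.get(t.id)
        if prof is None:
            continue
        try:
            w = make_cds_core_window(t)
            add(t.gene, w.label, window_rpkm(prof, w, t, total))
        except NotAnalyzableError:
            add(t.gene, "cds_core", None)
        if not t.sec_codon_indices:
            continue
        sec = which_sec if (which_sec in t.sec_codon_indices) else None
        try:
            five, three = make_sec_windows(t, which_sec=sec)
            add(t.gene, five.label, window_rpkm(prof, five, t, total))
            add(t.gene, three.label, window_rpkm(prof, three, t, total))
        except NotAnalyzableError as exc:
            if exc.side in ("five_prime", "both"):
                add(t.gene, "five_prime_of_sec", None)
            else:
                first, last = 15, t.sec_codon_indices[0] - 6
                w = CodonWindow(t.id, first, last, "five_prime_of_sec")
                add(t.gene, w.label, window_rpkm(prof, w, t, total))
            if exc.side in ("three_prime", "both"):
                add(t.gene, "three_prime_of_sec", None)
            else:
                first = t.sec_codon_indices[0] + 2
                last = t.stop_codon_index - 3
                w = CodonWindow(t.id, first, last, "three_prime_of_sec")
                add(t.gene, w.label, window_rpkm(prof, w, t, total))
    return pd.DataFrame(rows, columns=[
        "gene", "sample", "label", "count", "length_nt", "total_mapped",
        "rpkm", "analyzable"])


def fold_change_table(quants: pd.DataFrame,
                      sample_conditions: Mapping[str, str],
                      numerator: str = "0.1Se",
                      denominator: str = "0Se") -> pd.DataFrame:
    """Per-gene, per-window fold changes across conditions.

    ``quants`` is a concatenation of :func:`quantify_sample` outputs over
    samples; ``sample_conditions`` maps sample id -> condition.  Genes whose
    window is not analyzable in any sample are flagged, not dropped.
    """
    df = quants.copy()
    df["condition"] = df["sample"].map(sample_conditions)
    rows = []
    for (gene, label), grp in df.groupby(["gene", "label"], sort=True):
        if not grp["analyzable"].all():
            rows.append((gene, label, np.nan, np.nan, np.nan, np.nan,
                         np.nan, np.nan, False, "not_analyzable"))
            continue
        num = grp.loc[grp["condition"] == numerator, "rpkm"].to_numpy()
        den = grp.loc[grp["condition"] == denominator, "rpkm"].to_numpy()
        fc = fold_change(gene, label, num, den)
        flag = "ok" if fc.defined else "denominator_zero"
        rows.append((gene, label, fc.mean_num, fc.sd_num, fc.mean_den,
                     fc.sd_den, fc.fold, fc.fold_sd, fc.defined, flag))
    return pd.DataFrame(rows, columns=[
        "gene", "label", "mean_num", "sd_num", "mean_den", "sd_den",
        "fold", "fold_sd", "defined", "flag"])


def readthrough_table(quants: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample 3'/5' RPKM readthrough estimates."""
    rows = []
    for (gene, sample), grp in quants.groupby(["gene", "sample"], sort=True):
        g = grp.set_index("label")
        if not {"five_prime_of_sec", "three_prime_of_sec"} <= set(g.index):
            continue
        five = g.loc["five_prime_of_sec"]
        three = g.loc["three_prime_of_sec"]
        if not (five["analyzable"] and three["analyzable"]):
            rows.append((gene, sample, np.nan, False, "not_analyzable"))
            continue
        if five["rpkm"] == 0:
            rows.append((gene, sample, np.nan, False, "five_prime_zero"))
            continue
        rows.append((gene, sample, three["rpkm"] / five["rpkm"], True, "ok"))
    return pd.DataFrame(rows, columns=["gene", "sample", "readthrough",
                                       "defined", "flag"])
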