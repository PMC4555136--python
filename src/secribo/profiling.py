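"""Metagene aggregation, A-site offset inference and triplet-phasing QC.

Genuine ribosome footprints show a 3-nt periodicity of their 5' ends that
reflects the codon step of translocation.  Anchored at start codons, the
periodic comb begins ``offset - 3`` nt upstream of the A of the AUG: the
initiating ribosome holds the start codon in its P site, so the first
elongation A-site is codon 1 (nt +3), and a footprint whose A-site first nt
is ``d`` nt downstream of its 5' end therefore has its 5' end at ``3 - d``.
For the canonical geometry (onset at -13) this gives an A-site offset of 16.

The offset detector makes that visual inference explicit: the onset is the
first window position where the 3-nt-spaced comb exceeds twice the local
background, and the offset is ``-onset + 3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .readproc import AlignedRead
from .transcriptome import (
    NotAnalyzableError,
    TranscriptModel,
    make_sec_windows,
)

START_WINDOW = (-50, 70)
STOP_WINDOW = (-70, 35)
MIN_CDS_NT = 400  # metagene includes only transcripts with CDS > 400 nt

REGION_CLASSES = ("cds", "utr5", "utr3", "five_prime_of_sec",
                  "three_prime_of_sec")


class PeriodicityError(RuntimeError):
    """No detectable triplet periodicity; supply the offset manually."""


@dataclass
class SiteProfile:
    """Per-nucleotide counts on one transcript.

    Raw 5'-end counts when ``offset_applied == 0``; A-site first-nt counts
    after offsetting.  Reads whose offset A-site falls outside the transcript
    are dropped and tallied by :func:`apply_offset`.
    """

    transcript_id: str
    counts: np.ndarray
    offset_applied: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PhasingSummary:
    """Fractions of read 5' ends on codon positions 1/2/3 of a region.

    ``fractions`` is None when the region received no reads (undefined, not
    0/0/0).  Frame is defined modulo 3 relative to the first nt of the start
    codon; position 1 is in frame with it.
    """

    region_class: str
    fractions: tuple[float, float, float] | None
    n_reads: int

    @property
    def dominant_fraction(self) -> float | None:
        return None if self.fractions is None else max(self.fractions)


def _group_positions(alignments: Iterable[AlignedRead]
                     ) -> dict[str, np.ndarray]:
    by_tx: dict[str, list[int]] = {}
    for a in alignments:
        by_tx.setdefault(a.transcript_id, []).append(a.pos5)
    return {k: np.asarray(v, dtype=int) for k, v in by_tx.items()}


def metagene_profile(alignments: Sequence[AlignedRead],
                     transcripts: Sequence[TranscriptModel],
                     anchor: str = "start",
                     window: tuple[int, int] | None = None,
                     min_cds_nt: int = MIN_CDS_NT) -> pd.Series:
    """Fraction of read 5' ends at each position relative to start/stop.

    Positions are relative to the first nt of the start codon (``anchor =
    'start'``) or the first nt of the stop codon (``'stop'``).  Counts are
    summed over qualifying transcripts (CDS > ``min_cds_nt``) and normalized
    over the window; an all-zero window yields an all-zero profile.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    if window is None:
        window = START_WINDOW if anchor == "start" else STOP_WINDOW
    lo, hi = window
    width = hi - lo + 1
    acc = np.zeros(width, dtype=float)
    by_tx = _group_positions(alignments)
    n_used = 0
    for t in transcripts:
        if t.cds_length <= min_cds_nt:
            continue
        pos = by_tx.get(t.id)
        n_used += 1
        if pos is None or pos.size == 0:
            continue
        anchor_nt = t.cds_start if anchor == "start" \
            else t.cds_start + 3 * t.stop_codon_index
        rel = pos - anchor_nt
        sel = rel[(rel >= lo) & (rel <= hi)]
        acc += np.bincount(sel - lo, minlength=width)
    if n_used == 0:
        import warnings
        warnings.warn("no transcripts qualify for the metagene profile")
    total = acc.sum()
    if total > 0:
        acc = acc / total
    return pd.Series(acc, index=np.arange(lo, hi + 1), name="fraction")


def dominant_frame_fraction(profile: pd.Series) -> float:
    """Largest of the three frame sums of a metagene profile."""
    vals = profile.to_numpy()
    frames = np.asarray(profile.index) % 3
    sums = [vals[frames == f].sum() for f in range(3)]
    total = sum(sums)
    if total == 0:
        return 0.0
    return max(sums) / total


def infer_asite_offset(start_profile: pd.Series,
                       search: tuple[int, int] = (-30, 0),
                       margin: float = 0.1,
                       comb_points: int = 4) -> int:
    """Infer the 5'-end -> A-site offset from a start-anchored metagene.

    The periodicity onset is the first position ``p`` (scanning 5' to 3'
    within ``search``) whose comb values ``profile[p], profile[p+3], ...``
    all exceed twice the local background (median of the profile upstream of
    ``p``) and dominate their two off-frame neighbours.  The offset is
    ``-p + 3``: the onset footprints hold the start codon in the P site, so
    their A-site is one codon downstream.
    """
    if dominant_frame_fraction(start_profile) < 1.0 / 3.0 + margin:
        raise PeriodicityError(
            "no dominant reading frame in the start-anchored profile; "
            "set the A-site offset manually")
    vals = start_profile.to_numpy()
    index = list(start_profile.index)
    floor = 1.0 / (10.0 * len(vals))
    for p in range(search[0], search[1] + 1):
        if p not in index or (p + 3 * (comb_points - 1)) not in index:
            continue
        i = index.index(p)
        upstream = vals[:i]
        background = max(float(np.median(upstream)) if upstream.size else 0.0,
                         floor)
        comb = vals[i:i + 3 * comb_points:3]
        if np.all(comb > 2.0 * background) and \
                vals[i] > vals[i + 1] and vals[i] > vals[i + 2]:
            return -p + 3
    raise PeriodicityError(
        "no periodicity onset found in the search window; "
        "set the A-site offset manually")


def _region_spans(t: TranscriptModel, region_class: str
                  ) -> list[tuple[int, int]]:
    if region_class == "cds":
        return [(t.cds_start, t.cds_end)]
    if region_class == "utr5":
        return [(0, t.cds_start)] if t.cds_start > 0 else []
    if region_class == "utr3":
        return [(t.cds_end, t.length)] if t.cds_end < t.length else []
    if region_class in ("five_prime_of_sec", "three_prime_of_sec"):
        if not t.sec_codon_indices:
            return []
        try:
            five, three = make_sec_windows(t)
        except NotAnalyzableError as exc:
            if exc.side == "three_prime" and region_class == "five_prime_of_sec":
                first, last = 15, t.sec_codon_indices[0] - 6
                if first <= last:
                    return [(t.codon_nt(first), t.codon_nt(last) + 3)]
            if exc.side == "five_prime" and region_class == "three_prime_of_sec":
                first = t.sec_codon_indices[0] + 2
                last = t.stop_codon_index - 3
                if first <= last:
                    return [(t.codon_nt(first), t.codon_nt(last) + 3)]
            return []
        w = five if region_class == "five_prime_of_sec" else three
        return [w.nt_span(t)]
    raise ValueError(f"unknown region class {region_class!r}")


def phasing_fractions(alignments: Sequence[AlignedRead],
                      transcripts: Sequence[TranscriptModel],
                      region_class: str) -> PhasingSummary:
    """Triplet-phasing fractions of read 5' ends within a region class.

    UTR "codon" positions are defined relative to the CDS reading frame, so
    the frame of a 5' end at transcript position ``p`` is always
    ``(p - cds_start) mod 3``.
    """
    by_tx = _group_positions(alignments)
    counts = np.zeros(3, dtype=np.int64)
    for t in transcripts:
        pos = by_tx.get(t.id)
        if pos is None or pos.size == 0:
            continue
        for s, e in _region_spans(t, region_class):
            sel = pos[(pos >= s) & (pos < e)]
            if sel.size:
                counts += np.bincount((sel - t.cds_start) % 3, minlength=3)
    n = int(counts.sum())
    if n == 0:
        return PhasingSummary(region_class, None, 0)
    frac = counts / n
    return PhasingSummary(region_class, (float(frac[0]), float(frac[1]),
                                         float(frac[2])), n)


def phasing_table(alignments: Sequence[AlignedRead],
                  transcripts: Sequence[TranscriptModel],
                  region_classes: Sequence[str] = REGION_CLASSES
                  ) -> pd.DataFrame:
    rows = []
    for rc in region_classes:
        s = phasing_fractions(alignments, transcripts, rc)
        f1, f2, f3 = s.fractions if s.fractions else (np.nan, np.nan, np.nan)
        rows.append((rc, s.n_reads, f1, f2, f3))
    return pd.DataFrame(rows, columns=["region_class", "n_reads",
                                       "f1", "f2", "f3"])


def apply_offset(alignments: Sequence[AlignedRead],
                 transcripts: Sequence[TranscriptModel],
                 offset: int) -> tuple[dict[str, SiteProfile], int]:
    """A-site profiles: each read contributes one count at ``pos5 + offset``.

    Returns the per-transcript profiles and the number of reads dropped
    because their A-site fell outside the transcript.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    lengths = {t.id: t.length for t in transcripts}
    profiles = {
        t.id: SiteProfile(t.id, np.zeros(t.length, dtype=np.int64), offset)
        for t in transcripts
    }
    n_dropped = 0
    by_tx = _group_positions(alignments)
    for tid, pos in by_tx.items():
        if tid not in profiles:
            n_dropped += pos.size
            continue
        shifted = pos + offset
        ok = shifted < lengths[tid]
        n_dropped += int((~ok).sum())
        profiles[tid].counts += np.bincount(shifted[ok],
                                            minlength=lengths[tid])
    return profiles, n_dropped
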