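"""Adapter trimming, rRNA depletion and unique transcript-space alignment.

The processing chain mirrors a standard footprint/RNA-Seq preprocessing
stack: 3' adapter removal, removal of reads aligning to an rRNA reference,
then unique alignment (forward strand, at most 2 mismatches) against the
reduced transcriptome.  The internal aligner is exhaustive and exact — a
seed-and-verify Hamming search over the concatenated reference — which is
entirely adequate at desk scale (a few dozen mRNAs); externally produced
transcript-space SAM/BAM can be imported for larger references.

Uniqueness is defined *within the best stratum*: a read is reported iff it
has exactly one alignment position at its minimal mismatch count (<= 2);
extra hits at higher mismatch counts do not disqualify it.  Libraries are
stranded, so only the forward strand is searched.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .transcriptome import TranscriptModel

MIN_READ_LENGTH = 15      # post-trim length floor
MAX_MISMATCHES = 2
FOOTPRINT_RANGE = (26, 36)  # gel-excision size window for footprint libraries


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely mapped read 5' end on a transcript."""

    transcript_id: str
    pos5: int
    length: int
    mismatches: int
    sample_id: str


@dataclass
class AlignStats:
    sample_id: str
    n_input: int = 0
    n_aligned: int = 0
    n_multi: int = 0
    n_unaligned: int = 0

    def conserved(self) -> bool:
        return self.n_input == self.n_aligned + self.n_multi + self.n_unaligned


def trim_adapter(read: str, adapter: str,
                 min_overlap: int = 5,
                 min_length: int = MIN_READ_LENGTH) -> str | None:
    """Remove the 3' adapter; return the insert or None if discarded.

    The read is truncated at the first internal full-adapter occurrence, or
    at a suffix of the read matching a prefix of the adapter of at least
    ``min_overlap`` nt.  Inserts shorter than ``min_length`` are discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    cut = read.find(adapter)
    if cut < 0:
        # suffix of read == prefix of adapter, >= min_overlap nt
        max_ov = min(len(read), len(adapter) - 1)
        for ov in range(max_ov, min_overlap - 1, -1):
            if read.endswith(adapter[:ov]):
                cut = len(read) - ov
                break
    if cut < 0:
        insert = read
    else:
        insert = read[:cut]
    return insert if len(insert) >= min_length else None


def trim_reads(reads: Iterable[str], adapter: str,
               min_overlap: int = 5,
               min_length: int = MIN_READ_LENGTH) -> tuple[list[str], int]:
    """Trim a library; returns (kept inserts, number discarded)."""
    kept: list[str] = []
    n_discarded = 0
    cache: dict[str, str | None] = {}
    for r in reads:
        ins = cache.get(r, "\0")
        if ins == "\0":
            ins = trim_adapter(r, adapter, min_overlap, min_length)
            cache[r] = ins
        if ins is None:
            n_discarded += 1
        else:
            kept.append(ins)
    return kept, n_discarded


class ReferenceIndex:
    """Concatenated forward-strand reference supporting exhaustive
    <=2-mismatch search.

    Exact hits are found with C-speed substring search; inexact hits use the
    pigeonhole principle (a read split into three chunks must match one chunk
    exactly if it has at most two mismatches) followed by full Hamming
    verification.
    """

    _SEP = "#" * 40  # longer than any read: no cross-boundary matches
    _K = 14          # prefix k-mer width of the exact-hit dictionary

    def __init__(self, sequences: Sequence[tuple[str, str]]):
        self.names = [name for name, _ in sequences]
        self.seqs = [seq for _, seq in sequences]
        offsets = []
        parts = []
        pos = 0
        for seq in self.seqs:
            offsets.append(pos)
            parts.append(seq)
            pos += len(seq) + len(self._SEP)
            parts.append(self._SEP)
        self.text = "".join(parts)
        self.offsets = offsets
        self.lengths = [len(s) for s in self.seqs]
        # k-mer -> text positions; drives the (dominant) exact-match path
        kmers: dict[str, list[int]] = {}
        k = self._K
        for off, seq in zip(offsets, self.seqs):
            for i in range(len(seq) - k + 1):
                kmers.setdefault(seq[i:i + k], []).append(off + i)
        self._kmers = kmers

    @classmethod
    def from_transcripts(cls, transcripts: Sequence[TranscriptModel]
                         ) -> "ReferenceIndex":
        return cls([(t.id, t.sequence) for t in transcripts])

    def _locate(self, text_pos: int, read_len: int) -> tuple[int, int] | None:
        i = bisect_right(self.offsets, text_pos) - 1
        pos = text_pos - self.offsets[i]
        if pos + read_len <= self.lengths[i]:
            return i, pos
        return None

    def _exact_hits(self, read: str) -> list[tuple[int, int]]:
        n = len(read)
        text = self.text
        if n >= self._K:
            hits = []
            for p in self._kmers.get(read[:self._K], ()):
                if text[p:p + n] == read:
                    loc = self._locate(p, n)
                    if loc is not None:
                        hits.append(loc)
            return hits
        hits = []
        start = text.find(read)
        while start >= 0:
            loc = self._locate(start, n)
            if loc is not None:
                hits.append(loc)
            start = text.find(read, start + 1)
        return hits

    def _inexact_hits(self, read: str, max_mm: int) -> list[tuple[int, int, int]]:
        n = len(read)
        third = n // 3
        chunks = [(0, read[:third]), (third, read[third:2 * third]),
                  (2 * third, read[2 * third:])]
        candidates: set[int] = set()
        for chunk_off, chunk in chunks:
            if not chunk:
                continue
            start = self.text.find(chunk)
            while start >= 0:
                candidates.add(start - chunk_off)
                start = self.text.find(chunk, start + 1)
        hits = []
        for cand in sorted(candidates):
            if cand < 0:
                continue
            loc = self._locate(cand, n)
            if loc is None:
                continue
            ref = self.text[cand:cand + n]
            mm = sum(a != b for a, b in zip(read, ref))
            if mm <= max_mm:
                hits.append((loc[0], loc[1], mm))
        return hits

    def find_all(self, read: str, max_mm: int = MAX_MISMATCHES
                 ) -> tuple[int, list[tuple[int, int]]]:
        """All hits in the minimal mismatch stratum.

        Returns ``(stratum, [(seq_index, pos), ...])``; stratum is -1 with an
        empty list when nothing aligns within ``max_mm``.
        """
        exact = self._exact_hits(read)
        if exact:
            return 0, exact
        hits = self._inexact_hits(read, max_mm)
        if not hits:
            return -1, []
        best = min(h[2] for h in hits)
        return best, [(i, p) for i, p, mm in hits if mm == best]

    def has_hit(self, read: str, max_mm: int = MAX_MISMATCHES) -> bool:
        if self._exact_hits(read):
            return True
        return bool(self._inexact_hits(read, max_mm))


def filter_rrna(reads: Iterable[str],
                rrna_sequences: Sequence[tuple[str, str]],
                max_mm: int = MAX_MISMATCHES) -> tuple[list[str], int]:
    """Drop reads aligning to the rRNA reference at <=2 mismatches."""
    if not rrna_sequences:
        raise ValueError("rRNA reference is required for depletion")
    index = ReferenceIndex(rrna_sequences)
    kept: list[str] = []
    n_removed = 0
    cache: dict[str, bool] = {}
    for r in reads:
        hit = cache.get(r)
        if hit is None:
            hit = index.has_hit(r, max_mm)
            cache[r] = hit
        if hit:
            n_removed += 1
        else:
            kept.append(r)
    return kept, n_removed


def align_unique(reads: Iterable[str],
                 transcripts: Sequence[TranscriptModel],
                 sample_id: str = "sample",
                 max_mm: int = MAX_MISMATCHES,
                 length_range: tuple[int, int] | None = None,
                 index: ReferenceIndex | None = None,
                 ) -> tuple[list[AlignedRead], AlignStats]:
    """Uniquely align reads to the transcriptome.

    ``length_range`` (inclusive), when given, drops reads outside it before
    alignment — used as the 26-36 nt footprint size filter.  Identical read
    sequences are aligned once and the result reused, so the output is
    invariant to input order (it is emitted sorted).
    """
    if index is None:
        index = ReferenceIndex.from_transcripts(transcripts)
    stats = AlignStats(sample_id=sample_id)
    counter = Counter()
    for r in reads:
        stats.n_input += 1
        counter[r] += 1

    out: list[AlignedRead] = []
    for seq, n in counter.items():
        if length_range is not None and not (
                length_range[0] <= len(seq) <= length_range[1]):
            stats.n_unaligned += n
            continue
        stratum, hits = index.find_all(seq, max_mm)
        if stratum < 0:
            stats.n_unaligned += n
        elif len(hits) > 1:
            stats.n_multi += n
        else:
            i, pos = hits[0]
            stats.n_aligned += n
            out.extend([AlignedRead(index.names[i], pos, len(seq),
                                    stratum, sample_id)] * n)
    out.sort(key=lambda a: (a.transcript_id, a.pos5, a.length))
    return out, stats


def alignments_to_frame(alignments: Sequence[AlignedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [a.sample_id for a in alignments],
            "transcript": [a.transcript_id for a in alignments],
            "pos5": np.array([a.pos5 for a in alignments], dtype=int),
            "length": np.array([a.length for a in alignments], dtype=int),
            "mismatches": np.array([a.mismatches for a in alignments],
                                   dtype=int),
        }
    )


def frame_to_alignments(df: pd.DataFrame) -> list[AlignedRead]:
    return [
        AlignedRead(r.transcript, int(r.pos5), int(r.length),
                    int(r.mismatches), r.sample)
        for r in df.itertuples(index=False)
    ]


def write_alignments(alignments: Sequence[AlignedRead],
                     path: str | Path) -> None:
    alignments_to_frame(alignments).to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path) -> list[AlignedRead]:
    return frame_to_alignments(pd.read_csv(path, sep="\t"))


def import_sam(path: str | Path,
               transcripts: Sequence[TranscriptModel],
               sample_id: str | None = None) -> list[AlignedRead]:
    """Import transcript-space alignments from SAM/BAM.

    The header is checked against the reference (names and lengths must
    match); unmapped and reverse-strand records are skipped; mismatches come
    from the NM tag when present.
    """
    import pysam

    expected = {t.id: t.length for t in transcripts}
    mode = "rb" if str(path).endswith(".bam") else "r"
    sample = sample_id or Path(path).stem
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for sq in fh.header.get("SQ", []):
            name, ln = sq["SN"], sq["LN"]
            if name in expected and expected[name] != ln:
                raise ValueError(
                    f"SAM header length {ln} for {name} does not match "
                    f"reference length {expected[name]}")
        for rec in fh:
            if rec.is_unmapped or rec.is_reverse:
                continue
            if rec.reference_name not in expected:
                continue
            mm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if mm > MAX_MISMATCHES:
                continue
            out.append(AlignedRead(rec.reference_name, rec.reference_start,
                                   rec.query_length, int(mm), sample))
    return out


def export_sam(alignments: Sequence[AlignedRead],
               transcripts: Sequence[TranscriptModel],
               path: str | Path) -> None:
    """Write alignments as transcript-space SAM (sequences from reference)."""
    import pysam

    seqs = {t.id: t.sequence for t in transcripts}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t.id, "LN": t.length} for t in transcripts],
    }
    tid = {t.id: i for i, t in enumerate(transcripts)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, a in enumerate(alignments):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = f"{a.sample_id}:{i}"
            rec.reference_id = tid[a.transcript_id]
            rec.reference_start = a.pos5
            rec.mapping_quality = 255
            rec.cigarstring = f"{a.length}M"
            rec.query_sequence = seqs[a.transcript_id][a.pos5:a.pos5 + a.length]
            rec.set_tag("NM", a.mismatches)
            fh.write(rec)
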