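"""Reference transcripts, CDS geometry, and codon windows.

All downstream counting happens in transcript space.  A transcript carries a
CDS (start codon through stop codon, inclusive) and, for selenoprotein mRNAs,
one or more in-frame UGA codons that are recoded to selenocysteine (Sec).
This module validates those annotations and derives the three codon windows
used for quantification:

``cds_core``
    the CDS with the first 15 and last 3 codons excluded, to avoid the
    initiation/termination coverage bias of ribosome footprints;
``five_prime_of_sec``
    codon 15 up to the 6th codon before the UGA-Sec (i.e. the 5 codons
    immediately preceding the UGA-Sec are excluded);
``three_prime_of_sec``
    the 2nd codon after the UGA-Sec up to the 3rd codon before the stop.

Coordinates are 0-based and half-open on nucleotides; codon indices are
0-based relative to the start codon, and the stop codon is the last codon of
the CDS.  When a UGA-Sec sits too close to the start or the stop to leave a
non-empty window, the transcript is *not analyzable* on that side — this is
exactly what happens for C-terminal-Sec selenoproteins such as Txnrd1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CDS_HEAD_EXCLUDE = 15  # codons excluded after the initiation codon
CDS_TAIL_EXCLUDE = 3   # codons excluded at the CDS 3' end (incl. the stop)
SEC_UPSTREAM_EXCLUDE = 5   # codons immediately 5' of the UGA-Sec excluded
SEC_DOWNSTREAM_EXCLUDE = 1  # the codon immediately 3' of the UGA-Sec excluded

WINDOW_LABELS = ("cds_core", "five_prime_of_sec", "three_prime_of_sec")


class TranscriptValidationError(ValueError):
    """A transcript record violates a CDS/Sec-annotation invariant."""


class NotAnalyzableError(ValueError):
    """A Sec codon is too close to the CDS boundary to define a window."""

    def __init__(self, transcript_id: str, side: str, message: str):
        self.transcript_id = transcript_id
        self.side = side
        super().__init__(message)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with CDS boundaries and UGA-Sec codon annotations.

    ``sec_codon_indices`` are codon indices relative to the start codon
    (codon 0); each must address a UGA (DNA: TGA) triplet strictly before the
    stop codon.
    """

    id: str
    gene: str
    sequence: str
    cds_start: int
    cds_end: int
    sec_codon_indices: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def n_codons(self) -> int:
        """Number of CDS codons, the stop codon included."""
        return self.cds_length // 3

    @property
    def stop_codon_index(self) -> int:
        return self.n_codons - 1

    def codon_nt(self, codon_index: int) -> int:
        """Transcript offset of the first nucleotide of a CDS codon."""
        return self.cds_start + 3 * codon_index

    def codon(self, codon_index: int) -> str:
        start = self.codon_nt(codon_index)
        return self.sequence[start:start + 3]

    def validate(self) -> None:
        if self.cds_start < 0 or self.cds_end > self.length:
            raise TranscriptValidationError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}) outside "
                f"sequence of length {self.length}")
        if self.cds_length <= 0 or self.cds_length % 3 != 0:
            raise TranscriptValidationError(
                f"{self.id}: CDS length {self.cds_length} is not a positive "
                "multiple of 3")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise TranscriptValidationError(
                f"{self.id}: sequence contains non-ACGTN characters {bad}")
        prev = -1
        for idx in self.sec_codon_indices:
            if idx <= prev:
                raise TranscriptValidationError(
                    f"{self.id}: Sec codon indices not strictly increasing")
            prev = idx
            if not (0 < idx < self.stop_codon_index):
                raise TranscriptValidationError(
                    f"{self.id}: Sec codon index {idx} outside the sense "
                    f"codons 1..{self.stop_codon_index - 1}")
            triplet = self.codon(idx)
            if triplet != "TGA":
                raise TranscriptValidationError(
                    f"{self.id}: annotated Sec codon {idx} reads "
                    f"{triplet!r}, not UGA")


@dataclass(frozen=True)
class CodonWindow:
    """An inclusive codon-index interval on a transcript CDS."""

    transcript_id: str
    first_codon: int
    last_codon: int
    label: str

    def __post_init__(self):
        if self.first_codon > self.last_codon:
            raise ValueError(
                f"{self.transcript_id}/{self.label}: empty window "
                f"{self.first_codon}..{self.last_codon}")
        if self.label not in WINDOW_LABELS:
            raise ValueError(f"unknown window label {self.label!r}")

    @property
    def n_codons(self) -> int:
        return self.last_codon - self.first_codon + 1

    @property
    def length_nt(self) -> int:
        return 3 * self.n_codons

    def nt_span(self, t: TranscriptModel) -> tuple[int, int]:
        """Half-open nucleotide interval of this window on ``t``."""
        start = t.codon_nt(self.first_codon)
        end = t.codon_nt(self.last_codon) + 3
        if start < t.cds_start or end > t.cds_end:
            raise ValueError(
                f"{self.transcript_id}/{self.label}: window outside CDS")
        return start, end


def _normalize_seq(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def load_transcripts(
    fasta_source,
    annotation_table,
    strict: bool = False,
) -> tuple[list[TranscriptModel], list[tuple[str, str]]]:
    """Load and validate transcripts from FASTA plus an annotation table.

    Parameters
    ----------
    fasta_source
        Path/handle readable by ``Bio.SeqIO`` (fasta format).
    annotation_table
        Path to a TSV, or a DataFrame, with columns ``accession``, ``gene``,
        ``cds_start``, ``cds_end``, ``sec_codon_indices`` (comma-separated,
        may be empty).
    strict
        If True, the first invalid record raises; otherwise invalid records
        are collected into the returned rejection report.

    Returns
    -------
    (models, rejected)
        ``models`` are the validated transcripts in FASTA order; ``rejected``
        is a list of ``(record_id, reason)`` pairs.
    """
    if isinstance(annotation_table, pd.DataFrame):
        ann = annotation_table.copy()
    else:
        ann = pd.read_csv(annotation_table, sep="\t", dtype=str)
    ann = ann.set_index("accession")

    models: list[TranscriptModel] = []
    rejected: list[tuple[str, str]] = []
    for rec in SeqIO.parse(fasta_source, "fasta"):
        try:
            if rec.id not in ann.index:
                raise TranscriptValidationError(
                    f"{rec.id}: no annotation row")
            row = ann.loc[rec.id]
            sec_raw = row.get("sec_codon_indices", "")
            if pd.isna(sec_raw) or str(sec_raw).strip() == "":
                sec = ()
            else:
                sec = tuple(int(x) for x in str(sec_raw).split(","))
            model = TranscriptModel(
                id=rec.id,
                gene=str(row["gene"]),
                sequence=_normalize_seq(rec.seq),
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
                sec_codon_indices=sec,
            )
            model.validate()
        except (TranscriptValidationError, ValueError, KeyError) as exc:
            if strict:
                raise
            rejected.append((rec.id, str(exc)))
            continue
        models.append(model)
    return models, rejected


def reduce_to_longest_isoform(
    records: Iterable[TranscriptModel],
) -> list[TranscriptModel]:
    """Keep one transcript per gene symbol: the longest.

    Length ties break toward the lexicographically smallest accession so the
    reduction is deterministic and idempotent.
    """
    best: dict[str, TranscriptModel] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.gene)
        if cur is None:
            best[rec.gene] = rec
            order.append(rec.gene)
        elif rec.length > cur.length or (
            rec.length == cur.length and rec.id < cur.id
        ):
            best[rec.gene] = rec
    return [best[g] for g in order]


def make_cds_core_window(t: TranscriptModel) -> CodonWindow:
    """CDS window with the first 15 and last 3 codons excluded."""
    first = CDS_HEAD_EXCLUDE
    last = t.stop_codon_index - CDS_TAIL_EXCLUDE
    if last < first:
        raise NotAnalyzableError(
            t.id, "cds",
            f"{t.id}: CDS of {t.n_codons} codons leaves no core window")
    return CodonWindow(t.id, first, last, "cds_core")


def make_sec_windows(
    t: TranscriptModel, which_sec: int | None = None
) -> tuple[CodonWindow, CodonWindow]:
    """The 5'-of-Sec and 3'-of-Sec quantification windows.

    ``which_sec`` selects the UGA-Sec codon index; default is the 5'-most
    annotated Sec codon.  The UGA-Sec itself, the 5 codons preceding it, the
    codon following it, the first 15 codons of the CDS and the last 3 codons
    (stop included) belong to neither window.

    Raises :class:`NotAnalyzableError` when the Sec codon is located too
    close to the start or the stop to leave a non-empty window on that side
    (e.g. C-terminal-Sec selenoproteins have no 3' window).
    """
    if not t.sec_codon_indices:
        raise NotAnalyzableError(t.id, "both", f"{t.id}: no UGA-Sec codon")
    if which_sec is None:
        which_sec = t.sec_codon_indices[0]
    if which_sec not in t.sec_codon_indices:
        raise ValueError(
            f"{t.id}: codon {which_sec} is not an annotated Sec codon")

    five_first = CDS_HEAD_EXCLUDE
    five_last = which_sec - SEC_UPSTREAM_EXCLUDE - 1
    if five_last < five_first:
        raise NotAnalyzableError(
            t.id, "five_prime",
            f"{t.id}: UGA-Sec at codon {which_sec} leaves no 5' window")

    three_first = which_sec + SEC_DOWNSTREAM_EXCLUDE + 1
    three_last = t.stop_codon_index - CDS_TAIL_EXCLUDE
    if three_last < three_first:
        raise NotAnalyzableError(
            t.id, "three_prime",
            f"{t.id}: UGA-Sec at codon {which_sec} of "
            f"{t.n_codons} leaves no 3' window")

    five = CodonWindow(t.id, five_first, five_last, "five_prime_of_sec")
    three = CodonWindow(t.id, three_first, three_last, "three_prime_of_sec")
    return five, three


def windows_table(
    transcripts: Sequence[TranscriptModel], which_sec: int | None = None
) -> pd.DataFrame:
    """BED-like table (transcript, start, end, label), 0-based half-open.

    Sec windows are emitted only for transcripts where they are analyzable;
    sides that are not analyzable are listed with the reason in the
    ``not_analyzable`` frame attribute is avoided — instead a row with
    start == end == -1 marks them so nothing silently disappears.
    """
    rows = []
    for t in transcripts:
        try:
            w = make_cds_core_window(t)
            s, e = w.nt_span(t)
            rows.append((t.id, t.gene, s, e, w.label))
        except NotAnalyzableError:
            rows.append((t.id, t.gene, -1, -1, "cds_core"))
        if not t.sec_codon_indices:
            continue
        try:
            five, three = make_sec_windows(t, which_sec=None)
        except NotAnalyzableError as exc:
            if exc.side in ("five_prime", "both"):
                rows.append((t.id, t.gene, -1, -1, "five_prime_of_sec"))
            if exc.side in ("three_prime", "both"):
                rows.append((t.id, t.gene, -1, -1, "three_prime_of_sec"))
            # a one-sided failure still defines the other side
            if exc.side == "five_prime":
                try:
                    three_first = t.sec_codon_indices[0] + 2
                    three_last = t.stop_codon_index - CDS_TAIL_EXCLUDE
                    w = CodonWindow(t.id, three_first, three_last,
                                    "three_prime_of_sec")
                    s, e = w.nt_span(t)
                    rows.append((t.id, t.gene, s, e, w.label))
                except ValueError:
                    rows.append((t.id, t.gene, -1, -1, "three_prime_of_sec"))
            elif exc.side == "three_prime":
                try:
                    five_first = CDS_HEAD_EXCLUDE
                    five_last = t.sec_codon_indices[0] - 6
                    w = CodonWindow(t.id, five_first, five_last,
                                    "five_prime_of_sec")
                    s, e = w.nt_span(t)
                    rows.append((t.id, t.gene, s, e, w.label))
                except ValueError:
                    rows.append((t.id, t.gene, -1, -1, "five_prime_of_sec"))
            continue
        for w in (five, three):
            s, e = w.nt_span(t)
            rows.append((t.id, t.gene, s, e, w.label))
    return pd.DataFrame(
        rows, columns=["transcript", "gene", "start", "end", "label"])


def write_transcripts(
    transcripts: Sequence[TranscriptModel],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Serialize a validated transcript set as FASTA + annotation TSV."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=t.gene)
        for t in transcripts
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    ann = pd.DataFrame(
        {
            "accession": [t.id for t in transcripts],
            "gene": [t.gene for t in transcripts],
            "cds_start": [t.cds_start for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
            "sec_codon_indices": [
                ",".join(map(str, t.sec_codon_indices)) for t in transcripts
            ],
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def transcripts_to_fasta_str(transcripts: Sequence[TranscriptModel]) -> str:
    buf = io.StringIO()
    for t in transcripts:
        buf.write(f">{t.id} {t.gene}\n{t.sequence}\n")
    return buf.getvalue()
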