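"""Synthetic ribosome-footprint and RNA-Seq libraries with known truth.

The generator emulates the data-generating process of a two-diet mouse liver
experiment: for each condition (default ``0Se`` and ``0.1Se``) and biological
replicate it emits one footprint library and/or one total-RNA library over a
small transcriptome, together with a ground-truth table (``SimTruth``).

Model
-----
*Footprints.*  Elongating ribosomes are placed per codon: the expected A-site
count on each CDS codon is uniform at a rate proportional to the per-gene,
per-condition mRNA abundance ``theta``; codons downstream of the (first)
UGA-Sec codon are additionally multiplied by the readthrough efficiency
``rho`` in [0, 1] — the probability that a ribosome reaching the UGA-Sec
incorporates Sec and continues rather than terminating.  Counts are Poisson.
The footprint 5' end sits exactly ``asite_offset`` nt upstream of the A-site
codon's first nucleotide with probability ``phasing_fidelity``, otherwise it
is jittered by +/-1 nt.  Footprint lengths are drawn from a 26-36 nt
distribution.

*RNA fragments.*  Random fragmentation: fragment 5' ends are uniform along
the full transcript at a per-nt rate proportional to ``theta``; there is no
phasing and no 5'/3' asymmetry around the UGA-Sec (the mRNA is full length
regardless of how translation ends).

Both libraries carry rRNA contaminant reads at a configurable fraction, and
every emitted read is written as a 50-cycle sequencer read: inserts shorter
than 50 nt run into the 3' adapter, so the downstream trimming stage is
always exercised.

Reproducibility: each sample draws from its own ``numpy`` Generator seeded by
``(seed, library-kind, condition-index, replicate)``, so outputs are
byte-identical for a fixed config and independent across samples.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transcriptome import (
    NotAnalyzableError,
    TranscriptModel,
    make_cds_core_window,
    make_sec_windows,
)

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: default footprint/fragment length distribution over 26-36 nt, peaked at
#: 30-31 nt as in monosome footprint gels
DEFAULT_LENGTH_DIST: dict[int, float] = {
    26: 0.02, 27: 0.04, 28: 0.08, 29: 0.14, 30: 0.20, 31: 0.18,
    32: 0.13, 33: 0.09, 34: 0.06, 35: 0.04, 36: 0.02,
}

_BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_transcript(
    rng: np.random.Generator,
    accession: str,
    gene: str,
    n_codons: int,
    sec_codons: Sequence[int] = (),
    utr5: int = 60,
    utr3: int = 60,
) -> TranscriptModel:
    """Random transcript with planted start, UGA-Sec and stop codons.

    ``n_codons`` counts all CDS codons including the stop.  Accidental TGA
    triplets elsewhere in the CDS are irrelevant: Sec annotation is by
    curation, never inferred from sequence.
    """
    cds = list(random_sequence(rng, 3 * n_codons))
    cds[0:3] = "ATG"
    cds[-3:] = "TAA"
    for idx in sec_codons:
        cds[3 * idx:3 * idx + 3] = "TGA"
    seq = random_sequence(rng, utr5) + "".join(cds) + random_sequence(rng, utr3)
    t = TranscriptModel(
        id=accession, gene=gene, sequence=seq,
        cds_start=utr5, cds_end=utr5 + 3 * n_codons,
        sec_codon_indices=tuple(sec_codons),
    )
    t.validate()
    return t


def synthetic_rrna(n_seqs: int = 2, length: int = 1800,
                   seed: int = 7001) -> list[tuple[str, str]]:
    """Deterministic synthetic rRNA contaminant reference.

    A stand-in reference built from seeded random sequence (it is not mouse
    rRNA); the pipeline only needs *some* reference that contaminant reads
    align to and real reads do not.
    """
    rng = np.random.default_rng(seed)
    return [(f"rRNA_syn_{i+1}", random_sequence(rng, length))
            for i in range(n_seqs)]


@dataclass
class SimulationConfig:
    """Study design and generative parameters for one synthetic experiment.

    ``abundance[gene][condition]`` is theta, the expected RNA fragments per
    nucleotide (relative units; only ratios matter — libraries are scaled to
    ``library_size``).  ``readthrough[gene][condition]`` is rho in [0, 1];
    genes without a UGA-Sec codon ignore it.
    """

    transcripts: list[TranscriptModel]
    abundance: Mapping[str, Mapping[str, float]]
    readthrough: Mapping[str, Mapping[str, float]]
    seed: int = 1
    library_size: int = 1_000_000
    length_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    phasing_fidelity: float = 0.8
    asite_offset: int = 16
    rrna_fraction: float = 0.1
    replicates: int = 2
    conditions: tuple[str, ...] = ("0Se", "0.1Se")
    adapter: str = DEFAULT_ADAPTER
    read_cycles: int = 50

    def validate(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if not 0.0 <= self.phasing_fidelity <= 1.0:
            raise ValueError("phasing_fidelity must be in [0, 1]")
        if not 0.0 <= self.rrna_fraction < 1.0:
            raise ValueError("rrna_fraction must be in [0, 1)")
        if self.asite_offset < 0:
            raise ValueError("asite_offset must be >= 0")
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("length distribution must sum to 1")
        if not all(26 <= k <= 36 for k in self.length_dist):
            raise ValueError("footprint lengths must lie in 26..36 nt")
        for t in self.transcripts:
            t.validate()
            for c in self.conditions:
                th = self.abundance[t.gene][c]
                if th < 0:
                    raise ValueError(f"theta<0 for {t.gene}/{c}")
                if t.sec_codon_indices:
                    rho = self.readthrough[t.gene][c]
                    if not 0.0 <= rho <= 1.0:
                        raise ValueError(f"rho outside [0,1] for {t.gene}/{c}")

    def samples(self, kind: str) -> list[tuple[str, str, int]]:
        """(sample_id, condition, replicate) triples for one library kind."""
        out = []
        for ci, cond in enumerate(self.conditions):
            for rep in range(1, self.replicates + 1):
                out.append((f"{kind}_{cond}_rep{rep}", cond, rep))
        return out

    def rng_for(self, kind: str, cond_index: int, rep: int) -> np.random.Generator:
        kind_code = {"fp": 1, "rna": 2}[kind]
        return np.random.default_rng(
            [int(self.seed), kind_code, cond_index, rep])


@dataclass
class SampleReads:
    """In-memory library: sequencer read strings plus planted truth."""

    sample_id: str
    kind: str
    condition: str
    replicate: int
    reads: list[str]
    truth: pd.DataFrame  # one row per gene


def _window_count(asite_positions: np.ndarray, span) -> float:
    s, e = span
    return int(np.count_nonzero((asite_positions >= s) & (asite_positions < e)))


def _truth_row(t: TranscriptModel, asites: np.ndarray) -> dict:
    """Realized A-site counts (pre-jitter) in each quantification window."""
    row = {"count_cds_core": np.nan, "count_five_prime": np.nan,
           "count_three_prime": np.nan}
    try:
        w = make_cds_core_window(t)
        row["count_cds_core"] = _window_count(asites, w.nt_span(t))
    except NotAnalyzableError:
        pass
    if t.sec_codon_indices:
        try:
            five, three = make_sec_windows(t)
            row["count_five_prime"] = _window_count(asites, five.nt_span(t))
            row["count_three_prime"] = _window_count(asites, three.nt_span(t))
        except NotAnalyzableError as exc:
            if exc.side == "five_prime":
                first = t.sec_codon_indices[0] + 2
                last = t.stop_codon_index - 3
                if first <= last:
                    span = (t.codon_nt(first), t.codon_nt(last) + 3)
                    row["count_three_prime"] = _window_count(asites, span)
            elif exc.side == "three_prime":
                first, last = 15, t.sec_codon_indices[0] - 6
                if first <= last:
                    span = (t.codon_nt(first), t.codon_nt(last) + 3)
                    row["count_five_prime"] = _window_count(asites, span)
    return row


def _emit_reads(
    seqs_and_pos: list[tuple[str, np.ndarray]],
    lengths: np.ndarray,
) -> list[str]:
    """Slice insert sequences; order follows the concatenated position list."""
    reads: list[str] = []
    i = 0
    for seq, positions in seqs_and_pos:
        for p in positions:
            reads.append(seq[p:p + lengths[i]])
            i += 1
    return reads


def _sequencer_reads(inserts: list[str], adapter: str, cycles: int) -> list[str]:
    tail = adapter + "A" * cycles
    return [(ins + tail)[:cycles] for ins in inserts]


def simulate_sample_footprints(config: SimulationConfig, cond_index: int,
                               rep: int) -> SampleReads:
    """Generate one footprint library in memory."""
    cond = config.conditions[cond_index]
    sample_id = f"fp_{cond}_rep{rep}"
    rng = config.rng_for("fp", cond_index, rep)

    lens = np.array(sorted(config.length_dist))
    lprobs = np.array([config.length_dist[k] for k in lens], dtype=float)
    lprobs = lprobs / lprobs.sum()

    # per-codon weights and global scale so that the expected number of
    # mRNA-derived footprints is library_size * (1 - rrna_fraction)
    weights: list[tuple[TranscriptModel, np.ndarray, np.ndarray]] = []
    total_w = 0.0
    for t in config.transcripts:
        theta = float(config.abundance[t.gene][cond])
        codons = np.arange(1, t.stop_codon_index + 1)
        w = np.full(codons.shape, theta, dtype=float)
        if t.sec_codon_indices:
            rho = float(config.readthrough[t.gene][cond])
            w[codons > t.sec_codon_indices[0]] *= rho
        weights.append((t, codons, w))
        total_w += w.sum()
    if total_w <= 0:
        raise ValueError("all abundances are zero")
    scale = config.library_size * (1.0 - config.rrna_fraction) / total_w

    inserts: list[str] = []
    truth_rows = []
    per_tx_pos: list[tuple[str, np.ndarray]] = []
    n_total = 0
    for t, codons, w in weights:
        counts = rng.poisson(scale * w)
        asites = np.repeat(t.codon_nt(0) + 3 * (codons - 1) + 3, counts)
        # (codon_nt(c) written via codon 0 base to keep integer arithmetic)
        pos5 = asites - config.asite_offset
        n = pos5.size
        if n:
            off_frame = rng.random(n) >= config.phasing_fidelity
            jitter = np.where(rng.random(n) < 0.5, -1, 1) * off_frame
            pos5 = pos5 + jitter
        keep = pos5 >= 0
        pos5 = pos5[keep]
        per_tx_pos.append((t.sequence, pos5))
        n_total += pos5.size
        row = {"gene": t.gene, "transcript": t.id, "condition": cond,
               "replicate": rep, "sample": sample_id, "kind": "fp",
               "theta": float(config.abundance[t.gene][cond]),
               "rho": (float(config.readthrough[t.gene][cond])
                       if t.sec_codon_indices else np.nan),
               "n_reads": int(pos5.size)}
        row.update(_truth_row(t, asites))
        truth_rows.append(row)

    lengths = rng.choice(lens, size=n_total, p=lprobs)
    inserts = _emit_reads(per_tx_pos, lengths)

    # rRNA contaminants
    n_rrna = rng.poisson(config.library_size * config.rrna_fraction)
    rrna = synthetic_rrna()
    which = rng.integers(0, len(rrna), size=n_rrna)
    rlen = rng.choice(lens, size=n_rrna, p=lprobs)
    for i in range(n_rrna):
        seq = rrna[which[i]][1]
        p = rng.integers(0, len(seq) - int(rlen[i]) + 1)
        inserts.append(seq[p:p + int(rlen[i])])

    reads = _sequencer_reads(inserts, config.adapter, config.read_cycles)
    return SampleReads(sample_id, "fp", cond, rep, reads,
                       pd.DataFrame(truth_rows))


def simulate_sample_rnaseq(config: SimulationConfig, cond_index: int,
                           rep: int) -> SampleReads:
    """Generate one total-RNA library in memory."""
    cond = config.conditions[cond_index]
    sample_id = f"rna_{cond}_rep{rep}"
    rng = config.rng_for("rna", cond_index, rep)

    lens = np.array(sorted(config.length_dist))
    lprobs = np.array([config.length_dist[k] for k in lens], dtype=float)
    lprobs = lprobs / lprobs.sum()
    max_len = int(lens.max())

    total_w = sum(
        float(config.abundance[t.gene][cond]) * (t.length - max_len + 1)
        for t in config.transcripts)
    if total_w <= 0:
        raise ValueError("all abundances are zero")
    scale = config.library_size * (1.0 - config.rrna_fraction) / total_w

    per_tx_pos: list[tuple[str, np.ndarray]] = []
    truth_rows = []
    n_total = 0
    for t in config.transcripts:
        theta = float(config.abundance[t.gene][cond])
        npos = t.length - max_len + 1  # fragments lie fully inside
        counts = rng.poisson(scale * theta, size=npos)
        pos5 = np.repeat(np.arange(npos), counts)
        per_tx_pos.append((t.sequence, pos5))
        n_total += pos5.size
        asites = pos5 + config.asite_offset
        row = {"gene": t.gene, "transcript": t.id, "condition": cond,
               "replicate": rep, "sample": sample_id, "kind": "rna",
               "theta": theta, "rho": np.nan, "n_reads": int(pos5.size)}
        row.update(_truth_row(t, asites))
        truth_rows.append(row)

    lengths = rng.choice(lens, size=n_total, p=lprobs)
    inserts = _emit_reads(per_tx_pos, lengths)

    n_rrna = rng.poisson(config.library_size * config.rrna_fraction)
    rrna = synthetic_rrna()
    which = rng.integers(0, len(rrna), size=n_rrna)
    rlen = rng.choice(lens, size=n_rrna, p=lprobs)
    for i in range(n_rrna):
        seq = rrna[which[i]][1]
        p = rng.integers(0, len(seq) - int(rlen[i]) + 1)
        inserts.append(seq[p:p + int(rlen[i])])

    reads = _sequencer_reads(inserts, config.adapter, config.read_cycles)
    return SampleReads(sample_id, "rna", cond, rep, reads,
                       pd.DataFrame(truth_rows))


def _iter_samples(config: SimulationConfig, kind: str) -> Iterable[SampleReads]:
    sim = (simulate_sample_footprints if kind == "fp"
           else simulate_sample_rnaseq)
    for ci, _cond in enumerate(config.conditions):
        for rep in range(1, config.replicates + 1):
            yield sim(config, ci, rep)


def write_fastq(reads: Sequence[str], path: str | Path,
                sample_id: str) -> Path:
    """Write reads as gzipped FASTQ (constant base quality)."""
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{sample_id}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def simulate_footprints(config: SimulationConfig,
                        outdir: str | Path | None = None
                        ) -> tuple[list[SampleReads], pd.DataFrame]:
    """All footprint libraries of the design; optionally write FASTQ.

    Returns the in-memory samples and the concatenated SimTruth table.
    """
    config.validate()
    samples = list(_iter_samples(config, "fp"))
    truth = pd.concat([s.truth for s in samples], ignore_index=True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            write_fastq(s.reads, outdir / f"{s.sample_id}.fastq.gz",
                        s.sample_id)
        truth.to_csv(outdir / "sim_truth_fp.tsv", sep="\t", index=False)
    return samples, truth


def simulate_rnaseq(config: SimulationConfig,
                    outdir: str | Path | None = None
                    ) -> tuple[list[SampleReads], pd.DataFrame]:
    """All total-RNA libraries of the design; optionally write FASTQ."""
    config.validate()
    samples = list(_iter_samples(config, "rna"))
    truth = pd.concat([s.truth for s in samples], ignore_index=True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            write_fastq(s.reads, outdir / f"{s.sample_id}.fastq.gz",
                        s.sample_id)
        truth.to_csv(outdir / "sim_truth_rna.tsv", sep="\t", index=False)
    return samples, truth
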