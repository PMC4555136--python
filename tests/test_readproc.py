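import numpy as np
import pytest

from secribo.readproc import (
    AlignedRead,
    ReferenceIndex,
    align_unique,
    export_sam,
    filter_rrna,
    import_sam,
    trim_adapter,
)
from secribo.simulate import DEFAULT_ADAPTER, make_transcript, random_sequence

ADAPTER = DEFAULT_ADAPTER


class TestTrimAdapter:
    def test_full_adapter_after_insert(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTA"  # 29 nt
        read = (insert + ADAPTER + "A" * 50)[:50]
        assert trim_adapter(read, ADAPTER) == insert

    def test_no_adapter_unchanged(self):
        read = "ACGTACCGTAACGTACCGTAACGTACCGTA"
        assert trim_adapter(read, ADAPTER) == read

    def test_short_insert_discarded(self):
        read = ("ACGTACGT" + ADAPTER + "A" * 50)[:50]
        assert trim_adapter(read, ADAPTER) is None

    def test_partial_adapter_suffix(self):
        insert = "ACGTACCGTAACGTACCGTAT"
        read = insert + ADAPTER[:7]  # only 7 adapter nt sequenced
        assert trim_adapter(read, ADAPTER) == insert

    def test_suffix_below_min_overlap_kept(self):
        insert = "ACGTACCGTAACGTACCGTAT"
        read = insert + ADAPTER[:3]
        assert trim_adapter(read, ADAPTER) == read

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT" * 10, "")


class TestFilterRrna:
    def _rrna(self, rng):
        return [("rr1", random_sequence(rng, 500))]

    def test_exact_substring_removed(self, rng):
        rrna = self._rrna(rng)
        read = rrna[0][1][100:130]
        kept, removed = filter_rrna([read], rrna)
        assert removed == 1 and kept == []

    def test_two_mismatches_removed_three_retained(self, rng):
        rrna = self._rrna(rng)
        read = list(rrna[0][1][100:130])
        subs = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in (3, 11):
            read[i] = subs[read[i]]
        kept, removed = filter_rrna(["".join(read)], rrna)
        assert removed == 1
        read[20] = subs[read[20]]
        kept, removed = filter_rrna(["".join(read)], rrna)
        assert removed == 0 and len(kept) == 1

    def test_planted_contaminants_recounted(self, rng):
        rrna = self._rrna(rng)
        clean = [random_sequence(rng, 30) for _ in range(90)]
        planted = [rrna[0][1][i:i + 30] for i in range(10)]
        kept, removed = filter_rrna(clean + planted, rrna)
        assert removed == 10
        assert len(kept) == 90

    def test_missing_reference_is_config_error(self):
        with pytest.raises(ValueError):
            filter_rrna(["ACGT" * 8], [])


def _brute_force_unique(read, transcripts, max_mm=2):
    """Exhaustive all-position Hamming scan (independent oracle)."""
    hits = []
    arr_read = np.frombuffer(read.encode(), dtype=np.uint8)
    for t in transcripts:
        seq = np.frombuffer(t.sequence.encode(), dtype=np.uint8)
        if len(seq) < len(arr_read):
            continue
        win = np.lib.stride_tricks.sliding_window_view(seq, len(arr_read))
        mm = (win != arr_read).sum(axis=1)
        for p in np.nonzero(mm <= max_mm)[0]:
            hits.append((t.id, int(p), int(mm[p])))
    if not hits:
        return None
    best = min(h[2] for h in hits)
    stratum = [h for h in hits if h[2] == best]
    return stratum[0] if len(stratum) == 1 else "multi"


class TestAlignUnique:
    def test_single_exact_hit(self, rng):
        t = make_transcript(rng, "T1", "g1", 100)
        read = t.sequence[50:80]
        out, stats = align_unique([read], [t])
        assert stats.n_aligned == 1
        assert out[0] == AlignedRead("T1", 50, 30, 0, "sample")

    def test_read_matching_two_transcripts_dropped(self, rng):
        t1 = make_transcript(rng, "T1", "g1", 100)
        t2 = make_transcript(rng, "T2", "g2", 100)
        shared = t1.sequence[10:40]
        t2 = type(t2)(t2.id, t2.gene, shared + t2.sequence[30:], t2.cds_start,
                      t2.cds_end, t2.sec_codon_indices)
        out, stats = align_unique([shared], [t1, t2])
        assert stats.n_multi == 1 and out == []

    def test_matches_bruteforce_on_random_reads(self, rng):
        transcripts = [make_transcript(rng, f"T{i}", f"g{i}",
                                       int(rng.integers(80, 200)))
                       for i in range(5)]
        reads = []
        subs = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for _ in range(500):
            t = transcripts[int(rng.integers(0, 5))]
            ln = int(rng.integers(26, 37))
            p = int(rng.integers(0, t.length - ln + 1))
            read = list(t.sequence[p:p + ln])
            for i in rng.choice(ln, size=int(rng.integers(0, 4)),
                                replace=False):
                read[i] = subs[read[i]]
            reads.append("".join(read))
        out, stats = align_unique(reads, transcripts)
        got = {}
        for a in out:
            got.setdefault((a.transcript_id, a.pos5, a.length,
                            a.mismatches), 0)
            got[(a.transcript_id, a.pos5, a.length, a.mismatches)] += 1
        expect = {}
        n_multi = n_unaligned = 0
        for read in reads:
            res = _brute_force_unique(read, transcripts)
            if res is None:
                n_unaligned += 1
            elif res == "multi":
                n_multi += 1
            else:
                key = (res[0], res[1], len(read), res[2])
                expect[key] = expect.get(key, 0) + 1
        assert got == expect
        assert stats.n_multi == n_multi
        assert stats.n_unaligned == n_unaligned

    def test_order_invariance(self, rng):
        t = make_transcript(rng, "T1", "g1", 200)
        reads = [t.sequence[int(p):int(p) + 30]
                 for p in rng.integers(0, t.length - 30, size=50)]
        out1, _ = align_unique(list(reads), [t])
        out2, _ = align_unique(list(reversed(reads)), [t])
        assert out1 == out2

    def test_count_conservation(self, rng):
        t = make_transcript(rng, "T1", "g1", 100)
        reads = [t.sequence[10:40], "A" * 30, t.sequence[20:50]]
        _, stats = align_unique(reads, [t])
        assert stats.conserved()

    def test_footprint_length_filter(self, rng):
        t = make_transcript(rng, "T1", "g1", 100)
        reads = [t.sequence[10:35], t.sequence[10:40]]  # 25 nt and 30 nt
        out, stats = align_unique(reads, [t], length_range=(26, 36))
        assert stats.n_aligned == 1 and stats.n_unaligned == 1


def test_sam_roundtrip(tmp_path, rng):
    transcripts = [make_transcript(rng, f"T{i}", f"g{i}", 120)
                   for i in range(3)]
    alignments = [AlignedRead("T0", 5, 30, 0, "s"),
                  AlignedRead("T1", 17, 28, 1, "s"),
                  AlignedRead("T2", 40, 33, 0, "s")]
    path = tmp_path / "aln.sam"
    export_sam(alignments, transcripts, path)
    back = import_sam(path, transcripts, sample_id="s")
    assert [(a.transcript_id, a.pos5, a.length, a.mismatches)
            for a in back] == \
           [(a.transcript_id, a.pos5, a.length, a.mismatches)
            for a in alignments]


def test_sam_header_mismatch_rejected(tmp_path, rng):
    transcripts = [make_transcript(rng, "T0", "g0", 120)]
    export_sam([AlignedRead("T0", 5, 30, 0, "s")], transcripts,
               tmp_path / "a.sam")
    other = [make_transcript(rng, "T0", "g0", 130)]
    with pytest.raises(ValueError):
        import_sam(tmp_path / "a.sam", other)


def test_reference_index_min_stratum(rng):
    t = make_transcript(rng, "T1", "g1", 100)
    idx = ReferenceIndex.from_transcripts([t])
    read = t.sequence[10:40]
    stratum, hits = idx.find_all(read)
    assert stratum == 0 and hits == [(0, 10)]
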