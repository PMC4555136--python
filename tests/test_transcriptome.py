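import io

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secribo.transcriptome import (
    CodonWindow,
    NotAnalyzableError,
    TranscriptModel,
    load_transcripts,
    make_cds_core_window,
    make_sec_windows,
    reduce_to_longest_isoform,
    windows_table,
)


def _fasta(records):
    return io.StringIO("".join(f">{rid}\n{seq}\n" for rid, seq in records))


def _ann(rows):
    return pd.DataFrame(rows, columns=["accession", "gene", "cds_start",
                                       "cds_end", "sec_codon_indices"])


class TestLoadTranscripts:
    def test_valid_record_with_sec_codon(self):
        # CDS 0..33 (11 codons), UGA at codon 5
        cds = "ATG" + "GCT" * 4 + "TGA" + "GCT" * 4 + "TAA"
        fasta = _fasta([("ACC1", cds)])
        models, rejected = load_transcripts(
            fasta, _ann([("ACC1", "geneA", 0, 33, "5")]))
        assert rejected == []
        (m,) = models
        assert m.sec_codon_indices == (5,)
        assert m.n_codons == 11

    def test_sec_codon_not_uga_rejected_with_name(self):
        cds = "ATG" + "GCT" * 4 + "TAA" + "GCT" * 4 + "TAA"
        models, rejected = load_transcripts(
            _fasta([("BAD1", cds)]), _ann([("BAD1", "g", 0, 33, "5")]))
        assert models == []
        ((rid, reason),) = rejected
        assert rid == "BAD1" and "not UGA" in reason

    def test_cds_not_multiple_of_three_rejected(self):
        seq = "ATG" + "GCTG"
        models, rejected = load_transcripts(
            _fasta([("BAD2", seq)]), _ann([("BAD2", "g", 0, 7, "")]))
        assert models == [] and rejected[0][0] == "BAD2"

    def test_strict_mode_raises(self):
        seq = "ATGGCTG"
        with pytest.raises(Exception):
            load_transcripts(_fasta([("BAD2", seq)]),
                             _ann([("BAD2", "g", 0, 7, "")]), strict=True)

    def test_u_normalized_to_t(self):
        cds = "AUG" + "GCU" * 4 + "UGA" + "GCU" * 4 + "UAA"
        models, rejected = load_transcripts(
            _fasta([("ACC2", cds)]), _ann([("ACC2", "g", 0, 33, "5")]))
        assert rejected == [] and models[0].codon(5) == "TGA"


class TestLongestIsoform:
    def _rec(self, acc, gene, n):
        return TranscriptModel(acc, gene, "A" * n, 0, 3, ())

    def test_longest_retained(self):
        out = reduce_to_longest_isoform(
            [self._rec("a1", "geneX", 900), self._rec("a2", "geneX", 1200)])
        assert [r.id for r in out] == ["a2"]

    def test_single_isoform_unchanged(self):
        recs = [self._rec("a1", "geneY", 500)]
        assert reduce_to_longest_isoform(recs) == recs

    def test_matches_bruteforce_groupwise_max(self, rng):
        recs = []
        for g in range(10):
            for i in range(int(rng.integers(1, 5))):
                recs.append(self._rec(f"g{g}i{i}", f"gene{g}",
                                      int(rng.integers(100, 2000))))
        out = reduce_to_longest_isoform(recs)
        # brute force: per gene, max length, ties to smallest accession
        expect = {}
        for r in recs:
            cur = expect.get(r.gene)
            if cur is None or (r.length, [-ord(c) for c in r.id]) > \
                    (cur.length, [-ord(c) for c in cur.id]):
                expect[r.gene] = r
        assert {r.gene: r.id for r in out} == \
               {g: r.id for g, r in expect.items()}

    def test_idempotent(self, rng):
        recs = [self._rec(f"a{i}", f"gene{i%3}", int(rng.integers(50, 500)))
                for i in range(9)]
        once = reduce_to_longest_isoform(recs)
        assert reduce_to_longest_isoform(once) == once


class TestWindows:
    def _tx(self, n_codons, sec=()):
        seq = ["N"] * (3 * n_codons)
        for s in sec:
            seq[3 * s:3 * s + 3] = "TGA"
        # replace N with A except planted TGA, keep valid alphabet
        seq = "".join(c if c != "N" else "A" for c in seq)
        return TranscriptModel("t", "g", seq, 0, 3 * n_codons, tuple(sec))

    def test_cds_core_100_codons(self):
        w = make_cds_core_window(self._tx(100))
        assert (w.first_codon, w.last_codon) == (15, 96)

    def test_cds_core_boundary_19_and_18(self):
        w = make_cds_core_window(self._tx(19))
        assert (w.first_codon, w.last_codon) == (15, 15)
        with pytest.raises(NotAnalyzableError):
            make_cds_core_window(self._tx(18))

    def test_sec_windows_canonical(self):
        t = self._tx(202, sec=(46,))  # stop at codon 201
        five, three = make_sec_windows(t)
        assert (five.first_codon, five.last_codon) == (15, 40)
        assert (three.first_codon, three.last_codon) == (48, 198)

    def test_c_terminal_sec_not_analyzable_downstream(self):
        t = self._tx(200, sec=(198,))  # last sense codon
        with pytest.raises(NotAnalyzableError) as exc:
            make_sec_windows(t)
        assert exc.value.side == "three_prime"

    def test_early_sec_not_analyzable_upstream(self):
        t = self._tx(200, sec=(18,))
        with pytest.raises(NotAnalyzableError) as exc:
            make_sec_windows(t)
        assert exc.value.side == "five_prime"

    def test_which_sec_selects_codon(self):
        t = self._tx(300, sec=(50, 200))
        five_a, three_a = make_sec_windows(t)          # default: first
        five_b, three_b = make_sec_windows(t, which_sec=200)
        assert three_a.first_codon == 52
        assert (five_b.last_codon, three_b.first_codon) == (194, 202)

    @given(n_codons=st.integers(25, 500), sec_frac=st.floats(0.05, 0.95))
    @settings(max_examples=60, deadline=None)
    def test_windows_never_overlap_sec_or_each_other(self, n_codons,
                                                     sec_frac):
        sec = max(1, min(n_codons - 2, int(sec_frac * n_codons)))
        t = self._tx(n_codons, sec=(sec,))
        try:
            five, three = make_sec_windows(t)
        except NotAnalyzableError:
            return
        assert five.last_codon < sec < three.first_codon
        s5 = five.nt_span(t)
        s3 = three.nt_span(t)
        assert s5[1] <= s3[0]
        for s, e in (s5, s3):
            assert t.cds_start <= s < e <= t.cds_end
        sec_nt = t.codon_nt(sec)
        assert not (s5[0] <= sec_nt < s5[1])
        assert not (s3[0] <= sec_nt < s3[1])

    def test_windows_table_marks_unanalyzable(self, rng):
        from secribo.simulate import make_transcript
        t1 = make_transcript(rng, "A1", "g1", 100, (40,))
        t2 = make_transcript(rng, "A2", "g2", 100, (98,))  # C-terminal
        tab = windows_table([t1, t2])
        row = tab[(tab.transcript == "A2") &
                  (tab.label == "three_prime_of_sec")]
        assert (row["start"] == -1).all()
        row5 = tab[(tab.transcript == "A2") &
                   (tab.label == "five_prime_of_sec")]
        assert (row5["start"] >= 0).all()


def test_codon_window_rejects_empty_interval():
    with pytest.raises(ValueError):
        CodonWindow("t", 5, 4, "cds_core")
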