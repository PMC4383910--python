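"""Seeded local alignment vs the exact dynamic-programming oracle."""

import logging

import numpy as np
import pytest

from tdna_islands import (
    FragmentHit,
    Interval,
    Replicon,
    TdnaGene,
    classify_fragment_side,
    find_fragment_hits,
    local_align_oracle,
    search_sequences,
)
from tdna_islands.search import revcomp
from tdna_islands.simulate import TEMPLATES


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestOracle:
    def test_perfect_match(self, config):
        score, a_span, b_span = local_align_oracle("ACGT", "ACGT", config)
        assert score == 8.0
        assert a_span == (0, 4) and b_span == (0, 4)

    def test_no_positive_cell(self, config):
        assert local_align_oracle("AAAA", "TTTT", config)[0] == 0.0

    def test_single_insertion_costs_one_gap_extend_unit(self, config):
        # 8 matches minus a 1-residue gap (0 open + 1 * 2.5 extend)
        score, _, _ = local_align_oracle("ACGTACGT", "ACGTTACGT", config)
        assert score == pytest.approx(13.5)

    def test_empty_input(self, config):
        assert local_align_oracle("", "ACGT", config) == (0.0, (0, 0), (0, 0))


class TestSearchSequences:
    def test_planted_tail_copy_recovered(self, config):
        rng = np.random.default_rng(5)
        q = TEMPLATES[0]
        L = len(q)
        subject = q + _rand(rng, 5000) + "NNNN" + q[L - 20:]
        hits = search_sequences(q, subject, config)
        tail = [h for h in hits if h.sstart == L + 5004]
        assert len(tail) == 1
        h = tail[0]
        assert (h.qstart, h.qend) == (L - 20, L)
        assert h.identities == 20 and h.score == 40.0

    def test_minus_strand_hit_mirrored_query_span(self, config):
        rng = np.random.default_rng(6)
        q = TEMPLATES[1]
        subject = _rand(rng, 1000) + "NNNN" + revcomp(q[40:]) + "NNNN" + _rand(rng, 300)
        hits = [h for h in search_sequences(q, subject, config) if h.strand == "-"]
        assert hits and (hits[0].qstart, hits[0].qend) == (40, len(q))

    def test_score_never_exceeds_oracle(self, config):
        rng = np.random.default_rng(7)
        for _ in range(25):
            q = _rand(rng, int(rng.integers(30, 100)))
            s = _rand(rng, int(rng.integers(200, 800)))
            best = max((h.score for h in search_sequences(q, s, config)), default=0.0)
            oracle, _, _ = local_align_oracle(q, s, config)
            rc_oracle, _, _ = local_align_oracle(revcomp(q), s, config)
            assert best <= max(oracle, rc_oracle) + 1e-9

    def test_seeded_score_equals_oracle_on_planted_mutated_copies(self, config):
        rng = np.random.default_rng(8)
        for _ in range(60):
            n = int(rng.integers(40, 121))
            q = _rand(rng, n)
            copy = list(q[int(rng.integers(0, n // 3)): int(rng.integers(2 * n // 3, n))])
            for i in range(len(copy)):
                if rng.random() < 0.08:
                    copy[i] = "ACGT"[int(rng.integers(4))]
            s = _rand(rng, int(rng.integers(100, 1200))) + "".join(copy) + _rand(rng, 300)
            hits = search_sequences(q, s, config)
            oracle, _, _ = local_align_oracle(q, s, config)
            if hits:
                assert max(h.score for h in hits) == pytest.approx(oracle)


class TestFindFragmentHits:
    def _gene(self, iv, strand="+"):
        return TdnaGene("t1", "r", iv, strand, "tRNA", "S")

    def test_self_hit_removed(self, config):
        rep = Replicon(id="r", sequence=TEMPLATES[0])
        gene = self._gene(Interval(0, len(TEMPLATES[0])))
        assert find_fragment_hits(gene, rep, config) == []

    def test_query_shorter_than_word_size_warns(self, config, caplog):
        rep = Replicon(id="r", sequence="ACGTA" + "T" * 100)
        gene = self._gene(Interval(0, 5))
        with caplog.at_level(logging.WARNING):
            assert find_fragment_hits(gene, rep, config) == []
        assert any("word_size" in r.message for r in caplog.records)

    def test_reverse_complement_symmetry(self, config):
        rng = np.random.default_rng(9)
        q = TEMPLATES[2]
        L = 76
        seq = q + _rand(rng, 3000) + q[40:] + _rand(rng, 500)
        n = len(seq)
        rep_f = Replicon(id="r", sequence=seq)
        gene_f = self._gene(Interval(0, L), "+")
        rep_r = Replicon(id="r", sequence=revcomp(seq))
        gene_r = self._gene(Interval(n - L, n), "-")
        hits_f = find_fragment_hits(gene_f, rep_f, config)
        hits_r = find_fragment_hits(gene_r, rep_r, config)
        mirrored = sorted(
            (n - h.subject_interval.end, n - h.subject_interval.start,
             h.query_span, h.score)
            for h in hits_r
        )
        direct = sorted(
            (h.subject_interval.start, h.subject_interval.end, h.query_span, h.score)
            for h in hits_f
        )
        assert direct == mirrored

    def test_circular_hit_across_origin(self, config):
        rng = np.random.default_rng(10)
        q = TEMPLATES[3]
        frag = q[50:]  # 26 nt
        # place fragment straddling the origin: last 13 nt at the end, rest at start
        seq = frag[13:] + "NNNN" + _rand(rng, 2000) + q + _rand(rng, 1000) + "NNNN" + frag[:13]
        n = len(seq)
        rep = Replicon(id="r", sequence=seq, topology="circular")
        gene = self._gene(Interval(2017, 2017 + 76))
        hits = find_fragment_hits(gene, rep, config)
        wrap = [h for h in hits if h.subject_interval.wraps]
        assert wrap and wrap[0].subject_interval == Interval(n - 13, 13)
        assert wrap[0].query_span == (50, 76)


class TestClassifySide:
    def _hit(self, span):
        return FragmentHit(
            tdna_id="t1", subject_interval=Interval(1000, 1040),
            subject_strand="+", query_span=span, score=40.0, identities=20,
        )

    def _gene(self):
        return TdnaGene("t1", "r", Interval(0, 76), "+", "tRNA", "S")

    @pytest.mark.parametrize(
        "span,side,damaged",
        [
            ((0, 35), "five_prime", False),
            ((40, 76), "three_prime", False),
            ((40, 73), "three_prime", True),  # ends at the tolerated deletion site
            ((40, 72), "internal", False),
            ((20, 60), "internal", False),
        ],
    )
    def test_side_and_damage(self, config, span, side, damaged):
        h = classify_fragment_side(self._hit(span), self._gene(), config, 76)
        assert (h.side, h.damaged) == (side, damaged)
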