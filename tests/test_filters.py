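"""Candidate construction and the seven-filter cascade."""

import itertools
import logging

import pytest

from tdna_islands import (
    CascadeContext,
    DomainCall,
    FragmentHit,
    IntegraseCall,
    Interval,
    Replicon,
    TdnaGene,
    build_candidate,
    classify_subsite,
    run_cascade,
)
from tdna_islands.candidates import FILTERS
from tdna_islands.model import FILTER_ORDER


def _gene(iv=Interval(1000, 1076), strand="+", kind="tRNA", isotype="S"):
    return TdnaGene("t1", "r", iv, strand, kind, isotype)


def _hit(iv, strand="+", span=(40, 76), score=40.0, side=None, damaged=False):
    h = FragmentHit(
        tdna_id="t1", subject_interval=iv, subject_strand=strand,
        query_span=span, score=score, identities=span[1] - span[0],
    )
    if side is not None:
        h.side = side
    h.damaged = damaged
    return h


def _rep(n=300000, topology="linear"):
    return Replicon(id="r", sequence="A" * n, topology=topology)


def _ig(iv, sub="generic"):
    return IntegraseCall("ig", "r", iv, "+", sub)


class TestBuildCandidate:
    def test_downstream_arithmetic(self):
        c = build_candidate(_gene(), _hit(Interval(6076, 6096)), _rep())
        assert c.island_interval == Interval(1076, 6096)
        assert c.length == 5020
        assert c.fragment_downstream

    def test_upstream_fragment(self):
        c = build_candidate(_gene(), _hit(Interval(100, 130)), _rep())
        assert c.island_interval == Interval(100, 1000)
        assert c.length == 900
        assert not c.fragment_downstream

    def test_minus_strand_mirror(self):
        n = 10000
        # mirror of the downstream case on a genome of length n
        gene = _gene(Interval(n - 1076, n - 1000), strand="-")
        c = build_candidate(gene, _hit(Interval(n - 6096, n - 6076)), _rep(n))
        assert c.island_interval == Interval(n - 6096, n - 1076)
        assert c.length == 5020
        assert c.fragment_downstream  # still downstream in gene orientation

    def test_circular_shorter_arc_wraps(self):
        rep = _rep(20000, "circular")
        gene = _gene(Interval(18000, 18076))
        c = build_candidate(gene, _hit(Interval(2000, 2020)), rep)
        assert c.island_interval == Interval(18076, 2020)
        assert c.island_interval.wraps
        assert c.length == (2020 - 18076) % 20000
        assert c.length < 20000

    def test_fragment_overlapping_tdna_rejected(self):
        with pytest.raises(ValueError, match="self-hit"):
            build_candidate(_gene(), _hit(Interval(1050, 1090)), _rep())


def _ctx(integrases=(), domains=(), tdnas=(), rep=None, config=None):
    rep = rep or _rep()
    from tdna_islands import PipelineConfig

    return CascadeContext(
        replicon=rep,
        tdnas=list(tdnas) or [_gene()],
        integrases=list(integrases),
        domains=list(domains),
        config=config or PipelineConfig(),
    )


def _cand(hit=None, gene=None, rep=None):
    gene = gene or _gene()
    hit = hit or _hit(Interval(6076, 6096), side="three_prime")
    return build_candidate(gene, hit, rep or _rep())


class TestIntegraseFilter:
    def test_integrase_inside_island_passes(self):
        c = _cand()
        assert FILTERS["integrase"](c, _ctx([_ig(Interval(3000, 4000))]))
        assert c.integrases_within

    def test_integrase_straddling_boundary_passes(self):
        c = _cand()
        assert FILTERS["integrase"](c, _ctx([_ig(Interval(6090, 6200))]))

    def test_no_integrase_fails(self):
        assert not FILTERS["integrase"](_cand(), _ctx([_ig(Interval(250000, 251000))]))


class TestCdsFilter:
    def test_fragment_in_noninteg_domain_fails(self):
        dom = DomainCall("PF00005", "r", Interval(6070, 6100), "+", False)
        assert not FILTERS["cds"](_cand(), _ctx(domains=[dom]))

    def test_fragment_in_integrase_domain_passes(self):
        dom = DomainCall("PF00589", "r", Interval(6070, 6100), "+", True)
        assert FILTERS["cds"](_cand(), _ctx(domains=[dom]))

    def test_tdna_in_noninteg_domain_fails(self):
        dom = DomainCall("PF00005", "r", Interval(1040, 1100), "+", False)
        assert not FILTERS["cds"](_cand(), _ctx(domains=[dom]))

    def test_no_domain_overlap_passes(self):
        dom = DomainCall("PF00005", "r", Interval(50000, 50100), "+", False)
        assert FILTERS["cds"](_cand(), _ctx(domains=[dom]))


class TestTdnaFilter:
    def test_hit_contained_in_other_tdna_fails(self):
        other = TdnaGene("t2", "r", Interval(6070, 6146), "+", "tRNA", "S")
        c = _cand()
        assert not FILTERS["tdna"](c, _ctx(tdnas=[_gene(), other]))

    def test_hit_overlapping_but_not_contained_passes(self):
        other = TdnaGene("t2", "r", Interval(6090, 6166), "+", "tRNA", "S")
        assert FILTERS["tdna"](_cand(), _ctx(tdnas=[_gene(), other]))

    def test_intergenic_hit_passes(self):
        assert FILTERS["tdna"](_cand(), _ctx(tdnas=[_gene()]))


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,ok",
        [(1999, False), (2000, True), (200000, True), (200001, False), (611000, False)],
    )
    def test_bounds(self, length, ok):
        c = _cand(hit=_hit(Interval(1076 + length - 20, 1076 + length)))
        assert c.length == length
        assert FILTERS["length"](c, _ctx()) == ok


class TestGeometryFilters:
    def test_internal_fragment_fails_internal_filter(self):
        c = _cand(hit=_hit(Interval(6076, 6096), span=(20, 60), side="internal"))
        assert not FILTERS["internal"](c, _ctx())

    def test_damaged_three_prime_passes_internal_filter(self):
        c = _cand(hit=_hit(Interval(6076, 6096), span=(53, 73), side="three_prime",
                           damaged=True))
        assert FILTERS["internal"](c, _ctx())

    def test_three_prime_downstream_passes_configuration(self):
        c = _cand(hit=_hit(Interval(6076, 6096), side="three_prime"))
        assert FILTERS["configuration"](c, _ctx())

    def test_five_prime_downstream_fails_configuration(self):
        c = _cand(hit=_hit(Interval(6076, 6096), span=(0, 20), side="five_prime"))
        assert not FILTERS["configuration"](c, _ctx())

    def test_three_prime_upstream_fails_configuration(self):
        c = _cand(hit=_hit(Interval(100, 120), side="three_prime"))
        assert not FILTERS["configuration"](c, _ctx())

    def test_five_prime_upstream_passes_configuration(self):
        c = _cand(hit=_hit(Interval(100, 120), span=(0, 20), side="five_prime"))
        assert FILTERS["configuration"](c, _ctx())

    def test_internal_side_defers_to_internal_filter(self):
        c = _cand(hit=_hit(Interval(6076, 6096), span=(20, 60), side="internal"))
        assert FILTERS["configuration"](c, _ctx())

    def test_orientation(self):
        same = _cand(hit=_hit(Interval(6076, 6096), strand="+", side="three_prime"))
        opp = _cand(hit=_hit(Interval(6076, 6096), strand="-", side="three_prime"))
        assert FILTERS["orientation"](same, _ctx())
        assert not FILTERS["orientation"](opp, _ctx())


class TestSubsite:
    def test_mid_gene_crossover_is_anticodon_subsite(self, config):
        c = _cand(hit=_hit(Interval(6076, 6110), span=(34, 76), side="three_prime"))
        assert classify_subsite(c, config) == "A"

    def test_late_crossover_is_junction_subsite(self, config):
        c = _cand(hit=_hit(Interval(6076, 6090), span=(64, 76), side="three_prime"))
        assert classify_subsite(c, config) == "J"

    def test_early_crossover_called_j_with_warning(self, config, caplog):
        c = _cand(hit=_hit(Interval(6076, 6140), span=(12, 76), side="three_prime"))
        with caplog.at_level(logging.WARNING):
            assert classify_subsite(c, config) == "J"
        assert any("acceptor" in r.message for r in caplog.records)

    def test_tmrna_target_is_na(self, config):
        gene = _gene(kind="tmRNA", isotype="tmRNA")
        c = _cand(gene=gene, hit=_hit(Interval(6076, 6110), span=(34, 76),
                                      side="three_prime"))
        assert classify_subsite(c, config) == "NA"

    def test_five_prime_crossover_is_query_end(self, config):
        c = _cand(hit=_hit(Interval(100, 138), span=(0, 38), side="five_prime"))
        assert classify_subsite(c, config) == "A"


class TestCascade:
    def test_empty_input(self):
        survivors, trace = run_cascade([], _ctx())
        assert survivors == []
        assert all(trace.entering[n] == 0 for n in FILTER_ORDER)

    def test_canonical_candidate_survives_all_filters(self):
        ig = _ig(Interval(3000, 4000))
        c = _cand(hit=_hit(Interval(6076, 6096), span=(56, 76), side="three_prime"))
        survivors, trace = run_cascade([c], _ctx([ig]))
        assert survivors == [c]
        assert all(v == "pass" for v in c.filter_trace.values())
        assert c.subsite in ("A", "J")

    def test_short_circuit_marks_not_evaluated(self):
        c = _cand()  # no integrase in context -> fails first filter
        _, _ = run_cascade([c], _ctx())
        assert c.filter_trace["integrase"] == "fail"
        assert c.filter_trace["orientation"] == "not-evaluated"

    def test_trace_counts_are_conserved(self):
        ig = _ig(Interval(3000, 4000))
        cands = [
            _cand(hit=_hit(Interval(6076, 6096), span=(56, 76), side="three_prime")),
            _cand(hit=_hit(Interval(6076, 6096), strand="-", span=(56, 76),
                           side="three_prime")),
            _cand(),  # internal side default
        ]
        survivors, trace = run_cascade(cands, _ctx([ig]))
        for a, b in zip(FILTER_ORDER, FILTER_ORDER[1:]):
            assert trace.entering[b] == trace.entering[a] - trace.rejected[a]
        assert trace.entering[FILTER_ORDER[0]] == 3

    def test_accepted_set_is_filter_order_independent(self):
        ig = _ig(Interval(3000, 4000))
        ctx = _ctx([ig])
        cands = [
            _cand(hit=_hit(Interval(6076, 6096), span=(56, 76), side="three_prime")),
            _cand(hit=_hit(Interval(6076, 6096), strand="-", span=(56, 76),
                           side="three_prime")),
            _cand(hit=_hit(Interval(6076, 6096), span=(20, 60), side="internal")),
            _cand(hit=_hit(Interval(100, 120), span=(56, 76), side="three_prime")),
            _cand(hit=_hit(Interval(1076 + 1900 - 20, 1076 + 1900),
                           span=(56, 76), side="three_prime")),
        ]
        baseline = {
            id(c) for c in cands
            if all(FILTERS[n](c, ctx) for n in FILTER_ORDER)
        }
        for order in itertools.islice(itertools.permutations(FILTER_ORDER), 0, 500, 71):
            surviving = {
                id(c) for c in cands if all(FILTERS[n](c, ctx) for n in order)
            }
            assert surviving == baseline
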