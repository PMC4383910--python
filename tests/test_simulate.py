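"""The synthetic-genome generator: determinism, truth exactness, decoys."""

import numpy as np
import pytest

from tdna_islands import PlantSpec, SyntheticPlan, generate, truth_compare
from tdna_islands.intervals import Interval, mirror
from tdna_islands.pipeline import run_replicon
from tdna_islands.search import revcomp
from tdna_islands.simulate import (
    DECOY_KINDS,
    DESIGNED_FILTER,
    TEMPLATES,
    filter_suite_plan,
)


def _kmers(s, k=7):
    return {s[i: i + k] for i in range(len(s) - k + 1)}


class TestTemplates:
    def test_pairwise_disjoint_word_vocabularies(self):
        vocab = []
        for t in TEMPLATES:
            assert len(t) == 76
            assert set(t) <= set("ACGT")
            ks = _kmers(t) | _kmers(revcomp(t))
            assert not (_kmers(t) & _kmers(revcomp(t)))
            vocab.append(ks)
        for i in range(len(vocab)):
            for j in range(i + 1, len(vocab)):
                assert not (vocab[i] & vocab[j])


class TestGenerate:
    def test_same_seed_is_byte_identical(self):
        plan = filter_suite_plan(5)
        a = generate(plan)
        b = generate(filter_suite_plan(5))
        assert a.replicon.sequence == b.replicon.sequence
        assert [
            (t.interval, t.tandem_index) for t in a.truth.expected_islands
        ] == [(t.interval, t.tandem_index) for t in b.truth.expected_islands]

    def test_different_seed_differs(self):
        a = generate(filter_suite_plan(5))
        b = generate(filter_suite_plan(6))
        assert a.replicon.sequence != b.replicon.sequence

    def test_infeasible_plans_rejected_before_output(self):
        with pytest.raises(ValueError, match="crossover"):
            generate(SyntheticPlan(seed=1, plants=[PlantSpec(crossover=80)]))
        with pytest.raises(ValueError, match="island_length"):
            generate(SyntheticPlan(seed=1, plants=[PlantSpec(island_length=600)]))
        with pytest.raises(ValueError, match="replicon_length"):
            generate(
                SyntheticPlan(
                    seed=1, plants=[PlantSpec()], replicon_length=5000
                )
            )

    def test_canonical_plant_recovered_end_to_end(self, config):
        plan = SyntheticPlan(
            seed=2,
            plants=[PlantSpec(kind="canonical_island", island_length=10000,
                              crossover=53)],
        )
        data = generate(plan)
        res = run_replicon(
            data.replicon, data.tdnas, data.integrases, data.domains, config
        )
        truth = data.truth.expected_islands[0]
        assert len(res.islands) == 1
        assert res.islands[0].interval == truth.interval
        assert res.islands[0].length == 10000
        assert res.islands[0].subsite == truth.subsite == "J"

    def test_decoy_only_plan_yields_zero_islands(self, config):
        plan = SyntheticPlan(
            seed=3,
            plants=[
                PlantSpec(
                    kind=k,
                    island_length=(
                        201000 if k == "decoy_long"
                        else 1500 if k == "decoy_short" else 4000
                    ),
                    crossover=45,
                )
                for k in DECOY_KINDS
            ],
        )
        data = generate(plan)
        res = run_replicon(
            data.replicon, data.tdnas, data.integrases, data.domains, config,
            evaluate_all=True,
        )
        assert res.islands == []
        cmp_ = truth_compare(
            res.islands, data.truth, candidates=res.candidates,
            replicon_length=len(data.replicon),
        )
        assert cmp_.all_decoys_rejected_at_designed_filter
        by_kind = {r.kind: r for r in cmp_.decoy_reports}
        assert set(by_kind) == set(DECOY_KINDS)
        for kind, rep in by_kind.items():
            assert rep.failed_filters == (DESIGNED_FILTER[kind],)

    def test_tandem_array_depth_three(self, config):
        plan = SyntheticPlan(
            seed=4,
            plants=[PlantSpec(kind="tandem_array", island_length=3000,
                              crossover=53, array_size=3)],
        )
        data = generate(plan)
        res = run_replicon(
            data.replicon, data.tdnas, data.integrases, data.domains, config
        )
        assert [i.tandem_index for i in res.islands] == [(1, 3), (2, 3), (3, 3)]
        got = {(i.interval.start, i.interval.end) for i in res.islands}
        want = {
            (t.interval.start, t.interval.end) for t in data.truth.expected_islands
        }
        assert got == want

    def test_rotation_invariance_of_recovery(self, config):
        for rot in (0, 1, 4321, 11111):
            plan = SyntheticPlan(
                seed=6,
                plants=[
                    PlantSpec(kind="canonical_island", island_length=6000,
                              crossover=38),
                    PlantSpec(kind="decoy_no_integrase", island_length=4000,
                              crossover=45),
                ],
                topology="circular",
                rotation=rot,
            )
            data = generate(plan)
            res = run_replicon(
                data.replicon, data.tdnas, data.integrases, data.domains, config
            )
            cmp_ = truth_compare(res.islands, data.truth)
            assert cmp_.exact_endpoint_recall == 1.0
            assert cmp_.precision == 1.0

    def test_reverse_complement_invariance_of_recovery(self, config):
        plan = SyntheticPlan(
            seed=7,
            plants=[PlantSpec(kind="canonical_island", island_length=8000,
                              crossover=34)],
        )
        data = generate(plan)
        n = len(data.replicon)
        # mirror the whole dataset
        rc_rep = type(data.replicon)(
            id=data.replicon.id, sequence=revcomp(data.replicon.sequence),
            topology=data.replicon.topology, organism=data.replicon.organism,
        )
        for g in data.tdnas:
            g.interval = mirror(g.interval, n)
            g.strand = "-" if g.strand == "+" else "+"
        for ig in data.integrases:
            ig.orf_interval = mirror(ig.orf_interval, n)
            ig.strand = "-" if ig.strand == "+" else "+"
        for d in data.domains:
            d.dna_interval = mirror(d.dna_interval, n)
            d.strand = "-" if d.strand == "+" else "+"
        res = run_replicon(rc_rep, data.tdnas, data.integrases, data.domains, config)
        truth_mirrored = {
            (mirror(t.interval, n).start, mirror(t.interval, n).end)
            for t in data.truth.expected_islands
        }
        got = {(i.interval.start, i.interval.end) for i in res.islands}
        assert got == truth_mirrored


class TestTruthCompare:
    def test_off_by_one_endpoint_counts_as_miss(self, config):
        plan = SyntheticPlan(
            seed=8,
            plants=[PlantSpec(kind="canonical_island", island_length=5000,
                              crossover=38)],
        )
        data = generate(plan)
        res = run_replicon(
            data.replicon, data.tdnas, data.integrases, data.domains, config
        )
        isl = res.islands[0]
        isl.interval = Interval(isl.interval.start + 1, isl.interval.end)
        cmp_ = truth_compare(res.islands, data.truth)
        assert cmp_.exact_endpoint_recall == 0.0
        assert cmp_.precision == 0.0
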