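"""AMOVA variance components, fixed-partition evaluation, and SAMOVA search."""

import math

import numpy as np
import pytest

from haplogeo import bretschneidera
from haplogeo.model import (
    Dataset,
    Haplotype,
    HaplotypeMatrix,
    MutationSite,
    Population,
)
from haplogeo.simulate import GeneratorConfig, generate
from haplogeo.structure import (
    AnnealingSchedule,
    amova,
    delaunay_adjacency,
    evaluate_partition,
    k_sweep,
    samova,
)

FAST = AnnealingSchedule(n_restarts=8, n_proposals=2000)


def _two_pop_fixed():
    sites = [MutationSite(1, "r", "substitution"), MutationSite(2, "r", "substitution")]
    m = HaplotypeMatrix(sites, [Haplotype("X", ("C", "C")), Haplotype("Y", ("T", "T"))])
    return Dataset(m, [Population("P0", 0, 0, {"X": 8}),
                       Population("P1", 1, 1, {"Y": 8})])


class TestAmova:
    def test_survey_among_population_percentage(self, dataset):
        res = amova(dataset, n_perm=0)
        assert abs(res.percent_among_populations - 98.09) < 0.05
        assert abs(res.levels[1]["percent"] - 1.91) < 0.05

    def test_percentages_sum_to_100_and_ss_decomposes(self, dataset):
        res = amova(dataset, n_perm=0)
        assert math.isclose(sum(l["percent"] for l in res.levels), 100.0,
                            rel_tol=1e-9)
        ss_among, ss_within = (l["SS"] for l in res.levels)
        flat = amova(dataset, n_perm=0)
        # SS reproduce the total sum of squares
        from haplogeo.structure import _SSParts
        from haplogeo.model import DistanceModel

        parts = _SSParts.build(dataset, DistanceModel.substitutions_only(), False)
        assert math.isclose(ss_among + ss_within, parts.ss_total, rel_tol=1e-9)

    def test_fixed_populations_fully_differentiated(self):
        res = amova(_two_pop_fixed(), n_perm=0)
        assert math.isclose(res.percent_among_populations, 100.0, rel_tol=1e-9)
        assert math.isclose(res.phi["Phi_ST"], 1.0, rel_tol=1e-9)

    def test_arbitrary_split_of_one_population_has_no_structure(self):
        rng = np.random.default_rng(1)
        sites = [MutationSite(i + 1, "r", "substitution") for i in range(3)]
        haps = [Haplotype("X", ("C", "C", "C")), Haplotype("Y", ("T", "C", "C")),
                Haplotype("Z", ("T", "T", "C"))]
        m = HaplotypeMatrix(sites, haps)
        pool = rng.multinomial(60, [0.5, 0.3, 0.2])
        half = rng.multivariate_hypergeometric(pool, 30)
        ds = Dataset(m, [
            Population("P0", 0, 0, dict(zip("XYZ", (int(x) for x in half)))),
            Population("P1", 1, 1, dict(zip("XYZ", (int(x) for x in pool - half)))),
        ])
        res = amova(ds, n_perm=200, seed=0)
        assert abs(res.phi["Phi_ST"]) < 0.1
        assert res.p_values["Phi_ST"] > 0.1

    def test_survey_permutation_significance(self, dataset):
        res = amova(dataset, n_perm=100, seed=0)
        assert res.p_values["Phi_ST"] <= 1 / 101 + 1e-12

    def test_identical_individuals_rejected(self):
        sites = [MutationSite(1, "r", "substitution")]
        m = HaplotypeMatrix(sites, [Haplotype("X", ("C",))])
        ds = Dataset(m, [Population("P0", 0, 0, {"X": 5}),
                         Population("P1", 1, 1, {"X": 5})])
        with pytest.raises(ValueError, match="identical"):
            amova(ds, n_perm=0)


class TestEvaluatePartition:
    def test_published_partitions(self, dataset):
        f5 = evaluate_partition(dataset, grouping=bretschneidera.load_partition(5))
        assert abs(f5[0] - 0.96096) / 0.96096 < 0.02
        f2 = evaluate_partition(dataset, grouping=bretschneidera.load_partition(2))
        assert abs(f2[0] - 0.83573) / 0.83573 < 0.02

    def test_group_relabeling_and_order_invariance(self, dataset):
        grouping = bretschneidera.load_partition(5)
        relabeled = {p: f"grp-{g}" for p, g in grouping.items()}
        reordered = Dataset(dataset.matrix, list(dataset.populations)[::-1])
        a = evaluate_partition(dataset, grouping=grouping)
        b = evaluate_partition(dataset, grouping=relabeled)
        c = evaluate_partition(reordered, grouping=grouping)
        for x, y in zip(a, b):
            assert math.isclose(x, y, rel_tol=1e-12)
        for x, y in zip(a, c):
            assert math.isclose(x, y, rel_tol=1e-12)

    def test_singleton_groups_degenerate(self, dataset):
        grouping = {p.label: p.label for p in dataset.populations}
        f_ct, f_sc, f_st = evaluate_partition(dataset, grouping=grouping)
        assert math.isnan(f_sc)
        assert math.isclose(f_ct, f_st, rel_tol=1e-12)

    def test_requires_grouping_and_multiple_groups(self, dataset):
        with pytest.raises(ValueError):
            evaluate_partition(dataset, grouping=None)
        with pytest.raises(ValueError):
            evaluate_partition(dataset,
                               grouping={p.label: 0 for p in dataset.populations})


def _two_island(seed=5):
    return generate(GeneratorConfig(n_populations=8, n_groups=2,
                                    between_group_steps=5, within_group_steps=1,
                                    seed=seed))


class TestSamova:
    def test_search_matches_or_beats_published_partition(self, dataset):
        printed = evaluate_partition(dataset, grouping=bretschneidera.load_partition(5))
        res = samova(dataset, K=5, schedule=FAST, seed=1)
        assert res.F_CT >= printed[0] - 1e-9
        assert len(res.sa_trace) == FAST.n_restarts
        assert math.isclose(max(res.sa_trace), res.F_CT, rel_tol=1e-9)

    def test_groups_are_contiguous(self, dataset):
        from haplogeo.structure import _connected

        adj = delaunay_adjacency(dataset)
        res = samova(dataset, K=4, schedule=FAST, seed=2)
        for g in set(res.groups.values()):
            members = {p for p, gg in res.groups.items() if gg == g}
            assert _connected(members, adj)

    def test_recovers_planted_two_island_structure(self):
        ds = _two_island()
        res = samova(ds, K=2, schedule=FAST, seed=0)
        planted = [res.groups[p.label] for p in ds.populations]
        assert len(set(planted[:4])) == 1 and len(set(planted[4:])) == 1
        assert planted[0] != planted[-1]

    def test_reproducible_under_seed(self, dataset):
        a = samova(dataset, K=3, schedule=AnnealingSchedule(2, 500), seed=9)
        b = samova(dataset, K=3, schedule=AnnealingSchedule(2, 500), seed=9)
        assert a.groups == b.groups and a.F_CT == b.F_CT

    def test_k_bounds(self, dataset):
        with pytest.raises(ValueError):
            samova(dataset, K=1)
        with pytest.raises(ValueError):
            samova(dataset, K=24)

    def test_unconstrained_bound_not_below_contiguous(self, dataset):
        free = samova(dataset, K=3, schedule=FAST, seed=4,
                      enforce_contiguity=False)
        tied = samova(dataset, K=3, schedule=FAST, seed=4)
        assert free.F_CT >= tied.F_CT - 0.02


class TestKSweep:
    def test_survey_sweep_selects_five_groups(self, dataset):
        sched = AnnealingSchedule(n_restarts=12, n_proposals=3000)
        results, chosen = k_sweep(dataset, k_range=range(2, 8),
                                  schedule=sched, seed=0)
        assert chosen == 5
        assert set(results) == set(range(2, 8))

    def test_two_island_sweep_selects_two(self):
        ds = _two_island()
        _, chosen = k_sweep(ds, k_range=range(2, 5), schedule=FAST, seed=0)
        assert chosen == 2

    def test_single_value_range(self, dataset):
        results, chosen = k_sweep(dataset, k_range=[3],
                                  schedule=AnnealingSchedule(2, 500), seed=0)
        assert chosen == 3 and list(results) == [3]


def test_delaunay_adjacency_is_connected(dataset):
    adj = delaunay_adjacency(dataset)
    from haplogeo.structure import _connected

    assert _connected(set(adj), adj)
    # symmetry
    for a, nbs in adj.items():
        for b in nbs:
            assert a in adj[b]
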