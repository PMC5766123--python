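"""Diversity estimators and the GST/NST differentiation partition."""

import itertools
import math

import numpy as np
import pytest

from haplogeo.diversity import (
    EFFECTIVE_LENGTH,
    nei_h,
    nei_h_se,
    nm_from_gst,
    nucleotide_diversity,
    permut_nst_gst,
    pons_petit,
    pop_diversity,
)
from haplogeo.model import (
    Dataset,
    DistanceModel,
    Haplotype,
    HaplotypeMatrix,
    MutationSite,
    Population,
)


class TestNeiH:
    @pytest.mark.parametrize("counts,expected", [
        ((7, 4), 0.5091),
        ((12,), 0.0),
        ((6, 3, 3), 0.6818),
        ((9, 3), 0.4091),
        ((10, 1, 1), 0.3182),
    ])
    def test_printed_values(self, counts, expected):
        assert round(nei_h(counts), 4) == expected

    @pytest.mark.parametrize("counts,expected", [
        ((7, 4), 0.1008),
        ((12,), 0.0),
        ((9, 3), 0.1333),
        ((10, 1, 1), 0.1637),
        ((6, 3, 3), 0.0910),
    ])
    def test_printed_standard_errors(self, counts, expected):
        assert round(nei_h_se(counts), 4) == expected

    def test_undefined_below_two(self):
        with pytest.raises(ValueError):
            nei_h([1])

    def test_matches_brute_force_ordered_pair_probability(self):
        """h equals the probability that two draws without replacement
        differ, enumerated over all ordered pairs of individuals."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 8, size=rng.integers(2, 5))
            if counts.sum() < 2:
                continue
            pop = [i for i, c in enumerate(counts) for _ in range(c)]
            diff = sum(a != b for a, b in itertools.permutations(pop, 2))
            brute = diff / (len(pop) * (len(pop) - 1))
            assert math.isclose(nei_h(counts), brute, rel_tol=1e-12)


class TestNucleotideDiversity:
    def test_printed_values(self, dataset):
        lp = dataset.population("LP").counts
        ls = dataset.population("LS").counts
        assert round(nucleotide_diversity(lp, dataset.matrix) * 1e3, 3) == 0.074
        assert round(nucleotide_diversity(ls, dataset.matrix) * 1e3, 3) == 0.182

    def test_monomorphic_is_zero(self, dataset):
        es = dataset.population("ES").counts
        assert nucleotide_diversity(es, dataset.matrix) == 0.0

    def test_rejects_nonpositive_length(self, dataset):
        with pytest.raises(ValueError):
            nucleotide_diversity(dataset.population("LP").counts,
                                 dataset.matrix, effective_length=0)


def _toy_dataset(pop_counts, distances=None):
    """Dataset over haplotypes X/Y/Z with controllable substitution states."""
    sites = [MutationSite(i + 1, "r", "substitution") for i in range(4)]
    rows = {"X": ("C", "C", "C", "C"), "Y": ("T", "C", "C", "C"),
            "Z": ("T", "T", "C", "C")}
    m = HaplotypeMatrix(sites, [Haplotype(k, v) for k, v in rows.items()])
    pops = [Population(f"P{i}", float(i), float(i), c)
            for i, c in enumerate(pop_counts)]
    return Dataset(m, pops)


class TestPonsPetit:
    def test_survey_partition(self, dataset):
        part = pons_petit(dataset)
        assert round(part.hS, 3) == 0.083
        assert abs(part.hT - 0.739) / 0.739 < 0.02
        assert abs(part.GST - 0.887) / 0.887 < 0.02
        assert abs(part.NST - 0.973) / 0.973 < 0.02
        assert part.NST > part.GST

    def test_hS_is_mean_of_per_population_diversities(self, dataset):
        part = pons_petit(dataset)
        mean_h = np.mean([r.h for r in pop_diversity(dataset)])
        assert math.isclose(part.hS, mean_h, rel_tol=1e-12)

    def test_gst_identity(self, dataset):
        part = pons_petit(dataset)
        assert math.isclose(part.GST, (part.hT - part.hS) / part.hT, rel_tol=1e-12)

    def test_identical_populations_have_near_zero_gst(self):
        """With identical population samples GST vanishes up to the
        small-sample bias correction of hS (order 1/n)."""
        ds = _toy_dataset([{"X": 200, "Y": 200}, {"X": 200, "Y": 200}])
        part = pons_petit(ds)
        assert abs(part.GST) < 0.01
        small = _toy_dataset([{"X": 5, "Y": 5}, {"X": 5, "Y": 5}])
        assert abs(pons_petit(small).GST) < 0.15

    def test_equal_distances_make_nst_equal_gst(self):
        # X..Z pairwise substitution distances are not all equal, so force
        # them equal through a saturating model on a 1-difference design
        ds = _toy_dataset([{"X": 6, "Y": 2}, {"Y": 5, "Z": 3}])
        part = pons_petit(ds, model=DistanceModel(ssr_saturate=True))
        d01, d02, d12 = 1, 2, 1
        # with unequal distances NST != GST; rebuild with an equal-distance matrix
        from haplogeo.diversity import _partition_stats, _frequencies

        sizes = np.array([p.n for p in ds.populations], dtype=float)
        freqs = _frequencies(ds)
        ident = 1.0 - np.eye(3)
        vS, vT = _partition_stats(freqs, sizes, 2.5 * ident)
        hS, hT = _partition_stats(freqs, sizes, ident)
        assert math.isclose((vT - vS) / vT, (hT - hS) / hT, rel_tol=1e-12)

    def test_population_order_invariance(self, dataset):
        reordered = Dataset(dataset.matrix, list(dataset.populations)[::-1])
        a, b = pons_petit(dataset), pons_petit(reordered)
        assert math.isclose(a.hT, b.hT, rel_tol=1e-12)
        assert math.isclose(a.GST, b.GST, rel_tol=1e-12)
        assert math.isclose(a.NST, b.NST, rel_tol=1e-12)

    def test_duplicating_every_population_keeps_hS(self, dataset):
        """hS (a per-population average) is exactly invariant under
        duplication; hT moves only slightly because duplication enlarges
        the deme universe with same-frequency pairs."""
        doubled = Dataset(dataset.matrix, list(dataset.populations) + [
            Population(p.label + "_copy", p.latitude, p.longitude, p.counts)
            for p in dataset.populations
        ])
        a, b = pons_petit(dataset), pons_petit(doubled)
        assert math.isclose(a.hS, b.hS, rel_tol=1e-12)
        assert abs(a.hT - b.hT) < 0.03

    def test_needs_two_populations(self, dataset):
        with pytest.raises(ValueError):
            pons_petit(dataset.subset(["LP"]))


class TestPermutationComparison:
    def test_survey_phylogeographic_signal_is_significant(self, dataset):
        part = permut_nst_gst(dataset, n_perm=200, seed=0)
        assert part.p_NST_gt_GST < 0.05

    def test_no_signal_when_distances_uninformative(self):
        # two haplotypes: permuting a 2x2 distance matrix never changes NST
        sites = [MutationSite(1, "r", "substitution")]
        m = HaplotypeMatrix(sites, [Haplotype("X", ("C",)), Haplotype("Y", ("T",))])
        ds = Dataset(m, [Population("P0", 0, 0, {"X": 6, "Y": 2}),
                         Population("P1", 1, 1, {"X": 2, "Y": 6})])
        part = permut_nst_gst(ds, n_perm=99, seed=0)
        assert part.p_NST_gt_GST > 0.5

    def test_reproducible_under_seed(self, dataset):
        a = permut_nst_gst(dataset, n_perm=50, seed=7).p_NST_gt_GST
        b = permut_nst_gst(dataset, n_perm=50, seed=7).p_NST_gt_GST
        assert a == b


class TestNm:
    @pytest.mark.parametrize("gst,expected", [
        (0.855, 0.0848), (1.0, 0.0), (0.5, 0.5),
    ])
    def test_closed_form(self, gst, expected):
        assert round(nm_from_gst(gst), 4) == expected

    def test_zero_gst_signalled(self):
        with pytest.raises(ValueError):
            nm_from_gst(0.0)
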