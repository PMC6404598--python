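import itertools
import math

import numpy as np
import pytest
from scipy import stats

from polydose import (CrossDesign, DosageMatrix, GenotypeProbArray,
                      LinkageConfig, PloidyHypothesis, PopulationModel,
                      hwe_prior, ld_adjusted_priors, mapping_priors,
                      popstruct_individual_freqs, progeny_dosage_distribution,
                      update_allele_freqs)
from polydose.priors import (gamete_distribution, hwe_priors_matrix,
                             parent_gamete_distribution)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_force_gametes(dosage, k):
    """Enumerate all C(k, k/2) chromosome subsets of a dosage-i genotype."""
    chroms = [1] * dosage + [0] * (k - dosage)
    counts = {}
    for subset in itertools.combinations(range(k), k // 2):
        j = sum(chroms[c] for c in subset)
        counts[j] = counts.get(j, 0) + 1
    total = sum(counts.values())
    return np.array([counts.get(j, 0) / total for j in range(k // 2 + 1)])


def brute_force_f1(d1, d2, k):
    """Progeny dosage pmf by enumerating every gamete pair."""
    g1, g2 = brute_force_gametes(d1, k), brute_force_gametes(d2, k)
    out = np.zeros(k + 1)
    for j1, w1 in enumerate(g1):
        for j2, w2 in enumerate(g2):
            out[j1 + j2] += w1 * w2
    return out


class TestHWEPrior:
    def test_diploid_binomial(self):
        np.testing.assert_allclose(hwe_prior(0.5, 2), [0.25, 0.5, 0.25])

    def test_tetraploid_binomial(self):
        np.testing.assert_allclose(hwe_prior(0.5, 4),
                                   np.array([1, 4, 6, 4, 1]) / 16)

    @pytest.mark.parametrize("k", [2, 3, 4, 6, 8])
    def test_matches_binomial_coefficients(self, k):
        for p in [0.1, 0.37, 0.5, 0.9]:
            np.testing.assert_allclose(hwe_prior(p, k),
                                       stats.binom.pmf(np.arange(k + 1), k, p),
                                       atol=1e-12)

    @pytest.mark.parametrize("k,subs", [(4, "2,2"), (6, "2,2,2"), (8, "4,4")])
    def test_subgenome_convolution_equals_merged_binomial(self, k, subs):
        # Vandermonde: convolving per-subgenome binomials gives Binomial(k, p)
        for p in np.arange(0.1, 1.0, 0.2):
            np.testing.assert_allclose(hwe_prior(p, subs), hwe_prior(p, k),
                                       atol=1e-12)

    def test_full_selfing_diploid_fixed_point(self):
        # heterozygosity halves every generation; the fixed point is
        # homozygotes only, in allele-frequency proportions
        np.testing.assert_allclose(hwe_prior(0.5, 2, s=1.0), [0.5, 0.0, 0.5],
                                   atol=1e-8)

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_selfing_preserves_mean_dosage(self, k):
        for p in np.arange(0.1, 1.0, 0.1):
            for s in [0.0, 0.3, 0.7, 1.0]:
                prior = hwe_prior(p, k, s)
                assert prior.sum() == pytest.approx(1.0, abs=1e-9)
                mean = (prior * np.arange(k + 1)).sum()
                assert mean == pytest.approx(k * p, abs=1e-6)

    def test_selfing_increases_homozygosity(self):
        free = hwe_prior(0.5, 4, s=0.0)
        selfed = hwe_prior(0.5, 4, s=0.8)
        assert selfed[0] > free[0] and selfed[4] > free[4]

    def test_vectorized_matches_scalar(self):
        freqs = np.array([0.1, 0.5, 0.8])
        mat = hwe_priors_matrix(freqs, PloidyHypothesis.parse(4), s=0.4)
        for i, p in enumerate(freqs):
            np.testing.assert_allclose(mat[i], hwe_prior(p, 4, 0.4), atol=1e-12)


class TestGametes:
    @pytest.mark.parametrize("k", [2, 4])
    def test_hypergeometric_matches_enumeration(self, k):
        for dosage in range(k + 1):
            np.testing.assert_allclose(gamete_distribution(dosage, k),
                                       brute_force_gametes(dosage, k))

    def test_odd_ploidy_rejected(self):
        with pytest.raises(ValueError, match="even"):
            gamete_distribution(1, 3)

    def test_allotetraploid_simplex_gamete(self):
        # one copy among 2+2 subgenomes: the carrying subgenome transmits it
        # half the time regardless of which subgenome holds it
        g = parent_gamete_distribution(1, PloidyHypothesis.parse("2,2"))
        np.testing.assert_allclose(g, [0.5, 0.5, 0.0])


class TestProgenyDistribution:
    @pytest.mark.parametrize("k", [2, 4])
    def test_f1_matches_gamete_pair_enumeration(self, k):
        for d1 in range(k + 1):
            for d2 in range(k + 1):
                np.testing.assert_allclose(
                    progeny_dosage_distribution(d1, d2, k),
                    brute_force_f1(d1, d2, k), atol=1e-12)

    def test_diploid_f1_het_cross(self):
        np.testing.assert_allclose(progeny_dosage_distribution(1, 1, 2),
                                   [0.25, 0.5, 0.25])

    def test_tetraploid_simplex_by_nulliplex(self):
        # AAAB x AAAA: gametes of AAAB carry B with probability 1/2
        np.testing.assert_allclose(progeny_dosage_distribution(1, 0, 4),
                                   [0.5, 0.5, 0, 0, 0])

    def test_f2_from_het_parents(self):
        design = CrossDesign("p1", "p2", generations_selfing=1)
        # selfing an F1 of Aa x Aa: sum over F1 classes of their selfed progeny
        got = progeny_dosage_distribution(1, 1, 2, design)
        np.testing.assert_allclose(got, [0.375, 0.25, 0.375])

    def test_backcross_to_homozygote(self):
        design = CrossDesign("p1", "p2", generations_backcross=1,
                             recurrent_parent="p2")
        got = progeny_dosage_distribution(1, 0, 2, design)
        # F1 of Aa x aa is (1/2 aa, 1/2 Aa); BC1 to aa keeps that ratio
        np.testing.assert_allclose(got, [0.75, 0.25, 0.0])


class TestMappingPriors:
    def _f1_dataset(self, depth_parents, depth_progeny, n_prog=6):
        rows = [depth_parents[0], depth_parents[1]] + [depth_progeny] * n_prog
        taxa = ["P1", "P2"] + [f"F{i}" for i in range(n_prog)]
        return make_dataset(np.array(rows), [2], taxa=taxa)

    def test_diploid_het_by_het_prior(self):
        ds = self._f1_dataset([[50, 50], [40, 60]], [2, 1])
        model = PopulationModel(freq=np.array([0.5, 0.5]), c=0.001)
        priors, flags = mapping_priors(ds, CrossDesign("P1", "P2"),
                                       PloidyHypothesis.parse(2), model)
        assert not flags.any()
        np.testing.assert_allclose(priors.values[2, 0], [0.25, 0.5, 0.25])

    def test_monomorphic_cross_gives_point_prior(self):
        ds = self._f1_dataset([[100, 0], [100, 0]], [10, 0])
        model = PopulationModel(freq=np.array([0.99, 0.01]), c=0.001)
        priors, flags = mapping_priors(ds, CrossDesign("P1", "P2"),
                                       PloidyHypothesis.parse(2), model)
        np.testing.assert_allclose(priors.values[2, 0], [0, 0, 1.0], atol=1e-12)

    def test_zero_depth_parent_falls_back_to_hwe(self):
        ds = self._f1_dataset([[0, 0], [40, 60]], [2, 1])
        model = PopulationModel(freq=np.array([0.5, 0.5]), c=0.001)
        priors, flags = mapping_priors(ds, CrossDesign("P1", "P2"),
                                       PloidyHypothesis.parse(2), model)
        assert flags.all()
        # HWE prior from progeny frequencies, not a segregation ratio
        p = 2.0 / 3.0
        np.testing.assert_allclose(priors.values[2, 0],
                                   stats.binom.pmf(np.arange(3), 2, p),
                                   atol=1e-9)

    def test_contradicted_homozygous_parents_flagged(self):
        # parents look AA but the progeny are half B reads
        ds = self._f1_dataset([[100, 0], [100, 0]], [5, 5])
        model = PopulationModel(freq=np.array([0.5, 0.5]), c=0.001)
        _, flags = mapping_priors(ds, CrossDesign("P1", "P2"),
                                  PloidyHypothesis.parse(2), model)
        assert flags.all()

    def test_missing_parent_is_an_error(self, toy_dataset):
        model = PopulationModel(freq=np.full(4, 0.5))
        with pytest.raises(KeyError, match="parent"):
            mapping_priors(toy_dataset, CrossDesign("nope", "T1"),
                           PloidyHypothesis.parse(2), model)


class TestPopstructFreqs:
    def test_identical_individuals_recover_global_frequency(self):
        ds = make_dataset(np.tile([5, 5], (12, 1)), [2])
        vals = np.tile([0.8, 1.2], (12, 1))
        pmg = DosageMatrix(vals, k=2)
        freqs = popstruct_individual_freqs(pmg, ds, 2, n_axes=2)
        np.testing.assert_allclose(freqs[:, 0], 0.4, atol=1e-9)
        np.testing.assert_allclose(freqs.sum(axis=1)[:, None],
                                   np.ones((12, 1)), atol=1e-9)

    def test_intercept_only_reproduces_global_frequencies(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 2, size=(20, 2))
        vals[:, 1] = 2 - vals[:, 0]
        ds = make_dataset(np.ones((20, 2), int), [2])
        pmg = DosageMatrix(vals, k=2)
        freqs = popstruct_individual_freqs(pmg, ds, 2, n_axes=0)
        np.testing.assert_allclose(freqs[:, 0], vals[:, 0].mean() / 2, atol=1e-9)

    def test_two_clusters_recover_cluster_frequencies(self):
        # two subpopulations with very different dosage means
        rng = np.random.default_rng(1)
        n, m = 60, 30
        labels = np.repeat([0, 1], n // 2)
        truth_p = np.where(labels[:, None] == 0, 0.15, 0.85)  # per ind
        g = rng.binomial(2, np.broadcast_to(truth_p, (n, m)))
        vals = np.empty((n, 2 * m))
        vals[:, 0::2] = g
        vals[:, 1::2] = 2 - g
        ds = make_dataset(np.ones((n, 2 * m), int), [2] * m)
        pmg = DosageMatrix(vals.astype(float), k=2)
        freqs = popstruct_individual_freqs(pmg, ds, 2, n_axes=1)
        est = freqs[:, 0::2].mean(axis=1)
        assert np.abs(est - truth_p[:, 0]).max() < 0.1

    def test_clamping_keeps_frequencies_interior(self):
        ds = make_dataset(np.ones((10, 2), int), [2])
        pmg = DosageMatrix(np.zeros((10, 2)), k=2)
        freqs = popstruct_individual_freqs(pmg, ds, 2, n_axes=0)
        assert (freqs > 0).all() and (freqs < 1).all()

    def test_too_many_axes_rejected(self):
        ds = make_dataset(np.ones((3, 2), int), [2])
        pmg = DosageMatrix(np.ones((3, 2)), k=2)
        with pytest.raises(ValueError, match="individuals"):
            popstruct_individual_freqs(pmg, ds, 2, n_axes=5)


class TestLDPriors:
    def _setup(self, positions):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.5, size=50)
        depth = np.zeros((50, 4), int)
        a = rng.binomial(30, np.clip(g / 2, 1e-9, 1 - 1e-9))
        depth[:, 0] = a
        depth[:, 1] = 30 - a
        a2 = rng.binomial(30, np.clip(g / 2, 1e-9, 1 - 1e-9))
        depth[:, 2] = a2
        depth[:, 3] = 30 - a2
        ds = make_dataset(depth, [2, 2], positions=positions)
        vals = np.empty((50, 4))
        vals[:, 0] = g
        vals[:, 1] = 2 - g
        vals[:, 2] = g
        vals[:, 3] = 2 - g
        pmg = DosageMatrix(vals.astype(float), k=2)
        base = GenotypeProbArray(np.full((50, 4, 3), 1 / 3), kind="prior")
        return ds, pmg, base

    def test_no_neighbor_within_distance_keeps_base(self):
        ds, pmg, base = self._setup([0, 10_000_000])
        out = ld_adjusted_priors(base, pmg, ds, LinkageConfig(1000, 5, 0.5), 2)
        np.testing.assert_array_equal(out.values, base.values)

    def test_zero_mix_weight_keeps_base(self):
        ds, pmg, base = self._setup([0, 500])
        out = ld_adjusted_priors(base, pmg, ds, LinkageConfig(1000, 5, 0.0), 2)
        np.testing.assert_array_equal(out.values, base.values)

    def test_linked_locus_sharpens_prior_toward_truth(self):
        ds, pmg, base = self._setup([0, 500])
        out = ld_adjusted_priors(base, pmg, ds, LinkageConfig(1000, 5, 0.5), 2)
        # individuals with dosage 2 at the linked locus get more prior mass
        # on dosage 2 than the flat base
        two = pmg.values[:, 2] == 2
        assert out.values[two, 0, 2].mean() > base.values[two, 0, 2].mean()
        np.testing.assert_allclose(out.values.sum(axis=2), 1.0, atol=1e-9)

    def test_missing_positions_is_an_error(self, toy_dataset):
        base = GenotypeProbArray(np.full((4, 4, 3), 1 / 3), kind="prior")
        pmg = DosageMatrix(np.ones((4, 4)), k=2)
        with pytest.raises(ValueError, match="position"):
            ld_adjusted_priors(base, pmg, toy_dataset, LinkageConfig(), 2)


class TestUpdateAlleleFreqs:
    def test_constant_dosage_matrix(self):
        ds = make_dataset(np.ones((5, 2), int), [2])
        pmg = DosageMatrix(np.column_stack([np.full(5, 0.6), np.full(5, 1.4)]), k=2)
        p = update_allele_freqs(pmg, ds, 2)
        np.testing.assert_allclose(p, [0.3, 0.7])

    def test_renormalizes_within_locus(self):
        ds = make_dataset(np.ones((5, 2), int), [2])
        pmg = DosageMatrix(np.column_stack([np.full(5, 0.4), np.full(5, 1.8)]), k=2)
        p = update_allele_freqs(pmg, ds, 2)
        np.testing.assert_allclose(p, [0.2 / 1.1, 0.9 / 1.1])

    def test_truth_genotypes_give_sample_frequency(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, size=(40, 1))
        vals = np.column_stack([g, 2 - g]).astype(float)
        ds = make_dataset(np.ones((40, 2), int), [2])
        p = update_allele_freqs(DosageMatrix(vals, k=2), ds, 2)
        assert p[0] == pytest.approx(g.mean() / 2)

    def test_blanks_excluded(self):
        ds = make_dataset(np.ones((3, 2), int), [2], blanks={"T2"})
        vals = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        p = update_allele_freqs(DosageMatrix(vals, k=2), ds, 2)
        np.testing.assert_allclose(p, [0.5, 0.5])


def test_every_prior_operation_yields_normalized_vectors():
    rng = np.random.default_rng(2)
    freqs = rng.uniform(0.05, 0.95, size=6)
    for k in (2, 4):
        for s in (0.0, 0.5):
            mat = hwe_priors_matrix(freqs, PloidyHypothesis.parse(k), s)
            assert (mat >= 0).all()
            np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-9)
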