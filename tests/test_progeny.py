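import numpy as np
import pytest

from cpsim.genome import PhasedPopulation, uniform_linkage_map
from cpsim.progeny import (InbredMomentEngine, cross_inbred_sigma2,
                           pair_inbred_moments, selection_intensity, self_inbred_sigma2,
                           sigma_matrix_for_cross, simulate_inbred_progeny, uc_cross,
                           uc_self)
from tests.conftest import random_population


class TestSelectionIntensity:
    def test_pool_750(self):
        assert selection_intensity(750) == pytest.approx(3.004, abs=5e-4)

    def test_pool_50(self):
        assert selection_intensity(50) == pytest.approx(2.054, abs=5e-4)

    def test_pool_2_is_zero(self):
        assert selection_intensity(2) == pytest.approx(0.0, abs=1e-12)

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            selection_intensity(1)

    def test_truncation_mode(self):
        # classical phi(z)/p intensity, exposed as an option
        assert selection_intensity(750, mode="truncation") == pytest.approx(3.2866, abs=1e-3)
        assert selection_intensity(50, mode="truncation") == pytest.approx(2.4209, abs=1e-3)


class TestPairMoments:
    def test_identical_homozygous_parents(self):
        e_l, e_m, cov = pair_inbred_moments((1, 0), (1, 0), (1, 0), (1, 0),
                                            r=0.2, n_self=7)
        assert e_l == pytest.approx(1.0)
        assert e_m == pytest.approx(-1.0)
        assert cov == pytest.approx(0.0, abs=1e-12)

    def test_single_locus_variance_after_7_selfings(self):
        # inbred parents differing at one locus; duplicated-locus encoding
        _, _, var = pair_inbred_moments((1, 1), (1, 1), (0, 0), (0, 0), r=0.0, n_self=7)
        assert var == pytest.approx(1 - 0.5**7)

    @pytest.mark.parametrize("n_self", range(0, 9))
    def test_unlinked_loci_zero_covariance(self, n_self):
        _, _, cov = pair_inbred_moments((1, 1), (0, 1), (0, 0), (1, 0),
                                        r=0.5, n_self=n_self)
        assert cov == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("r", [0.01, 0.1, 0.25, 0.4])
    def test_ril_limit_closed_form(self, r):
        # classical RIL-by-selfing covariance 1 - 2R, R = 2r/(1+2r)
        _, _, cov = pair_inbred_moments((1, 1), (1, 1), (0, 0), (0, 0), r=r, n_self=400)
        R = 2 * r / (1 + 2 * r)
        assert cov == pytest.approx(1 - 2 * R, abs=1e-9)

    def test_mean_is_midparent(self):
        # A scores: x_l = 1, x_m = 0; B scores: x_l = 0, x_m = 0
        e_l, e_m, _ = pair_inbred_moments((1, 1), (1, 0), (1, 1), (0, 0), r=0.3, n_self=7)
        assert e_l == pytest.approx(0.5)
        assert e_m == pytest.approx(0.0)

    def test_bad_r_rejected(self):
        with pytest.raises(ValueError):
            pair_inbred_moments((1, 1), (0, 0), (1, 1), (0, 0), r=0.6, n_self=7)

    def test_self_mode_single_heterozygous_locus(self):
        _, _, var = pair_inbred_moments((1, 1), (0, 0), r=0.0, n_self=7,
                                        initial_cross=False)
        assert var == pytest.approx(1 - 0.5**7)


class TestEngineAgainstScalarChain:
    def test_cross_matrix_matches_pairwise_sums(self, rng):
        gmap = uniform_linkage_map(2, 4)
        pop = random_population(rng, 4, gmap)
        beta = rng.normal(size=8)
        engine = InbredMomentEngine(gmap, n_self=7)
        mat = engine.cross_sigma2_matrix(pop, beta)
        for (i, j) in [(0, 1), (1, 3), (2, 0)]:
            expected = _sigma2_by_scalar_chain(pop, i, j, gmap, beta, n_self=7)
            assert mat[i, j] == pytest.approx(expected, abs=1e-10)

    def test_self_vector_matches_scalar_chain(self, rng):
        gmap = uniform_linkage_map(2, 4)
        pop = random_population(rng, 3, gmap)
        beta = rng.normal(size=8)
        engine = InbredMomentEngine(gmap, n_self=7)
        vec = engine.self_sigma2(pop, beta)
        for i in range(3):
            expected = _sigma2_by_scalar_chain(pop, i, None, gmap, beta, n_self=7)
            assert vec[i] == pytest.approx(expected, abs=1e-10)

    def test_chunking_is_exact(self, rng):
        gmap = uniform_linkage_map(2, 10)
        pop = random_population(rng, 5, gmap)
        beta = rng.normal(size=20)
        full = InbredMomentEngine(gmap, n_self=7).cross_sigma2_matrix(pop, beta)
        chunked = InbredMomentEngine(gmap, n_self=7, pair_chunk=7).cross_sigma2_matrix(pop, beta)
        np.testing.assert_allclose(chunked, full, atol=1e-12)


def _pair_state(pop, i, l, m):
    return ((int(pop.hap0[i, l]), int(pop.hap0[i, m])),
            (int(pop.hap1[i, l]), int(pop.hap1[i, m])))


def _sigma2_by_scalar_chain(pop, i, j, gmap, beta, n_self):
    """Independent accumulation over loci/pairs via the reference chain."""
    total = 0.0
    for _, sl in gmap.chromosome_slices():
        idx = range(sl.start, sl.stop)
        for l in idx:
            for m in idx:
                if m < l:
                    continue
                r = 0.0 if l == m else gmap.pair_r(l, m)
                a0, a1 = _pair_state(pop, i, l, m)
                if j is None:
                    _, _, cov = pair_inbred_moments(a0, a1, r=r, n_self=n_self,
                                                    initial_cross=False)
                else:
                    b0, b1 = _pair_state(pop, j, l, m)
                    _, _, cov = pair_inbred_moments(a0, a1, b0, b1, r=r, n_self=n_self)
                total += (1 if l == m else 2) * beta[l] * beta[m] * cov
    return total


class TestCrossSigma2:
    def test_zero_beta(self, rng, small_map):
        pop = random_population(rng, 2, small_map)
        cm = cross_inbred_sigma2(pop.take([0]), pop.take([1]), small_map, np.zeros(10))
        assert cm.sigma2 == 0.0

    def test_homozygous_self_cross(self, rng, small_map):
        pop = random_population(rng, 1, small_map, het=False)
        cm = cross_inbred_sigma2(pop.take([0]), pop.take([0]), small_map,
                                 rng.normal(size=10))
        assert cm.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_oracle(self, rng):
        # gamete-dropping oracle on a random 2-chromosome, 10-marker case
        gmap = uniform_linkage_map(2, 5)
        pop = random_population(rng, 2, gmap)
        beta = rng.normal(size=10)
        cm = cross_inbred_sigma2(pop.take([0]), pop.take([1]), gmap, beta)
        sim = simulate_inbred_progeny(pop.take([0]), pop.take([1]), gmap, beta,
                                      n_lines=20_000, rng=rng)
        g = sim["gebv"]
        n = len(g)
        m2 = np.mean((g - g.mean()) ** 2)
        m4 = np.mean((g - g.mean()) ** 4)
        se_var = np.sqrt(max(m4 - m2**2 * (n - 3) / (n - 1), 0.0) / n)
        assert abs(cm.sigma2 - sim["var"]) < 3 * se_var
        se_mean = g.std(ddof=1) / np.sqrt(n)
        assert abs(cm.mu - sim["mean"]) < 3 * se_mean

    def test_between_chromosome_terms_are_exactly_zero(self, rng):
        # additivity across chromosomes: sigma2(both) == sigma2(chr0) + sigma2(chr1)
        gmap = uniform_linkage_map(2, 5)
        pop = random_population(rng, 2, gmap)
        beta = rng.normal(size=10)
        b0, b1 = beta.copy(), beta.copy()
        b0[5:] = 0.0
        b1[:5] = 0.0
        full = cross_inbred_sigma2(pop.take([0]), pop.take([1]), gmap, beta).sigma2
        parts = (cross_inbred_sigma2(pop.take([0]), pop.take([1]), gmap, b0).sigma2
                 + cross_inbred_sigma2(pop.take([0]), pop.take([1]), gmap, b1).sigma2)
        assert full == pytest.approx(parts, rel=1e-12)

    def test_mismatched_markers_rejected(self, rng, small_map):
        a = random_population(rng, 1, small_map)
        b = random_population(rng, 1, uniform_linkage_map(2, 3))
        with pytest.raises(ValueError, match="mismatch"):
            cross_inbred_sigma2(a, b, small_map, np.zeros(10))

    def test_convergence_to_complete_inbreeding(self, rng):
        # residual to the n -> inf limit shrinks like (1/2)^n_self
        gmap = uniform_linkage_map(1, 6)
        pop = random_population(rng, 2, gmap)
        beta = rng.normal(size=6)
        a, b = pop.take([0]), pop.take([1])
        limit = cross_inbred_sigma2(a, b, gmap, beta, n_self=80).sigma2
        gaps = [abs(cross_inbred_sigma2(a, b, gmap, beta, n_self=n).sigma2 - limit)
                for n in range(3, 10)]
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))
        ratios = [g2 / g1 for g1, g2 in zip(gaps, gaps[1:]) if g1 > 1e-12]
        assert all(0.3 < r < 0.7 for r in ratios)

    def test_relabel_invariance_within_chromosome(self, rng):
        # flipping marker order (positions preserved) leaves sigma2 unchanged
        gmap = uniform_linkage_map(1, 5)
        pop = random_population(rng, 2, gmap)
        beta = rng.normal(size=5)
        s1 = cross_inbred_sigma2(pop.take([0]), pop.take([1]), gmap, beta).sigma2
        # reversing a uniformly spaced map preserves all pairwise distances
        order = np.arange(5)[::-1]
        rev_pop = PhasedPopulation(pop.hap0[:, order], pop.hap1[:, order],
                                   ids=list(pop.ids))
        s2 = cross_inbred_sigma2(rev_pop.take([0]), rev_pop.take([1]), gmap,
                                 beta[order]).sigma2
        assert s2 == pytest.approx(s1, rel=1e-12)


class TestSelfSigma2:
    def test_homozygote_zero(self, rng, small_map):
        pop = random_population(rng, 1, small_map, het=False)
        cm = self_inbred_sigma2(pop, small_map, rng.normal(size=10))
        assert cm.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_single_heterozygous_locus(self):
        gmap = uniform_linkage_map(1, 3)
        h0 = np.array([[1, 1, 0]], dtype=np.int8)
        h1 = np.array([[1, 0, 0]], dtype=np.int8)
        ind = PhasedPopulation(h0, h1, ["x"])
        beta = np.array([0.4, 1.5, -2.0])
        cm = self_inbred_sigma2(ind, gmap, beta, n_self=7)
        assert cm.sigma2 == pytest.approx(1.5**2 * (1 - 0.5**7))

    def test_monte_carlo_oracle(self, rng):
        gmap = uniform_linkage_map(2, 5)
        pop = random_population(rng, 1, gmap)
        beta = rng.normal(size=10)
        cm = self_inbred_sigma2(pop, gmap, beta)
        sim = simulate_inbred_progeny(pop, None, gmap, beta, n_lines=20_000, rng=rng)
        g = sim["gebv"]
        n = len(g)
        m2 = np.mean((g - g.mean()) ** 2)
        m4 = np.mean((g - g.mean()) ** 4)
        se_var = np.sqrt(max(m4 - m2**2 * (n - 3) / (n - 1), 0.0) / n)
        assert abs(cm.sigma2 - sim["var"]) < 3 * se_var


class TestUsefulness:
    def test_cross_constant(self):
        s = uc_cross(10.0, 2.0)
        assert s.uc == pytest.approx(10 + 3.004 * 2, abs=2e-3)

    def test_cross_zero_sigma(self):
        assert uc_cross(5.0, 0.0).uc == 5.0

    def test_cross_h_zero(self):
        assert uc_cross(5.0, 2.0, h=0.0).uc == 5.0

    def test_self_constant(self):
        assert uc_self(5.0, 1.0).uc == pytest.approx(7.054, abs=1e-3)

    def test_self_zero_sigma(self):
        assert uc_self(4.0, 0.0).uc == 4.0

    def test_self_monotone_in_sigma(self):
        assert uc_self(1.0, 2.0).uc > uc_self(1.0, 1.0).uc > uc_self(1.0, 0.5).uc


class TestSigmaMatrix:
    def test_per_chromosome_matrix_psd_and_consistent(self, rng):
        gmap = uniform_linkage_map(1, 4)
        pop = random_population(rng, 2, gmap)
        beta = rng.normal(size=4)
        C = sigma_matrix_for_cross(pop.take([0]), pop.take([1]), gmap, 0, n_self=7)
        eig = np.linalg.eigvalsh(0.5 * (C + C.T))
        assert eig.min() > -1e-10
        sigma2 = float(beta @ C @ beta)
        cm = cross_inbred_sigma2(pop.take([0]), pop.take([1]), gmap, beta)
        assert sigma2 == pytest.approx(cm.sigma2, abs=1e-10)


class TestSimulateInbredProgeny:
    def test_homozygous_parent_zero_variance(self, rng, small_map):
        pop = random_population(rng, 1, small_map, het=False)
        sim = simulate_inbred_progeny(pop, None, small_map, rng.normal(size=10),
                                      n_lines=100, rng=rng)
        assert sim["var"] == 0.0

    def test_reproducible(self, rng, small_map):
        pop = random_population(rng, 2, small_map)
        beta = rng.normal(size=10)
        s1 = simulate_inbred_progeny(pop.take([0]), pop.take([1]), small_map, beta,
                                     n_lines=500, rng=77)
        s2 = simulate_inbred_progeny(pop.take([0]), pop.take([1]), small_map, beta,
                                     n_lines=500, rng=77)
        np.testing.assert_array_equal(s1["gebv"], s2["gebv"])
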