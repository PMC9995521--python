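"""Odour-profile construction and random-library sampling."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from beeal.odours import (GEOSMIN_K2_PRESETS, OdourLibrary, OdourProfile,
                          gaussian_k1_profile, make_designated_pair,
                          sample_random_odour)


class TestGaussianProfile:
    def test_peak_value_is_power_of_eta(self):
        v = gaussian_k1_profile(eta=0.8, sigma=3.0, center=10, n_glo=20)
        assert v[10] == pytest.approx(10**0.8)  # ~6.3096 kHz
        for eta in (-1.0, 0.0, 2.5, 4.4):
            v = gaussian_k1_profile(eta, 2.0, 5, 11)
            assert v[5] == 10**eta

    def test_kernel_value_one_index_away(self):
        v = gaussian_k1_profile(eta=0.0, sigma=1.0, center=5, n_glo=11)
        assert v[6] == pytest.approx(np.exp(-0.5))
        assert v[4] == pytest.approx(np.exp(-0.5))

    def test_positive_and_truncated_at_bounds(self):
        v = gaussian_k1_profile(1.0, 2.0, center=0, n_glo=8)
        assert np.all(v > 0)
        assert v.argmax() == 0  # no circular wrap-around

    def test_one_sided_dialect(self):
        v = gaussian_k1_profile(1.0, 3.0, center=0, n_glo=10, one_sided=True)
        # peak at index 0 with offset d=1, strictly decreasing
        assert v[0] == pytest.approx(10.0 * np.exp(-1.0 / 18.0))
        assert np.all(np.diff(v) < 0)

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, sigma):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_k1_profile(1.0, sigma, 0, 10)


N_DRAWS = 10_000


@pytest.fixture(scope="module")
def draws():
    rng = np.random.default_rng(7)
    return [sample_random_odour(rng, 30) for _ in range(N_DRAWS)]


class TestRandomOdours:

    def test_parameters_inside_truncation_bounds(self, draws):
        eta = np.array([od.eta for od in draws])
        sigma = np.array([od.sigma for od in draws])
        k2 = np.array([od.k2 for od in draws])
        assert eta.min() >= 0.0 and eta.max() <= 4.0
        assert sigma.min() >= 1.5
        assert k2.min() >= 0.0028 and k2.max() <= 0.2

    def test_eta_mean_matches_truncated_normal_quadrature(self, draws):
        # independent oracle: E[eta] of N(1.5, 0.5^2) truncated to [0, 4]
        pdf = lambda x: norm.pdf(x, 1.5, 0.5)
        z, _ = quad(pdf, 0.0, 4.0)
        mean_true, _ = quad(lambda x: x * pdf(x), 0.0, 4.0)
        mean_true /= z
        eta = np.array([od.eta for od in draws])
        se = eta.std(ddof=1) / np.sqrt(eta.size)
        assert abs(eta.mean() - mean_true) < 3 * se

    def test_unscrambling_recovers_unimodal_profile(self, draws):
        for od in draws[:50]:
            base = od.unscrambled_k1()
            peak = base.argmax()
            assert base[peak] == pytest.approx(10**od.eta)
            assert np.all(np.diff(base[: peak + 1]) >= 0)
            assert np.all(np.diff(base[peak:]) <= 0)

    def test_default_k_off_rates(self, draws):
        assert draws[0].k_minus1 == 0.025 and draws[0].k_minus2 == 0.025


class TestDesignatedPair:
    def test_printed_parameters(self):
        iaa, geo = make_designated_pair(160, rng=np.random.default_rng(0))
        assert iaa.k2 == pytest.approx(0.1)
        assert iaa.eta == 0.8 and iaa.sigma == 3.0
        assert geo.eta == 4.4 and geo.sigma == 10.0
        assert geo.k2 == pytest.approx(0.003)  # "methods" preset default

    def test_geosmin_k2_presets(self):
        _, geo = make_designated_pair(160, rng=np.random.default_rng(0),
                                      geosmin_k2="results")
        assert geo.k2 == pytest.approx(0.03)
        assert GEOSMIN_K2_PRESETS == {"methods": 0.003, "results": 0.03}
        with pytest.raises(ValueError, match="preset"):
            make_designated_pair(160, geosmin_k2="nope")

    def test_shared_permutation_and_peak_distance(self):
        iaa, geo = make_designated_pair(160, 30, np.random.default_rng(3))
        assert np.array_equal(iaa.permutation, geo.permutation)
        d = geo.unscrambled_k1().argmax() - iaa.unscrambled_k1().argmax()
        assert d == 30

    def test_peak_distance_must_fit(self):
        with pytest.raises(ValueError, match="peak_distance"):
            make_designated_pair(20, peak_distance=25)


class TestLibrary:
    def test_default_size_is_98_random_plus_pair(self):
        lib = OdourLibrary.generate(n_glo=40, seed=0)
        assert lib.n_random == 98 and len(lib) == 100
        assert {"IAA", "Geosmin"} <= set(lib.names)

    def test_generation_is_bitwise_reproducible(self):
        a = OdourLibrary.generate(n_glo=40, n_random=5, seed=11)
        b = OdourLibrary.generate(n_glo=40, n_random=5, seed=11)
        for oa, ob in zip(a, b):
            assert np.array_equal(oa.k1, ob.k1)
            assert (oa.eta, oa.sigma, oa.k2) == (ob.eta, ob.sigma, ob.k2)
            assert np.array_equal(oa.permutation, ob.permutation)

    def test_random_odours_have_own_permutations(self):
        lib = OdourLibrary.generate(n_glo=40, n_random=6, seed=2)
        perms = np.stack([od.permutation for od in lib][:6])
        assert np.unique(perms, axis=0).shape[0] > 1

    def test_lookup_and_serialisation(self, tmp_path):
        lib = OdourLibrary.generate(n_glo=16, n_random=3, seed=5, peak_distance=8)
        assert lib["IAA"].name == "IAA"
        with pytest.raises(KeyError):
            lib["linalool"]
        lib.save(tmp_path / "params.csv", tmp_path / "k1.csv")
        params, k1 = lib.to_frames()
        assert len(params) == 5 and k1.shape == (5, 16)
        assert (tmp_path / "params.csv").exists()


class TestProfileValidation:
    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            OdourProfile(name="x", k1=np.ones(4), k2=0.02, eta=0.0,
                         sigma=1.0, center=0, permutation=np.zeros(4, int))

    def test_negative_k1_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            OdourProfile(name="x", k1=np.array([-1.0, 1.0]), k2=0.02,
                         eta=0.0, sigma=1.0, center=0,
                         permutation=np.arange(2))
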