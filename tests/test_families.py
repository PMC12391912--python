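"""Response families: normalization, gradients, limits, sampling identities."""

import numpy as np
import pytest
from scipy import integrate, stats

from oracles import nb_pmf_series_oracle
from savannagrad.families import (
    DomainError,
    ZeroAdjustedGamma,
    family_from_name,
    fit_mle,
)

FAMILIES = {
    "nb": {"mu": 2.3, "sigma": 0.7},
    "truncnb": {"mu": 3.1, "sigma": 0.4},
    "zaga": {"mu": 2.0, "sigma": 0.6, "nu": 0.3},
    "gaussian": {"mu": 1.0, "sigma": 2.0},
}


def _support_values(name):
    if name == "nb":
        return np.arange(0, 12)
    if name == "truncnb":
        return np.arange(1, 12)
    if name == "zaga":
        return np.array([0.0, 0.2, 0.9, 1.7, 4.2])
    return np.array([-2.0, 0.0, 1.3])


class TestNegativeBinomial:
    def test_matches_series_oracle(self):
        fam = family_from_name("nb")
        for y, mu, sigma in [(1, 2.0, 1.0), (0, 0.5, 0.3), (7, 4.0, 2.0)]:
            got = float(np.exp(fam.logpdf(np.array([y]), mu, sigma))[0])
            assert got == pytest.approx(nb_pmf_series_oracle(y, mu, sigma), rel=1e-10)

    def test_normalizes(self):
        fam = family_from_name("nb")
        y = np.arange(0, 5000)
        assert np.exp(fam.logpdf(y, 2.0, 1.0)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_poisson_limit_at_vanishing_dispersion(self):
        fam = family_from_name("nb")
        y = np.arange(0, 15)
        nb = np.exp(fam.logpdf(y, 3.0, 1e-8))
        po = stats.poisson.pmf(y, 3.0)
        assert np.max(np.abs(nb - po)) < 1e-6


class TestTruncatedNegativeBinomial:
    def test_no_mass_at_zero_and_normalizes(self):
        fam = family_from_name("truncnb")
        with pytest.raises(DomainError):
            fam.logpdf(np.array([0]), 2.0, 0.5)
        y = np.arange(1, 5000)
        assert np.exp(fam.logpdf(y, 2.0, 0.5)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_ratios_match_untruncated(self):
        """truncNB(2)/truncNB(1) = NB(2)/NB(1): the common factor cancels."""
        t, u = family_from_name("truncnb"), family_from_name("nb")
        for mu, sigma in [(0.7, 0.2), (3.0, 1.5), (10.0, 0.05)]:
            rt = t.logpdf(np.array([2]), mu, sigma) - t.logpdf(np.array([1]), mu, sigma)
            ru = u.logpdf(np.array([2]), mu, sigma) - u.logpdf(np.array([1]), mu, sigma)
            assert float(rt[0]) == pytest.approx(float(ru[0]), abs=1e-12)


class TestZeroAdjustedGamma:
    def test_degenerate_all_mass_at_zero(self):
        fam = family_from_name("zaga")
        assert float(fam.logpdf(np.array([0.0]), 2.0, 0.5, 1.0 - 1e-15)[0]) == pytest.approx(0.0, abs=1e-9)

    def test_normalizes_by_quadrature(self):
        fam = family_from_name("zaga")
        mu, sigma, nu = 2.0, 0.6, 0.3
        dens = lambda z: float(np.exp(fam.logpdf(np.array([z]), mu, sigma, nu))[0])
        integral, _ = integrate.quad(dens, 1e-12, np.inf, limit=200)
        assert nu + integral == pytest.approx(1.0, abs=1e-8)

    def test_mixture_mean_by_sampling(self, rng):
        fam = family_from_name("zaga")
        mu, sigma, nu = 3.0, 0.5, 0.4
        draws = fam.rvs(rng, 1_000_000, mu=mu, sigma=sigma, nu=nu)
        assert draws.mean() == pytest.approx((1 - nu) * mu, rel=0.01)

    def test_negative_support_rejected(self):
        with pytest.raises(DomainError):
            family_from_name("zaga").logpdf(np.array([-0.1]), 1.0, 1.0, 0.2)


class TestShiftedResponse:
    def test_shift_composition_is_identity(self):
        fam = ZeroAdjustedGamma(shift=1.0)
        d = np.array([1.0, 1.5, 3.3])
        assert np.allclose(fam.unshift_prediction(fam.shift_response(d)), d)

    def test_unity_maps_to_the_zero_part(self):
        fam = ZeroAdjustedGamma(shift=1.0)
        assert fam.shift_response(np.array([1.0]))[0] == 0.0

    def test_diversity_below_one_is_impossible(self):
        fam = ZeroAdjustedGamma(shift=1.0)
        with pytest.raises(DomainError):
            fam.shift_response(np.array([0.5]))


class TestGradients:
    @pytest.mark.parametrize("name", list(FAMILIES))
    def test_analytic_matches_central_differences(self, name, rng):
        """100 random parameter points per family, tolerance 1e-6."""
        fam = family_from_name(name)
        y = _support_values(name)
        h = 1e-6
        for _ in range(100):
            eta0 = {
                "mu": rng.normal(0.5, 0.6),
                "sigma": rng.normal(-0.3, 0.5),
                "nu": rng.normal(0.0, 0.8),
            }
            if name == "gaussian":
                eta0["mu"] = rng.normal(0.0, 1.0)
            eta = {p: np.full(len(y), eta0[p]) for p in fam.params}
            g = fam.gradients(y, fam.theta(eta))
            for p in fam.params:
                ep = {k: v.copy() for k, v in eta.items()}
                em = {k: v.copy() for k, v in eta.items()}
                ep[p] += h
                em[p] -= h
                fd = (fam.logpdf(y, **fam.theta(ep)) - fam.logpdf(y, **fam.theta(em))) / (2 * h)
                assert np.max(np.abs(fd - g[p])) < 1e-6

    @pytest.mark.parametrize("name", ["nb", "truncnb", "zaga"])
    def test_score_vanishes_at_mle(self, name, rng):
        fam = family_from_name(name)
        y = fam.rvs(rng, 4000, **FAMILIES[name])
        fit = fit_mle(fam, y)
        eta = {p: np.full(len(y), fam.link(p, fit[p])) for p in fam.params}
        g = fam.gradients(y, fam.theta(eta))
        for p in fam.params:
            assert abs(np.mean(g[p])) < 1e-6

    def test_nb_mean_gradient_vanishes_at_observed_mean(self):
        fam = family_from_name("nb")
        g = fam.gradients(np.array([4.0]), {"mu": np.array([4.0]), "sigma": np.array([0.7])})
        assert g["mu"][0] == pytest.approx(0.0, abs=1e-12)
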