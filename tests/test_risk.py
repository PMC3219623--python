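"""Jensen-Shannon divergence, error-rate bounds, and exact 1-D oracles."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm, spearmanr

from designrisk.models import GaussianPredictive, build_model_set
from designrisk.risk import (
    chernoff_bounds,
    exact_error_rate_1d,
    family_risk,
    jensen_shannon,
    kl_gaussian,
    laplace_chernoff_risk,
    posterior_error_probability,
    selection_loss,
)

from conftest import gauss1d, linear_model


class TestKL:
    def test_zero_for_identical(self):
        p = gauss1d(0.3, 2.0)
        assert kl_gaussian(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_matches_numerical_quadrature(self):
        p, q = gauss1d(0.0), gauss1d(1.0)

        def integrand(y):
            fp = norm.pdf(y, 0, 1)
            return fp * np.log2(fp / norm.pdf(y, 1, 1))

        expected, _ = integrate.quad(integrand, -12, 13)
        assert kl_gaussian(p, q) == pytest.approx(expected, abs=1e-6)

    def test_dimension_mismatch_raises(self):
        p = gauss1d(0.0)
        q = GaussianPredictive(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError, match="dimension"):
            kl_gaussian(p, q)

    def test_nonnegative_random_pairs(self, rng):
        for _ in range(20):
            A = rng.standard_normal((3, 3))
            B = rng.standard_normal((3, 3))
            p = GaussianPredictive(rng.standard_normal(3), A @ A.T + np.eye(3))
            q = GaussianPredictive(rng.standard_normal(3), B @ B.T + np.eye(3))
            assert kl_gaussian(p, q) >= 0.0


class TestJensenShannon:
    def test_zero_for_identical_densities(self):
        ps = [gauss1d(0.7, 1.3) for _ in range(3)]
        for method in ("laplace", "quadrature"):
            assert jensen_shannon(ps, method=method) == pytest.approx(0.0, abs=1e-9)

    def test_one_bit_for_fully_separated_pair(self):
        ps = [gauss1d(-1e6), gauss1d(1e6)]
        assert jensen_shannon(ps, method="laplace") >= 1.0  # laplace overshoots
        # quadrature gives the exact disjoint-support limit
        assert jensen_shannon(ps, method="quadrature") == pytest.approx(1.0, abs=1e-6)

    def test_laplace_agrees_with_monte_carlo_at_weak_separation(self):
        """Two equally likely unit-variance Gaussians one sd apart: the
        moment-matched closed form agrees with a large stratified Monte-Carlo
        estimate within 3 Monte-Carlo standard errors."""
        ps = [gauss1d(0.0), gauss1d(1.0)]
        lap = jensen_shannon(ps, method="laplace")
        mcs = [jensen_shannon(ps, method="monte-carlo", mc_samples=50_000, seed=s)
               for s in range(16)]
        se = np.std(mcs, ddof=1) / np.sqrt(len(mcs))
        assert abs(lap - np.mean(mcs)) < 3 * se

    def test_bounded_by_prior_entropy_two_models(self):
        for d in (0.1, 0.5, 1.0, 2.0):
            ps = [gauss1d(0.0), gauss1d(d)]
            assert jensen_shannon(ps, method="quadrature") <= 1.0 + 1e-9

    def test_quadrature_rejects_multivariate(self):
        ps = [GaussianPredictive(np.zeros(2), np.eye(2)) for _ in range(2)]
        with pytest.raises(ValueError, match="univariate"):
            jensen_shannon(ps, method="quadrature")


class TestChernoffBounds:
    def test_vanishing_jsd_upper_bound_half(self):
        lower, upper = chernoff_bounds(0.0, [0.5, 0.5])
        assert upper == pytest.approx(0.5, abs=1e-12)

    def test_one_bit_jsd_bounds_zero(self):
        lower, upper = chernoff_bounds(1.0, [0.5, 0.5])
        assert lower == pytest.approx(0.0, abs=1e-12)
        assert upper == pytest.approx(0.0, abs=1e-12)

    def test_half_bit_values(self):
        # b = H - jsd = 0.5; upper = b/2, lower = b^2 / (4 (M-1))
        lower, upper = chernoff_bounds(0.5, [0.5, 0.5])
        assert upper == pytest.approx(0.25, abs=1e-12)
        assert lower == pytest.approx(0.0625, abs=1e-12)

    def test_monotone_decreasing_in_jsd(self):
        grid = np.linspace(0.0, 1.0, 21)
        bounds = [chernoff_bounds(j, [0.5, 0.5]) for j in grid]
        lowers, uppers = zip(*bounds)
        assert all(np.diff(lowers) <= 1e-12)
        assert all(np.diff(uppers) <= 1e-12)

    def test_jsd_above_entropy_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            chernoff_bounds(1.5, [0.5, 0.5])


class TestExactErrorRate:
    def test_identical_densities_coin_flip(self):
        assert exact_error_rate_1d([gauss1d(0.0), gauss1d(0.0)]) == \
            pytest.approx(0.5, abs=1e-9)

    def test_huge_separation_zero(self):
        err = exact_error_rate_1d([gauss1d(0.0), gauss1d(1e6)])
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_matches_closed_form(self):
        """Equal-variance equal-prior Gaussians one sd apart: the Bayes error
        is Phi(-1/2)."""
        err = exact_error_rate_1d([gauss1d(0.0), gauss1d(1.0)])
        assert err == pytest.approx(norm.cdf(-0.5), abs=1e-9)

    def test_error_rate_increases_with_model_count(self):
        """Adding equally spaced unit-variance models (neighbour
        discriminability fixed) increases the selection error rate."""
        errs = [
            exact_error_rate_1d([gauss1d(float(i)) for i in range(m)])
            for m in range(2, 7)
        ]
        assert all(np.diff(errs) >= -1e-12)


class TestLaplaceChernoffRisk:
    def test_identical_models_risk_at_maximum(self):
        X = np.eye(4)
        ms = build_model_set([linear_model(X, name="a"), linear_model(X, name="b")])
        rep = laplace_chernoff_risk(ms, noise_mode="fixed")
        assert rep.laplace_chernoff_risk == pytest.approx(1.0, abs=1e-9)
        assert rep.upper_bound == pytest.approx(0.5, abs=1e-9)
        assert rep.jsd == pytest.approx(0.0, abs=1e-9)

    def test_equal_covariance_contrast_resolution_form(self, rng):
        """With equal predictive covariances Q the risk reduces to
        1 - 0.5 log2(1 + dmu' Q^-1 dmu / 4)."""
        Q = np.array([[2.0, 0.3], [0.3, 1.0]])
        mu1, mu2 = np.array([0.0, 0.0]), np.array([0.8, -0.4])
        ps = [GaussianPredictive(mu1, Q), GaussianPredictive(mu2, Q)]
        ms = build_model_set([linear_model(np.eye(2), name="a"),
                              linear_model(np.eye(2), name="b")])
        rep = laplace_chernoff_risk(ms, predictives=ps)
        d = mu2 - mu1
        expected = 1.0 - 0.5 * np.log2(1.0 + d @ np.linalg.solve(Q, d) / 4.0)
        assert rep.laplace_chernoff_risk == pytest.approx(expected, abs=1e-10)

    def test_comonotone_with_exact_error_mean_shift(self):
        shifts = np.linspace(0.05, 2.5, 20)
        risks, exacts = [], []
        for s in shifts:
            ps = [gauss1d(0.0), gauss1d(float(s))]
            ms = build_model_set([linear_model(np.eye(1), name="a"),
                                  linear_model(np.eye(1), name="b")])
            risks.append(laplace_chernoff_risk(ms, predictives=ps).laplace_chernoff_risk)
            exacts.append(exact_error_rate_1d(ps))
        rho, _ = spearmanr(risks, exacts)
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_error_rate_decreases_with_data_dimension(self):
        """Fixed per-dimension contrast: both the exact error
        (Phi(-sqrt(n)/2) closed form) and the risk decrease with n."""
        risks, exacts = [], []
        for n in (1, 2, 4, 8, 16):
            ps = [GaussianPredictive(np.zeros(n), np.eye(n)),
                  GaussianPredictive(np.ones(n), np.eye(n))]
            ms = build_model_set([linear_model(np.eye(n), name="a"),
                                  linear_model(np.eye(n), name="b")])
            risks.append(laplace_chernoff_risk(ms, predictives=ps).laplace_chernoff_risk)
            exacts.append(norm.cdf(-np.sqrt(n) / 2.0))
        assert all(np.diff(risks) < 0)
        assert all(np.diff(exacts) < 0)

    def test_validity_flag_at_high_discriminability(self):
        ps = [gauss1d(0.0), gauss1d(6.0)]
        ms = build_model_set([linear_model(np.eye(1), name="a"),
                              linear_model(np.eye(1), name="b")])
        with np.errstate(all="ignore"):
            rep = laplace_chernoff_risk(ms, predictives=ps)
        assert not rep.valid
        assert rep.laplace_chernoff_risk < 0  # unclipped, like the reported values


class TestFamilyRisk:
    def _model_set(self, n_models, dim=1):
        return build_model_set(
            [linear_model(np.eye(dim), name=f"m{i}") for i in range(n_models)]
        )

    def test_singleton_families_reduce_to_model_level(self):
        ps = [gauss1d(0.0), gauss1d(0.6), gauss1d(1.4)]
        ms = self._model_set(3)
        model_level = laplace_chernoff_risk(ms, predictives=ps)
        fam_level = family_risk(ms, {0: "a", 1: "b", 2: "c"}, predictives=ps)
        assert fam_level.laplace_chernoff_risk == \
            pytest.approx(model_level.laplace_chernoff_risk, abs=1e-12)

    def test_single_family_rejected(self):
        ps = [gauss1d(0.0), gauss1d(1.0)]
        ms = self._model_set(2)
        with pytest.raises(ValueError, match="2 families"):
            family_risk(ms, {0: "a", 1: "a"}, predictives=ps)

    def test_different_partitions_give_different_risks(self):
        ps = [gauss1d(0.0), gauss1d(0.5), gauss1d(2.0), gauss1d(2.5)]
        ms = self._model_set(4)
        r1 = family_risk(ms, {0: "x", 1: "x", 2: "y", 3: "y"}, predictives=ps)
        r2 = family_risk(ms, {0: "x", 1: "y", 2: "x", 3: "y"}, predictives=ps)
        assert abs(r1.laplace_chernoff_risk - r2.laplace_chernoff_risk) > 0.05

    def test_moment_matched_ranking_agrees_with_exact_mixtures(self, rng):
        """Family risks computed by Gaussian collapse rank a handful of
        'designs' (mean configurations) the same way as the exact
        family-mixture JSD (quadrature over the true two-component
        mixtures, no collapse)."""
        from designrisk.risk import _LN2, _mixture_logpdf_1d

        def mixture_entropy(ps, ws):
            def f(y):
                lp = _mixture_logpdf_1d(np.asarray([y]), ps, ws)[0]
                return -np.exp(lp) * lp / _LN2
            lo = min(p.mean[0] for p in ps) - 10
            hi = max(p.mean[0] for p in ps) + 10
            val, _ = integrate.quad(f, lo, hi, limit=400)
            return val

        ms = self._model_set(4)
        labels = {0: "x", 1: "x", 2: "y", 3: "y"}
        collapsed, exact = [], []
        half = np.array([0.5, 0.5])
        quarter = np.full(4, 0.25)
        for _ in range(5):
            mus = rng.uniform(-1.5, 1.5, size=4)
            ps = [gauss1d(float(m)) for m in mus]
            rep = family_risk(ms, labels, predictives=ps)
            collapsed.append(rep.jsd)
            h_total = mixture_entropy(ps, quarter)
            h_f1 = mixture_entropy(ps[:2], half)
            h_f2 = mixture_entropy(ps[2:], half)
            exact.append(h_total - 0.5 * h_f1 - 0.5 * h_f2)
        rho, _ = spearmanr(collapsed, exact)
        assert rho == pytest.approx(1.0, abs=1e-12)


class TestPosteriorError:
    @pytest.mark.parametrize("post,expected", [
        ((1.0, 0.0), 0.0),
        ((0.5, 0.5), 0.5),
        ((0.9, 0.1), 0.1),
    ])
    def test_values(self, post, expected):
        assert posterior_error_probability(post) == pytest.approx(expected)

    def test_loss_matrix(self):
        L = selection_loss(3)
        assert np.all(np.diag(L) == 0)
        assert np.all(L[~np.eye(3, dtype=bool)] == 1)
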