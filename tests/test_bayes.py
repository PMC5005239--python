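"""Vague and hierarchical posterior inference with MAP plug-in."""

import numpy as np
import pytest
from scipy import integrate

from ehld_records import (
    ConvergenceError,
    EHLDParams,
    PriorConfig,
    PriorConstraintError,
    RecordSample,
    h1,
    lambda_posterior_hier,
    lambda_posterior_vague,
    loglik,
    noninformative_prior_density,
    q1_q2,
    theta_hmap,
    theta_map,
)
from ehld_records.bayes import (
    hier_posterior_cdf,
    hier_posterior_pdf,
    log_marginal_posterior_theta_hier,
    log_marginal_posterior_theta_vague,
    prior_radicand,
)
from ehld_records.core import sample_record_matrix


class TestVagueThetaPosterior:
    def test_quadrature_oracle(self, rainfall):
        """The lambda-integrated closed form matches direct quadrature of
        likelihood x prior over lambda, up to an additive log constant."""
        prior = PriorConfig(prior_shape=0.01, prior_rate=0.01)
        thetas = [0.08, 0.15, 0.3]
        diffs = []
        for th in thetas:
            num, _ = integrate.quad(
                lambda la: np.exp(
                    loglik(EHLDParams(theta=th, lam=la), rainfall)
                    + (prior.prior_shape - 1) * np.log(la)
                    - prior.prior_rate * la
                )
                / th,
                0,
                60,
            )
            diffs.append(
                log_marginal_posterior_theta_vague(th, rainfall, prior) - np.log(num)
            )
        assert np.ptp(diffs) < 1e-6

    def test_map_rainfall(self, rainfall):
        assert theta_map(rainfall) == pytest.approx(0.156, abs=5e-3)

    def test_map_stationary(self, rainfall):
        th = theta_map(rainfall)
        prior = PriorConfig()
        h = 1e-6
        deriv = (
            log_marginal_posterior_theta_vague(th + h, rainfall, prior)
            - log_marginal_posterior_theta_vague(th - h, rainfall, prior)
        ) / (2 * h)
        assert abs(deriv) < 1e-3

    def test_map_concentrates_with_k(self):
        """theta_MAP concentrates near the true theta as k grows."""
        p = EHLDParams(theta=1.0, lam=2.0)
        rng = np.random.default_rng(4)
        errs = {}
        for k in (8, 24):
            vals = []
            for row in sample_record_matrix(300, k, p, rng):
                try:
                    vals.append(theta_map(RecordSample(row)))
                except ConvergenceError:
                    continue
            errs[k] = np.median(np.abs(np.array(vals) - 1.0))
        assert errs[24] < errs[8]

    def test_scale_equivariance(self, rainfall):
        """Rescaling data by s and theta by 1/s shifts the profile by a constant."""
        prior = PriorConfig()
        s = 4.0
        scaled = RecordSample([v / s for v in rainfall.values])
        thetas = np.array([0.1, 0.2, 0.4])
        a = log_marginal_posterior_theta_vague(thetas, rainfall, prior)
        b = log_marginal_posterior_theta_vague(thetas * s, scaled, prior)
        assert np.ptp(a - b) < 1e-9

    def test_domain(self, rainfall):
        with pytest.raises(ValueError):
            log_marginal_posterior_theta_vague(-0.1, rainfall, PriorConfig())


class TestVagueLambdaPosterior:
    def test_rainfall_summary(self, rainfall):
        post = lambda_posterior_vague(rainfall, level=0.95)
        assert post.lam_mean == pytest.approx(7.051, abs=5e-3)
        lo, hi = post.lam_interval
        # HPD convention reproduces the published (3.055, 11.530) pattern
        assert lo == pytest.approx(3.055, abs=0.05)
        assert hi == pytest.approx(11.530, abs=0.05)

    def test_equal_tail_from_gamma_quantiles(self, rainfall):
        from scipy import stats

        post = lambda_posterior_vague(rainfall, interval="equal-tail")
        prior = PriorConfig()
        rate = prior.prior_rate + h1(post.theta_map, rainfall)
        dist = stats.gamma(rainfall.k + prior.prior_shape, scale=1 / rate)
        assert post.lam_interval[0] == pytest.approx(dist.ppf(0.025), rel=1e-9)
        assert post.lam_interval[1] == pytest.approx(dist.ppf(0.975), rel=1e-9)

    def test_flat_prior_limits(self, rainfall):
        """alpha, beta -> 0: mean -> k/h1 (known-theta MLE), mode -> (k-1)/h1."""
        prior = PriorConfig(prior_shape=1e-9, prior_rate=1e-9)
        post = lambda_posterior_vague(rainfall, prior)
        hv = h1(post.theta_map, rainfall)
        assert post.lam_mean == pytest.approx(rainfall.k / hv, rel=1e-6)
        mode = (rainfall.k + prior.prior_shape - 1) / (prior.prior_rate + hv)
        assert mode == pytest.approx((rainfall.k - 1) / hv, rel=1e-6)


class TestHierThetaPosterior:
    @pytest.mark.parametrize("c", [5.0, 100.0, 500.0])
    def test_hmap_rainfall(self, rainfall, c):
        assert theta_hmap(rainfall, c) == pytest.approx(0.137, abs=5e-3)

    def test_quadrature_oracle(self, rainfall):
        """Integrated variant matches quadrature of the joint posterior over
        lambda, up to an additive log constant."""
        c = 5.0
        thetas = [0.08, 0.15, 0.3]
        diffs = []
        for th in thetas:
            num, _ = integrate.quad(
                lambda la: np.exp(loglik(EHLDParams(theta=th, lam=la), rainfall))
                / (c * th * la**2)
                * (1 - (1 + c * la) * np.exp(-c * la)),
                0,
                60,
            )
            diffs.append(
                log_marginal_posterior_theta_hier(th, rainfall, c) - np.log(num)
            )
        assert np.ptp(diffs) < 1e-6

    def test_as_printed_variant_has_no_interior_mode(self, rainfall):
        """The reciprocal-h2 form has no interior maximum on the rainfall
        data; only the lambda-integrated form reproduces the published 0.137."""
        with pytest.raises(ConvergenceError):
            theta_hmap(rainfall, 5.0, variant="as-printed")

    def test_large_c_limit_shape(self, rainfall):
        """c -> inf: the uniform-rate mixture tends to a lambda^-2 marginal
        prior, so the theta-profile tends to theta^{k-1} h1^{-(k-1)} times
        the record factor (h2 -> h1^{-(k-1)}), up to an additive constant."""
        from ehld_records.bayes import _log_record_factor

        thetas = np.array([0.08, 0.12, 0.2, 0.35])
        k = rainfall.k
        hier = log_marginal_posterior_theta_hier(thetas, rainfall, c=1e8)
        limit = (
            (k - 1) * np.log(thetas)
            - (k - 1) * np.log(h1(thetas, rainfall))
            + _log_record_factor(thetas, rainfall.as_array())
        )
        assert np.ptp(hier - limit) < 1e-5


class TestHierLambdaPosterior:
    def test_rainfall_summary(self, rainfall):
        post = lambda_posterior_hier(rainfall, c=5.0, level=0.95)
        assert post.lam_mean == pytest.approx(5.891, abs=5e-3)
        lo, hi = post.lam_interval
        # HPD convention; published interval (2.428, 9.889), length 7.461
        assert hi - lo == pytest.approx(7.461, abs=0.05)

    def test_c_robustness(self, rainfall):
        means = [lambda_posterior_hier(rainfall, c).lam_mean for c in (5.0, 100.0, 500.0)]
        assert max(means) - min(means) < 0.005

    def test_density_normalises_and_matches_cdf(self, rainfall):
        th = theta_hmap(rainfall, 5.0)
        h1v = float(h1(th, rainfall))
        total, _ = integrate.quad(
            lambda la: hier_posterior_pdf(la, h1v, 5.0, rainfall.k), 0, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-8)
        for t in (2.0, 6.0, 12.0):
            num, _ = integrate.quad(
                lambda la: hier_posterior_pdf(la, h1v, 5.0, rainfall.k), 0, t
            )
            assert hier_posterior_cdf(t, h1v, 5.0, rainfall.k) == pytest.approx(num, abs=1e-8)

    def test_corollary_limit(self, rainfall):
        """c -> inf: posterior mean tends to the unbiased (k-1)/h1."""
        c = 1e6
        post = lambda_posterior_hier(rainfall, c)
        unbiased = (rainfall.k - 1) / h1(post.theta_map, rainfall)
        assert post.lam_mean == pytest.approx(unbiased, rel=1e-4)

    def test_equal_tail_quantiles(self, rainfall):
        post = lambda_posterior_hier(rainfall, 5.0, interval="equal-tail")
        h1v = float(h1(post.theta_map, rainfall))
        lo, hi = post.lam_interval
        assert hier_posterior_cdf(lo, h1v, 5.0, rainfall.k) == pytest.approx(0.025, abs=1e-8)
        assert hier_posterior_cdf(hi, h1v, 5.0, rainfall.k) == pytest.approx(0.975, abs=1e-8)


class TestParameterRecovery:
    def test_hier_mean_low_bias(self):
        """On synthetic chains (theta=1, k=16) the hierarchical mean tracks
        the true shape with small bias relative to its spread."""
        k, c, n = 16, 5.0, 300
        for lam in (2.0, 4.0):
            p = EHLDParams(theta=1.0, lam=lam)
            rng = np.random.default_rng(int(lam))
            vals = []
            for row in sample_record_matrix(n, k, p, rng):
                s = RecordSample(row)
                try:
                    th = theta_hmap(s, c)
                except ConvergenceError:
                    continue
                from ehld_records import h2_h3

                h2v, h3v = h2_h3(th, c, s)
                vals.append((k - 1) * h3v / h2v)
            vals = np.asarray(vals)
            bias = vals.mean() - lam
            assert abs(bias) < 3 * vals.std(ddof=1) / np.sqrt(vals.size) + 0.05


class TestNoninformativePriors:
    def test_inverse_theta_factor(self):
        p1 = noninformative_prior_density(EHLDParams(theta=0.5, lam=2.0), 10, "jeffreys")
        p2 = noninformative_prior_density(EHLDParams(theta=1.0, lam=2.0), 10, "jeffreys")
        assert p1 == pytest.approx(2 * p2, rel=1e-10)

    def test_jeffreys_reference_ratio(self):
        """Jeffreys / reference = sqrt(Q1) at equal (lambda, theta)."""
        lam, k = 2.0, 10
        p = EHLDParams(theta=1.0, lam=lam)
        q1, _ = q1_q2(lam, k)
        ratio = noninformative_prior_density(p, k, "jeffreys") / noninformative_prior_density(
            p, k, "reference"
        )
        assert ratio == pytest.approx(np.sqrt(q1), rel=1e-9)

    def test_radicand_positive_but_vanishing(self):
        """[lam Q2]^2/Q1 climbs toward k without crossing it: the radicand
        stays positive and decays toward the constraint boundary."""
        k = 10
        lams = np.array([0.5, 2.0, 10.0, 100.0])
        rads = np.array([prior_radicand(la, k, "reference") for la in lams])
        assert np.all(rads > 0)
        assert np.all(np.diff(rads) < 0)
        assert rads[-1] < 1e-3

    def test_constraint_violation_signals(self, monkeypatch):
        import ehld_records.bayes as bayes_mod

        monkeypatch.setattr(bayes_mod, "prior_radicand", lambda *a, **kw: -1.0)
        with pytest.raises(PriorConstraintError, match="constraint"):
            bayes_mod.noninformative_prior_density(
                EHLDParams(theta=1.0, lam=2.0), 10, "jeffreys"
            )

    def test_kind_validation(self):
        with pytest.raises(ValueError):
            noninformative_prior_density(EHLDParams(theta=1.0, lam=2.0), 10, "flat")
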