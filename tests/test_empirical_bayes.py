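"""Tests for prior estimation, the EM mixture fit, and the conjugate posteriors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ec50shrink import (
    MixturePrior,
    NormalPrior,
    PosteriorNormal,
    ShrinkageModel,
    estimate_prior_ml,
    estimate_prior_robust,
    fit_mixture_em,
    posterior_mixture,
    posterior_normal,
    posterior_point_and_interval,
)
from ec50shrink.empirical_bayes import MAD_NORMAL_FACTOR
from ec50shrink.synthetic import VPA_ETILDE_MIXTURE


def quadrature_posterior(x, sigma2, prior_pdf, lo, hi, n=20001):
    """Trapezoid-quadrature posterior mean/variance, independent of closed forms."""
    mu = np.linspace(lo, hi, n)
    unnorm = norm.pdf(x, loc=mu, scale=np.sqrt(sigma2)) * prior_pdf(mu)
    z = np.trapezoid(unnorm, mu)
    mean = np.trapezoid(mu * unnorm, mu) / z
    var = np.trapezoid((mu - mean) ** 2 * unnorm, mu) / z
    return mean, var


class TestNormalPriors:
    def test_ml_hand_example(self):
        prior = estimate_prior_ml([1, 2, 3, 4, 5])
        assert prior.mu0 == pytest.approx(3.0)
        assert prior.tau2 == pytest.approx(2.5)  # denominator n-1

    def test_ml_degenerate_and_short_inputs(self):
        with pytest.raises(ValueError):
            estimate_prior_ml([5, 5, 5])
        with pytest.raises(ValueError):
            estimate_prior_ml([5.0])
        with pytest.raises(ValueError):
            estimate_prior_ml([np.nan, np.inf, 1.0])

    def test_permutation_invariance(self):
        a = estimate_prior_ml([3.0, 1.5, 9.1, 2.2])
        b = estimate_prior_ml([9.1, 2.2, 3.0, 1.5])
        assert (a.mu0, a.tau2) == (b.mu0, b.tau2)

    def test_robust_hand_example(self):
        prior = estimate_prior_robust([1, 2, 3, 4, 100])
        assert prior.mu0 == pytest.approx(3.0)
        assert prior.tau2 == pytest.approx((MAD_NORMAL_FACTOR * 1.0) ** 2)

    def test_robust_breakdown(self):
        a = estimate_prior_robust([1, 2, 3, 4, 100])
        b = estimate_prior_robust([1, 2, 3, 4, 1e6])
        assert (a.mu0, a.tau2) == (b.mu0, b.tau2)

    def test_robust_consistency_for_normal(self):
        """(1.4826 * MAD)^2 estimates the variance of a normal sample."""
        rng = np.random.default_rng(123)
        v = rng.normal(0.0, 2.0, size=10**6)
        prior = estimate_prior_robust(v)
        assert prior.tau2 == pytest.approx(4.0, rel=0.02)

    def test_ml_robust_agree_on_normal_sample(self):
        rng = np.random.default_rng(5)
        v = rng.normal(6.2, 0.35, size=200_000)
        ml, rb = estimate_prior_ml(v), estimate_prior_robust(v)
        assert ml.mu0 == pytest.approx(rb.mu0, abs=0.01)
        assert ml.tau2 == pytest.approx(rb.tau2, rel=0.02)

    def test_non_finite_entries_dropped(self):
        prior = estimate_prior_ml([1, 2, 3, 4, 5, np.nan, np.inf])
        assert prior.mu0 == pytest.approx(3.0)


class TestMixtureEM:
    def test_k1_closed_form(self):
        v = np.array([1.0, 2.0, 3.0, 6.0])
        mix = fit_mixture_em(v, k=1)
        assert mix.success
        assert mix.weights[0] == pytest.approx(1.0)
        assert mix.means[0] == pytest.approx(v.mean())
        assert mix.variances[0] == pytest.approx(v.var())  # ML variance, /n

    def test_planted_two_component_recovery(self):
        rng = np.random.default_rng(99)
        v = np.concatenate([rng.normal(0, 1, 1000), rng.normal(8, 1, 1000)])
        init = {"weights": (0.5, 0.5), "means": (1.0, 7.0), "sds": (2.0, 2.0)}
        mix = fit_mixture_em(v, k=2, init=init)
        assert mix.success
        order = np.argsort(mix.means)
        np.testing.assert_allclose(mix.means[order], [0.0, 8.0], atol=0.15)
        np.testing.assert_allclose(mix.weights[order], [0.5, 0.5], atol=0.05)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 2, 300)])
        mix = fit_mixture_em(v, k=3)
        assert mix.success
        assert np.all(np.diff(mix.loglik_trace) >= -1e-9)

    def test_init_stability_on_separated_mixture(self):
        """Two valid inits reach the same log-likelihood on an easy problem."""
        rng = np.random.default_rng(17)
        v = np.concatenate([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        m1 = fit_mixture_em(v, k=2, init={"weights": (0.5, 0.5), "means": (-1, 11), "sds": (1.5, 1.5)})
        m2 = fit_mixture_em(v, k=2, init={"weights": (0.3, 0.7), "means": (2, 8), "sds": (3, 3)})
        assert abs(m1.loglik - m2.loglik) < 1e-3

    def test_cross_check_against_sklearn(self):
        """Final log-likelihood matches scikit-learn's GaussianMixture."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(11)
        v = np.concatenate([rng.normal(6.2, 0.35, 700), rng.normal(7.5, 1.4, 300)])
        mix = fit_mixture_em(v, k=2, tol=1e-10)
        gm = GaussianMixture(
            n_components=2, covariance_type="spherical", tol=1e-10,
            max_iter=2000, means_init=np.sort(mix.means)[:, None],
            weights_init=mix.weights[np.argsort(mix.means)],
            precisions_init=1.0 / mix.variances[np.argsort(mix.means)],
        ).fit(v[:, None])
        assert mix.loglik / v.size == pytest.approx(gm.score(v[:, None]), abs=1e-6)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        mix = fit_mixture_em(rng.normal(0, 1, 500), k=5)
        assert mix.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bad_init_length_raises(self):
        with pytest.raises(ValueError):
            fit_mixture_em(np.arange(50.0), k=5,
                           init={"weights": (1.0,), "means": (0.0,), "sds": (1.0,)})


class TestPosteriorNormal:
    def test_equal_precision_case(self):
        prior = NormalPrior(0.0, 1.0)
        post = posterior_normal(2.0, 1.0, prior)
        assert post.mean == pytest.approx(1.0)
        assert post.variance == pytest.approx(0.5)

    def test_hand_example_and_quadrature(self):
        prior = NormalPrior(0.0, 3.0)
        post = posterior_normal(2.0, 1.0, prior)
        assert post.mean == pytest.approx(1.5)
        assert post.variance == pytest.approx(0.75)
        qmean, qvar = quadrature_posterior(
            2.0, 1.0, lambda mu: norm.pdf(mu, 0.0, np.sqrt(3.0)), -20, 22
        )
        assert post.mean == pytest.approx(qmean, abs=1e-8)
        assert post.variance == pytest.approx(qvar, abs=1e-8)

    def test_shrinkage_limits(self):
        prior = NormalPrior(0.0, 1.0)
        assert posterior_normal(5.0, 1e-12, prior).mean == pytest.approx(5.0, abs=1e-6)
        assert posterior_normal(5.0, 1e12, prior).mean == pytest.approx(0.0, abs=1e-6)

    def test_invalid_inputs(self):
        prior = NormalPrior(0.0, 1.0)
        with pytest.raises(ValueError):
            posterior_normal(1.0, 0.0, prior)
        with pytest.raises(ValueError):
            posterior_normal(np.nan, 1.0, prior)
        with pytest.raises(ValueError):
            NormalPrior(0.0, 0.0)

    @given(
        x=st.floats(-20, 20),
        mu0=st.floats(-5, 5),
        sigma2=st.floats(1e-3, 50),
        tau2=st.floats(1e-3, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_shrinkage_geometry(self, x, mu0, sigma2, tau2):
        """Posterior mean lies weakly between x and the prior mean."""
        post = posterior_normal(x, sigma2, NormalPrior(mu0, tau2))
        assert abs(post.mean - mu0) <= abs(x - mu0) + 1e-12
        assert min(x, mu0) - 1e-12 <= post.mean <= max(x, mu0) + 1e-12

    def test_posterior_mean_increasing_in_x(self):
        prior = NormalPrior(1.0, 2.0)
        means = [posterior_normal(x, 0.5, prior).mean for x in np.linspace(-5, 5, 30)]
        assert np.all(np.diff(means) > 0)


class TestPosteriorMixture:
    @staticmethod
    def vpa_prior():
        return MixturePrior(
            weights=np.array(VPA_ETILDE_MIXTURE["weights"]) / np.sum(VPA_ETILDE_MIXTURE["weights"]),
            means=np.array(VPA_ETILDE_MIXTURE["means"]),
            variances=np.array(VPA_ETILDE_MIXTURE["sds"]) ** 2,
            loglik=0.0,
            n_iter=0,
        )

    def test_single_component_reduces_to_normal(self):
        prior = MixturePrior(
            weights=np.array([1.0]), means=np.array([0.5]),
            variances=np.array([2.0]), loglik=0.0, n_iter=0,
        )
        post = posterior_mixture(3.0, 1.0, prior)
        ref = posterior_normal(3.0, 1.0, NormalPrior(0.5, 2.0))
        assert post.mean == pytest.approx(ref.mean, abs=1e-12)
        assert post.variances[0] == pytest.approx(ref.variance, abs=1e-12)

    def test_degenerate_weights_match_component(self):
        prior = MixturePrior(
            weights=np.array([1.0, 0.0]), means=np.array([0.5, 9.0]),
            variances=np.array([2.0, 1.0]), loglik=0.0, n_iter=0,
        )
        post = posterior_mixture(3.0, 1.0, prior)
        ref = posterior_normal(3.0, 1.0, NormalPrior(0.5, 2.0))
        assert post.mean == pytest.approx(ref.mean, abs=1e-12)

    def test_quadrature_oracle_case_study_prior(self):
        """Posterior mean under the case-study mixture prior vs quadrature."""
        prior = self.vpa_prior()

        def pdf(mu):
            return sum(
                w * norm.pdf(mu, m, np.sqrt(v))
                for w, m, v in zip(prior.weights, prior.means, prior.variances)
            )

        post = posterior_mixture(6.0, 0.04, prior)
        qmean, qvar = quadrature_posterior(6.0, 0.04, pdf, -400, 450, n=400001)
        assert post.mean == pytest.approx(qmean, abs=1e-8)
        assert float(post.weights @ (post.variances + post.means**2) - post.mean**2) \
            == pytest.approx(qvar, abs=1e-8)

    def test_weights_normalised_random_inputs(self):
        rng = np.random.default_rng(8)
        prior = self.vpa_prior()
        for _ in range(50):
            post = posterior_mixture(rng.normal(7, 3), rng.uniform(0.01, 2), prior)
            assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_posterior_mean_increasing_in_x(self):
        prior = self.vpa_prior()
        means = [posterior_mixture(x, 0.3, prior).mean for x in np.linspace(2, 12, 60)]
        assert np.all(np.diff(means) > 0)


class TestPointAndInterval:
    def test_standard_normal_interval(self):
        pt, lo, up = posterior_point_and_interval(PosteriorNormal(0.0, 1.0), 0.95)
        assert pt == 0.0
        assert lo == pytest.approx(-1.959963985, abs=1e-8)
        assert up == pytest.approx(1.959963985, abs=1e-8)

    def test_single_component_mixture_matches_normal(self):
        from ec50shrink import PosteriorMixture

        post_m = PosteriorMixture(
            weights=np.array([1.0]), means=np.array([1.5]), variances=np.array([0.75])
        )
        pt_m, lo_m, up_m = posterior_point_and_interval(post_m, 0.9)
        pt_n, lo_n, up_n = posterior_point_and_interval(PosteriorNormal(1.5, 0.75), 0.9)
        assert (pt_m, lo_m, up_m) == pytest.approx((pt_n, lo_n, up_n), abs=1e-8)

    def test_mixture_endpoints_invert_cdf(self):
        prior = TestPosteriorMixture.vpa_prior()
        post = posterior_mixture(6.5, 0.2, prior)
        _, lo, up = posterior_point_and_interval(post, 0.95)
        assert post.cdf(lo) == pytest.approx(0.025, abs=1e-8)
        assert post.cdf(up) == pytest.approx(0.975, abs=1e-8)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            posterior_point_and_interval(PosteriorNormal(0, 1), 1.0)


class TestShrinkageModel:
    def test_fit_table_roundtrip_and_geometry(self):
        rng = np.random.default_rng(21)
        e = rng.normal(6.2, 0.35, 80)
        se = rng.uniform(0.05, 0.5, 80)
        model = ShrinkageModel(e, se)
        res = model.fit(prior="ml")
        mu0 = res.prior.mu0
        shrunk = res.point
        # every posterior mean between the direct estimate and the prior mean
        assert np.all(np.abs(shrunk - mu0) <= np.abs(e - mu0) + 1e-12)
        # larger-se genes shrink more (top vs bottom se decile)
        shift = np.abs(shrunk - e)
        hi, lo = se >= np.quantile(se, 0.9), se <= np.quantile(se, 0.1)
        assert shift[hi].mean() > shift[lo].mean()

    def test_non_converged_genes_excluded(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "e_tilde": [6.0, 6.5, 40.0, 6.2],
                "se_e_tilde": [0.1, 0.2, 5.0, 0.15],
                "converged": [True, True, False, True],
            }
        )
        model = ShrinkageModel.from_fit_table(table)
        prior = model.estimate_prior("ml")
        assert prior.mu0 == pytest.approx(np.mean([6.0, 6.5, 6.2]))
        res = model.fit(prior="ml")
        assert np.isnan(res.point[2]) and np.isfinite(res.point).sum() == 3

    def test_summary_mentions_prior(self):
        rng = np.random.default_rng(4)
        model = ShrinkageModel(rng.normal(6, 1, 60), rng.uniform(0.1, 0.3, 60))
        assert "mu0" in model.fit(prior="robust").summary()
        assert "mixture" in model.fit(prior="mixture").summary()
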