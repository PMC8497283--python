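"""Posterior inference: conjugacy, resampling, exact oracle, predictive counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scarbayes import (
    ArmCounts,
    BetaParams,
    Margins,
    conjugate_update,
    posterior_predictive,
    prob_less_exact,
    sample_difference,
    summarize_posterior,
)

# closed form for Beta(1,8) vs Beta(3,10): 1 - E[(1-Y)^8], 1-Y ~ Beta(10,3)
P_LESS_18_310 = 1.0 - (10 * 11 * 12) / (18 * 19 * 20)

shapes = st.floats(min_value=0.5, max_value=60.0)


class TestConjugateUpdate:
    @pytest.mark.parametrize(
        "prior,counts,expected",
        [
            ((1, 1), (0, 7), (1, 8)),
            ((1, 1), (2, 11), (3, 10)),
            ((6, 12), (0, 7), (6, 19)),
            ((18, 127), (0, 7), (18, 134)),
        ],
    )
    def test_adds_events_and_nonevents(self, prior, counts, expected):
        got = conjugate_update(BetaParams(*prior), ArmCounts(*counts))
        assert got.as_tuple() == expected

    @given(
        a=shapes, b=shapes,
        events=st.integers(1, 19), n=st.just(20),
    )
    @settings(derandomize=True, max_examples=100)
    def test_posterior_mean_between_prior_mean_and_data(self, a, b, events, n):
        """Conjugacy sandwich: the posterior mean interpolates prior and data."""
        prior = BetaParams(a, b)
        post = conjugate_update(prior, ArmCounts(events, n))
        lo, hi = sorted((prior.mean, events / n))
        assert lo <= post.mean <= hi


class TestProbLessExact:
    def test_closed_form_example(self):
        assert prob_less_exact(BetaParams(1, 8), BetaParams(3, 10)) == pytest.approx(
            P_LESS_18_310, abs=1e-10
        )

    @pytest.mark.parametrize("params", [(1, 1), (2, 2), (3.5, 1.2)])
    def test_identical_distributions_give_half(self, params):
        b = BetaParams(*params)
        assert prob_less_exact(b, b) == pytest.approx(0.5, abs=1e-8)

    def test_quadrature_agrees_with_summation(self):
        # integer-shape pair evaluated by both routes
        x, y = BetaParams(2.0, 5.0), BetaParams(4.0, 3.0)
        by_sum = prob_less_exact(x, y)
        # perturb shapes infinitesimally off-integer to force the quadrature path
        eps = 1e-9
        by_quad = prob_less_exact(
            BetaParams(2.0 + eps, 5.0 + eps), BetaParams(4.0 + eps, 3.0 + eps)
        )
        assert by_quad == pytest.approx(by_sum, abs=1e-6)

    def test_complement_identity(self):
        x, y = BetaParams(1, 8), BetaParams(3, 10)
        assert prob_less_exact(x, y) + prob_less_exact(y, x) == pytest.approx(
            1.0, abs=1e-10
        )


class TestSampleDifference:
    def test_reproducible_and_consistent(self):
        a, b = BetaParams(1, 8), BetaParams(3, 10)
        d1 = sample_difference(a, b, n_draws=1000, seed=42)
        d2 = sample_difference(a, b, n_draws=1000, seed=42)
        np.testing.assert_array_equal(d1.diff_samples, d2.diff_samples)
        np.testing.assert_array_equal(
            d1.diff_samples, d1.treat_samples - d1.control_samples
        )

    def test_invalid_draw_count(self):
        with pytest.raises(ValueError):
            sample_difference(BetaParams(1, 1), BetaParams(1, 1), n_draws=0)

    def test_symmetric_posteriors_split_at_zero(self):
        b = BetaParams(3, 10)
        d = sample_difference(b, b, n_draws=100_000, seed=7)
        p = np.mean(d.diff_samples < 0)
        assert p == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 100_000))

    def test_concentrated_posteriors_concentrate_difference(self):
        b = BetaParams(1e6, 1e6)
        d = sample_difference(b, b, n_draws=10_000, seed=3)
        assert abs(d.diff_samples.mean()) < 0.01
        assert d.diff_samples.std() < 0.01

    @pytest.mark.parametrize(
        "ax,bx,ay,by,seed",
        [(1, 8, 3, 10, 11), (5, 5, 2, 9, 12), (12.5, 3.5, 4, 20, 13), (2, 2, 7, 3, 14)],
    )
    def test_monte_carlo_matches_exact_oracle(self, ax, bx, ay, by, seed):
        """Resampled P(diff < 0) agrees with the closed-form/quadrature oracle."""
        x, y = BetaParams(ax, bx), BetaParams(ay, by)
        n = 200_000
        d = sample_difference(x, y, n_draws=n, seed=seed)
        p_mc = np.mean(d.diff_samples < 0)
        p_exact = prob_less_exact(x, y)
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(p_mc - p_exact) < 3 * se

    @pytest.mark.parametrize("m", [0.0, -0.1, 0.15])
    def test_arm_swap_antisymmetry(self, m):
        """P(A-B < m) == 1 - P(B-A < -m) up to Monte-Carlo error."""
        a, b = BetaParams(2, 9), BetaParams(6, 7)
        n = 200_000
        p_ab = np.mean(sample_difference(a, b, n, seed=21).diff_samples < m)
        p_ba = np.mean(sample_difference(b, a, n, seed=22).diff_samples < -m)
        assert p_ab == pytest.approx(1 - p_ba, abs=3 * np.sqrt(0.5 / n))


class TestSummarizePosterior:
    def _draws(self, values):
        from scarbayes import PosteriorDraws

        v = np.asarray(values, dtype=float)
        return PosteriorDraws(v, np.zeros_like(v), v, len(v), seed=0)

    def test_constant_draws(self):
        s = summarize_posterior(self._draws([-0.3] * 100), margins=(0.0, -0.2))
        assert s.median_diff == -0.3
        assert (s.ci_low, s.ci_high) == (-0.3, -0.3)
        assert s.prob_below[0.0] == 1.0
        assert s.prob_below[-0.2] == 1.0
        assert s.prob_between_margin_and_zero == 0.0

    def test_matches_exact_probability(self):
        d = sample_difference(BetaParams(1, 8), BetaParams(3, 10), 200_000, seed=5)
        s = summarize_posterior(d, margins=(0.0,))
        se = s.mc_se[0.0]
        assert s.prob_below[0.0] == pytest.approx(P_LESS_18_310, abs=3 * se)

    def test_prob_below_monotone_in_margin(self):
        d = sample_difference(BetaParams(2, 5), BetaParams(4, 4), 50_000, seed=9)
        s = summarize_posterior(d, margins=(-0.4, -0.2, 0.0, 0.2))
        probs = [s.prob_below[m] for m in (-0.4, -0.2, 0.0, 0.2)]
        assert probs == sorted(probs)

    def test_wider_level_nests_interval(self):
        d = sample_difference(BetaParams(2, 5), BetaParams(4, 4), 50_000, seed=9)
        s80 = summarize_posterior(d, margins=(0.0,), level=0.80)
        s95 = summarize_posterior(d, margins=(0.0,), level=0.95)
        assert s95.ci_low <= s80.ci_low <= s80.ci_high <= s95.ci_high

    def test_empty_margins_error(self):
        d = sample_difference(BetaParams(1, 1), BetaParams(1, 1), 100, seed=1)
        with pytest.raises(ValueError):
            summarize_posterior(d, margins=())

    def test_margin_outside_range_rejected(self):
        with pytest.raises(ValueError):
            Margins((1.5,))


class TestPosteriorPredictive:
    @pytest.mark.parametrize(
        "alpha,beta,n,median",
        [(3, 10, 11, 2), (1, 8, 7, 0)],
    )
    def test_exact_medians(self, alpha, beta, n, median):
        s = posterior_predictive(BetaParams(alpha, beta), n)
        assert s.median_events == median

    def test_zero_future_subjects(self):
        s = posterior_predictive(BetaParams(5, 5), 0)
        assert (s.median_events, s.interval_low, s.interval_high) == (0, 0, 0)

    def test_negative_future_errors(self):
        with pytest.raises(ValueError):
            posterior_predictive(BetaParams(1, 1), -1)

    def test_interval_ordering_and_bounds(self):
        s = posterior_predictive(BetaParams(62, 141), 11)
        assert 0 <= s.interval_low <= s.median_events <= s.interval_high <= 11

    @given(a=shapes, b=shapes, n=st.integers(1, 40))
    @settings(derandomize=True, max_examples=100)
    def test_pmf_normalization(self, a, b, n):
        """The beta-binomial predictive pmf sums to one over its support."""
        total = stats.betabinom.pmf(np.arange(n + 1), n, a, b).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_median_definition_against_cdf(self):
        post = BetaParams(3, 10)
        cdf = stats.betabinom.cdf(np.arange(12), 11, 3, 10)
        k = int(np.argmax(cdf >= 0.5))
        assert posterior_predictive(post, 11).median_events == k
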