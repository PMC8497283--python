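"""Posterior inference for the difference in event proportions.

The model is two independent beta-binomial arms: each arm's scar
proportion carries a Beta prior, is updated conjugately with the observed
events, and the posterior of the difference pi_treat - pi_control is
obtained by resampling — independent Monte-Carlo draws from each arm's
Beta posterior, differenced elementwise.  Summaries are the empirical
median, equal-tailed credible interval, and the probability that the
difference falls below clinical margins (0 = any benefit, -0.2 = at least
a 20-point absolute reduction).

Posterior predictive event counts for a future arm of given size follow
the beta-binomial distribution and are computed exactly from its pmf.

``prob_less_exact`` is a deterministic closed-form/quadrature oracle for
P(X < Y) between two Beta variables, kept independent of the sampling
path so the two can validate each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, special, stats

from .priors import ArmCounts, BetaParams

__all__ = [
    "TrialData",
    "PosteriorDraws",
    "Margins",
    "PosteriorSummary",
    "PredictiveSummary",
    "conjugate_update",
    "sample_difference",
    "prob_less_exact",
    "summarize_posterior",
    "posterior_predictive",
]

DEFAULT_MARGINS = (0.0, -0.2)


@dataclass(frozen=True)
class TrialData:
    """Observed per-arm counts of the current trial."""

    treat: ArmCounts
    control: ArmCounts


@dataclass(frozen=True)
class Margins:
    """Clinical margins on the difference in proportions, each in (-1, 1)."""

    margins: tuple[float, ...] = DEFAULT_MARGINS

    def __post_init__(self) -> None:
        object.__setattr__(self, "margins", tuple(float(m) for m in self.margins))
        for m in self.margins:
            if not -1.0 < m < 1.0:
                raise ValueError(f"margin must be in (-1, 1), got {m}")


@dataclass(frozen=True)
class PosteriorDraws:
    """Monte-Carlo draws of the per-arm proportions and their difference."""

    treat_samples: np.ndarray
    control_samples: np.ndarray
    diff_samples: np.ndarray
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        if not (
            len(self.treat_samples)
            == len(self.control_samples)
            == len(self.diff_samples)
            == self.n_draws
        ):
            raise ValueError("sample arrays must all have length n_draws")


@dataclass(frozen=True)
class PosteriorSummary:
    """Median, equal-tailed credible interval and margin probabilities."""

    median_diff: float
    ci_low: float
    ci_high: float
    level: float
    prob_below: Mapping[float, float]
    prob_between_margin_and_zero: float | None
    mc_se: Mapping[float, float]

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median_diff <= self.ci_high:
            raise ValueError("credible interval must bracket the median")


@dataclass(frozen=True)
class PredictiveSummary:
    """Exact beta-binomial predictive median and central interval."""

    n_future: int
    median_events: int
    interval_low: int
    interval_high: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.interval_low <= self.median_events <= self.interval_high <= self.n_future:
            raise ValueError("predictive summary ordering violated")


def conjugate_update(prior: BetaParams, counts: ArmCounts) -> BetaParams:
    """Beta-binomial conjugate update: add events to alpha, non-events to beta."""
    return BetaParams(prior.alpha + counts.events, prior.beta + counts.nonevents)


def sample_difference(
    treat_post: BetaParams,
    control_post: BetaParams,
    n_draws: int = 200_000,
    seed: int = 20210525,
) -> PosteriorDraws:
    """Independent Beta draws per arm; the difference is treat minus control."""
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    t = rng.beta(treat_post.alpha, treat_post.beta, size=n_draws)
    c = rng.beta(control_post.alpha, control_post.beta, size=n_draws)
    return PosteriorDraws(
        treat_samples=t,
        control_samples=c,
        diff_samples=t - c,
        n_draws=n_draws,
        seed=seed,
    )


def _prob_greater_int_alpha(a1: float, b1: float, a2: float, b2: float) -> float:
    """P(X1 > X2) for X_i ~ Beta(a_i, b_i) when a1 is a positive integer.

    Finite-sum identity, evaluated in log space:
    sum_{i=0}^{a1-1} B(a2+i, b1+b2) / [(b1+i) B(1+i, b1) B(a2, b2)].
    """
    i = np.arange(int(a1))
    log_terms = (
        special.betaln(a2 + i, b1 + b2)
        - np.log(b1 + i)
        - special.betaln(1 + i, b1)
        - special.betaln(a2, b2)
    )
    return float(np.sum(np.exp(log_terms)))


_MAX_SUM_TERMS = 20_000


def prob_less_exact(x: BetaParams, y: BetaParams, *, atol: float = 1e-8) -> float:
    """Exact P(X < Y) for independent X ~ Beta(ax, bx), Y ~ Beta(ay, by).

    When one of the four shapes is a (moderate) positive integer, a
    closed-form finite sum is used; otherwise deterministic quadrature of
    the Beta CDF of X against the density of Y, to absolute tolerance
    ``atol``.  Ties have probability zero.
    """
    ax, bx = x.alpha, x.beta
    ay, by = y.alpha, y.beta

    def usable(v: float) -> bool:
        return float(v).is_integer() and 1 <= v <= _MAX_SUM_TERMS

    # Four equivalent reductions to the integer-alpha identity:
    #   P(X<Y) = P(Y>X);  1-X ~ Beta(bx, ax) turns bx/by into alpha shapes.
    candidates = [
        (ay, lambda: _prob_greater_int_alpha(ay, by, ax, bx)),
        (ax, lambda: 1.0 - _prob_greater_int_alpha(ax, bx, ay, by)),
        (bx, lambda: _prob_greater_int_alpha(bx, ax, by, ay)),
        (by, lambda: 1.0 - _prob_greater_int_alpha(by, ay, bx, ax)),
    ]
    usable_candidates = [(v, f) for v, f in candidates if usable(v)]
    if usable_candidates:
        _, f = min(usable_candidates, key=lambda vf: vf[0])
        return min(max(f(), 0.0), 1.0)

    val, err = integrate.quad(
        lambda t: stats.beta.cdf(t, ax, bx) * stats.beta.pdf(t, ay, by),
        0.0,
        1.0,
        epsabs=atol / 10,
        limit=200,
    )
    if err > atol:
        raise RuntimeError(
            f"P(X<Y) quadrature did not reach atol={atol}: error estimate {err:.2e}"
        )
    return min(max(val, 0.0), 1.0)


def summarize_posterior(
    draws: PosteriorDraws,
    margins: Margins | Sequence[float] = DEFAULT_MARGINS,
    level: float = 0.95,
) -> PosteriorSummary:
    """Empirical summary of the difference draws.

    Median and equal-tailed interval use linear-interpolation (type-7)
    quantiles.  ``prob_below[m]`` is the fraction of draws strictly below
    margin ``m`` with its binomial Monte-Carlo standard error; when both 0
    and -0.2 are among the margins, the probability of a reduction of up
    to 20 points, P(-0.2 < diff < 0), is reported as their difference.
    """
    if not isinstance(margins, Margins):
        margins = Margins(tuple(margins))
    if not margins.margins:
        raise ValueError("at least one margin is required")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    d = draws.diff_samples
    if d.size == 0:
        raise ValueError("draws are empty")
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    ci_low, median, ci_high = np.quantile(d, [lo_q, 0.5, hi_q])
    prob_below = {}
    mc_se = {}
    for m in margins.margins:
        p = float(np.mean(d < m))
        prob_below[m] = p
        mc_se[m] = math.sqrt(p * (1.0 - p) / draws.n_draws)
    between = None
    if 0.0 in prob_below and -0.2 in prob_below:
        between = prob_below[0.0] - prob_below[-0.2]
    return PosteriorSummary(
        median_diff=float(median),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        level=level,
        prob_below=prob_below,
        prob_between_margin_and_zero=between,
        mc_se=mc_se,
    )


def posterior_predictive(
    post: BetaParams, n_future: int, level: float = 0.95
) -> PredictiveSummary:
    """Exact beta-binomial predictive count summary for a future arm.

    median = smallest k with CDF(k) >= 0.5; the central interval is
    [largest k with CDF(k-1) <= (1-level)/2, smallest k with
    CDF(k) >= 1-(1-level)/2].
    """
    if n_future < 0:
        raise ValueError(f"n_future must be >= 0, got {n_future}")
    if n_future == 0:
        return PredictiveSummary(0, 0, 0, 0, level)
    k = np.arange(n_future + 1)
    cdf = stats.betabinom.cdf(k, n_future, post.alpha, post.beta)
    tail = (1.0 - level) / 2.0
    median = int(np.searchsorted(cdf, 0.5))
    low_candidates = k[np.concatenate(([True], cdf[:-1] <= tail))]
    low = int(low_candidates[-1])
    high = int(np.searchsorted(cdf, 1.0 - tail))
    return PredictiveSummary(
        n_future=n_future,
        median_events=median,
        interval_low=min(low, median),
        interval_high=max(high, median),
        level=level,
    )
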