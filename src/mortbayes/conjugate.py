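"""Conjugate beta-binomial inference for survey death rates.

Each person-day at risk is treated as one Bernoulli trial with death
probability ``p``.  A Beta(alpha, beta) prior on ``p`` combined with
``d`` deaths over ``T`` person-days yields the posterior
Beta(alpha + d, beta + T - d); fractional person-days are accepted since
the update extends continuously.  Posterior summaries are the mean, the
highest-density interval (HDI: the shortest interval carrying a given
probability mass) and exceedance probabilities against emergency
thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import InvalidInputError
from .priors import BetaPrior
from .rates import SurveyObservation
from .units import prob_to_rate, rate_to_prob


@dataclass(frozen=True)
class PosteriorRate:
    """Posterior beta shapes plus rate-scale summaries.

    ``alpha_post = alpha + d`` and ``beta_post = beta + T - d``; the
    summaries (mean and HDI bounds) are in deaths/10,000/day.
    """

    alpha_post: float
    beta_post: float
    mean_rate: float
    hdi_low: float
    hdi_high: float
    hdi_mass: float = 0.95

    def exceedance(self, threshold_rate: float) -> float:
        return exceedance_probability(self, threshold_rate)

    def density_rate(self, rates: np.ndarray) -> np.ndarray:
        """Posterior density on the rate scale (for plotting)."""
        p = rate_to_prob(np.asarray(rates, dtype=float))
        return stats.beta.pdf(p, self.alpha_post, self.beta_post) / 10_000.0


def hdi(alpha: float, beta: float, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval of Beta(alpha, beta), in deaths/10,000/day.

    Among all intervals carrying probability ``mass`` this is the one of
    minimal width.  The width ``Q(w + mass) - Q(w)`` is minimised over the
    lower-tail mass ``w`` with bounded scalar optimisation (``Q`` is the
    beta quantile function) — exact for unimodal densities and free of
    sampling noise.  For monotone densities (``alpha <= 1`` decreasing at
    0, ``beta <= 1`` increasing at 1) the interval is anchored at the
    corresponding support boundary.
    """
    if not (math.isfinite(alpha) and math.isfinite(beta) and alpha > 0 and beta > 0):
        raise InvalidInputError(f"beta shapes must be positive finite, got ({alpha}, {beta})")
    if not 0 < mass < 1:
        raise InvalidInputError(f"mass must be in (0, 1), got {mass}")

    if alpha <= 1 and beta <= 1 and not (alpha == 1 and beta == 1):
        # bathtub-shaped (or one-sided monotone with the other shape == 1):
        # compare the two boundary-anchored candidates
        lo_anchor = (0.0, float(stats.beta.ppf(mass, alpha, beta)))
        hi_anchor = (float(stats.beta.ppf(1 - mass, alpha, beta)), 1.0)
        lo, hi = min((lo_anchor, hi_anchor), key=lambda iv: iv[1] - iv[0])
        return prob_to_rate(lo), prob_to_rate(hi)
    if alpha <= 1:  # mode at 0, density decreasing
        return 0.0, prob_to_rate(float(stats.beta.ppf(mass, alpha, beta)))
    if beta <= 1:  # mode at 1, density increasing
        return prob_to_rate(float(stats.beta.ppf(1 - mass, alpha, beta))), prob_to_rate(1.0)

    def width(w: float) -> float:
        return stats.beta.ppf(w + mass, alpha, beta) - stats.beta.ppf(w, alpha, beta)

    res = optimize.minimize_scalar(width, bounds=(0.0, 1.0 - mass),
                                   method="bounded", options={"xatol": 1e-10})
    w = float(res.x)
    # fall back to boundary-anchored interval when the optimum is pinned
    if width(0.0) <= res.fun:
        w = 0.0
    elif width(1.0 - mass) <= res.fun:
        w = 1.0 - mass
    lo = float(stats.beta.ppf(w, alpha, beta))
    hi = float(stats.beta.ppf(w + mass, alpha, beta))
    return prob_to_rate(lo), prob_to_rate(hi)


def posterior_update(prior: BetaPrior, obs: SurveyObservation,
                     hdi_mass: float = 0.95) -> PosteriorRate:
    """Conjugate update of a beta prior with one survey's (d, T).

    The posterior mean always lies between the prior mean and the
    observed rate (shrinkage with data weight ``T / (alpha + beta + T)``).
    """
    a_post = prior.alpha + obs.deaths
    b_post = prior.beta + obs.person_days - obs.deaths
    mean_rate = prob_to_rate(a_post / (a_post + b_post))
    lo, hi = hdi(a_post, b_post, hdi_mass)
    return PosteriorRate(alpha_post=a_post, beta_post=b_post, mean_rate=mean_rate,
                         hdi_low=lo, hdi_high=hi, hdi_mass=hdi_mass)


def exceedance_probability(posterior: PosteriorRate, threshold_rate: float) -> float:
    """Posterior probability that the rate exceeds ``threshold_rate``.

    ``P(r > tau) = 1 - F_Beta(tau / 10,000; alpha', beta')``; strict and
    non-strict versions coincide for a continuous posterior.
    """
    if threshold_rate < 0:
        raise InvalidInputError(f"threshold must be non-negative, got {threshold_rate}")
    return float(stats.beta.sf(rate_to_prob(threshold_rate),
                               posterior.alpha_post, posterior.beta_post))


class GridPosterior:
    """Discretised posterior on a uniform probability grid (test oracle).

    Multiplies the prior density by the binomial likelihood pointwise (in
    logs, for stability) and normalises by trapezoidal quadrature.  Serves
    as an independent check of the conjugate closed form; it is never the
    production path.
    """

    def __init__(self, grid: np.ndarray, density: np.ndarray):
        self.grid = grid
        self.density = density

    def _integrate(self, values: np.ndarray) -> float:
        return float(np.trapezoid(values, self.grid))

    @property
    def total_mass(self) -> float:
        return self._integrate(self.density)

    def mean(self) -> float:
        """Posterior mean of p (probability scale)."""
        return self._integrate(self.grid * self.density)

    def variance(self) -> float:
        m = self.mean()
        return self._integrate((self.grid - m) ** 2 * self.density)

    def mean_rate(self) -> float:
        return prob_to_rate(self.mean())

    def exceedance(self, threshold_rate: float) -> float:
        """P(rate > threshold) by quadrature over the grid."""
        tau = rate_to_prob(threshold_rate)
        above = self.grid >= tau
        if not above.any():
            return 0.0
        x = np.concatenate(([tau], self.grid[above]))
        y = np.concatenate(([np.interp(tau, self.grid, self.density)],
                            self.density[above]))
        return float(np.trapezoid(y, x))


def grid_posterior(prior: BetaPrior, obs: SurveyObservation,
                   grid_points: int = 200_001, p_max: float = 1.0) -> GridPosterior:
    """Numerical posterior for (prior, observation) on a uniform grid.

    ``p_max`` may truncate the grid to the region carrying the posterior
    mass (rates of a few per 10,000/day live at p ~ 1e-4); the density is
    renormalised on the truncated support.
    """
    if grid_points < 1_000:
        raise InvalidInputError(f"grid_points must be >= 1000, got {grid_points}")
    if not 0 < p_max <= 1:
        raise InvalidInputError(f"p_max must be in (0, 1], got {p_max}")
    grid = np.linspace(0.0, p_max, grid_points)
    d, T = obs.deaths, obs.person_days
    with np.errstate(divide="ignore", invalid="ignore"):
        log_prior = stats.beta.logpdf(grid, prior.alpha, prior.beta)
        log_lik = np.zeros_like(grid)
        if d > 0:
            log_lik += d * np.log(grid)  # -inf at p = 0
        if T - d > 0:
            log_lik += (T - d) * np.log1p(-grid)  # -inf at p = 1
        log_post = log_prior + log_lik
    log_post -= np.nanmax(log_post[np.isfinite(log_post)])
    density = np.exp(log_post)
    density[~np.isfinite(density)] = 0.0
    norm = np.trapezoid(density, grid)
    if norm <= 0:
        raise InvalidInputError("posterior mass underflowed on the requested grid")
    return GridPosterior(grid, density / norm)
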