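"""Beta prior elicitation from interpretable rate-scale constraints.

A prior belief about the daily death probability ``p`` is stated in the
units decision makers use: a mean rate (deaths/10,000/day) and one
percentile in the same units.  The classic examples are a *skeptical*
prior centred on the regional baseline with a small (e.g. 5%) prior
probability that the rate exceeds the emergency threshold, and a
*high-mortality* prior centred on an elevated rate with a small prior
probability that the rate is at or below baseline.

With the mean fixed at ``m``, the second beta shape is eliminated
analytically (``beta = alpha * (1 - m) / m``) and the percentile
constraint becomes a one-dimensional root problem in ``log alpha``,
solved with Brent's method on the branch where the beta CDF at the
constraint point is increasing in ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import BracketExhaustedError, InfeasibleSpecError, InvalidInputError
from .units import RATE_SCALE, prob_to_rate, rate_to_prob

# log-alpha search bracket; alpha spans orders of magnitude because the
# effective prior sample size alpha+beta reaches tens of thousands of
# person-days for rare-event rates
_LOG_ALPHA_BRACKET = (-10.0, 20.0)
_CDF_RESIDUAL_TOL = 1e-12


@dataclass(frozen=True)
class ElicitationSpec:
    """A mean-plus-percentile constraint pair on the death rate.

    ``mean_rate`` and ``quantile_rate`` are in deaths/10,000/day;
    ``quantile_level`` is the percentile being pinned (e.g. 0.95 for a
    skeptical prior whose 95th percentile sits at the emergency
    threshold).  The median (0.5) is rejected: the mean and median of a
    skewed beta differ, and a mean-median pair is not the intended use.
    """

    mean_rate: float
    quantile_level: float
    quantile_rate: float

    def __post_init__(self) -> None:
        if not self.mean_rate > 0:
            raise InvalidInputError(f"mean_rate must be positive, got {self.mean_rate}")
        if not self.mean_rate / RATE_SCALE < 1:
            raise InvalidInputError("mean_rate must correspond to a probability < 1")
        if not 0 < self.quantile_level < 1 or self.quantile_level == 0.5:
            raise InvalidInputError(
                f"quantile_level must be in (0,1) and != 0.5, got {self.quantile_level}")
        if not self.quantile_rate > 0:
            raise InvalidInputError(
                f"quantile_rate must be positive, got {self.quantile_rate}")
        if self.quantile_level > 0.5 and not self.quantile_rate > self.mean_rate:
            raise InfeasibleSpecError(
                f"an upper percentile ({self.quantile_level}) must lie above the "
                f"mean: {self.quantile_rate} <= {self.mean_rate}")
        if self.quantile_level < 0.5 and not self.quantile_rate < self.mean_rate:
            raise InfeasibleSpecError(
                f"a lower percentile ({self.quantile_level}) must lie below the "
                f"mean: {self.quantile_rate} >= {self.mean_rate}")


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior on the daily death probability.

    ``alpha + beta`` is the effective prior sample size in person-days:
    the amount of observed exposure the prior is worth.
    """

    alpha: float
    beta: float
    provenance: str = "reference"

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)
                and self.beta > 0 and math.isfinite(self.beta)):
            raise InvalidInputError(
                f"beta shapes must be positive and finite, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        """Prior mean of the daily death probability."""
        return self.alpha / (self.alpha + self.beta)

    @property
    def mean_rate(self) -> float:
        """Prior mean in deaths/10,000/day."""
        return prob_to_rate(self.mean)

    @property
    def effective_person_days(self) -> float:
        return self.alpha + self.beta

    def quantile_rate(self, level: float) -> float:
        """Prior quantile at ``level``, in deaths/10,000/day."""
        return prob_to_rate(stats.beta.ppf(level, self.alpha, self.beta))


def _cdf_residual(log_alpha: float, m: float, xq: float, q: float) -> float:
    alpha = math.exp(log_alpha)
    beta = alpha * (1.0 - m) / m
    return stats.beta.cdf(xq, alpha, beta) - q


def elicit_beta(spec: ElicitationSpec) -> BetaPrior:
    """Solve for the beta prior matching a mean and one percentile.

    The mean constraint fixes ``beta = alpha (1-m)/m`` exactly; Brent's
    method then finds ``alpha`` such that the beta CDF at the constraint
    point equals the requested level.

    For an upper percentile (``quantile_level > 0.5``) the CDF residual is
    not monotone over the whole bracket: it dips and then rises, and a
    second root exists at vanishing ``alpha`` where the prior degenerates
    into a two-point spike.  The solver brackets the increasing branch
    (from the residual's minimum upward) and returns the informative,
    larger-``alpha`` root, on which the CDF is strictly increasing in
    ``alpha`` and the root is unique.
    """
    m = rate_to_prob(spec.mean_rate)
    xq = rate_to_prob(spec.quantile_rate)
    q = spec.quantile_level
    lo, hi = _LOG_ALPHA_BRACKET

    if q > 0.5:
        res = optimize.minimize_scalar(_cdf_residual, bounds=(lo, hi), args=(m, xq, q),
                                       method="bounded", options={"xatol": 1e-10})
        if res.fun > 0:
            raise BracketExhaustedError(
                "no alpha satisfies the percentile constraint: the CDF residual "
                "never reaches zero", (math.exp(lo), math.exp(hi)))
        bracket = (float(res.x), hi)
    else:
        bracket = (lo, hi)

    f_lo = _cdf_residual(bracket[0], m, xq, q)
    f_hi = _cdf_residual(bracket[1], m, xq, q)
    if f_lo * f_hi > 0:
        raise BracketExhaustedError(
            "no sign change in the CDF residual over the search bracket",
            (math.exp(bracket[0]), math.exp(bracket[1])))

    log_alpha = optimize.brentq(_cdf_residual, bracket[0], bracket[1],
                                args=(m, xq, q), xtol=1e-13, maxiter=200)
    alpha = math.exp(log_alpha)
    beta = alpha * (1.0 - m) / m
    residual = stats.beta.cdf(xq, alpha, beta) - q
    if abs(residual) > math.sqrt(_CDF_RESIDUAL_TOL):
        raise BracketExhaustedError(
            f"root search converged poorly (CDF residual {residual:.2e})",
            (math.exp(bracket[0]), math.exp(bracket[1])))

    prior = BetaPrior(alpha=alpha, beta=beta,
                      provenance=(f"elicited: mean={spec.mean_rate} deaths/10,000/day, "
                                  f"P{100 * q:g}={spec.quantile_rate}"))
    # elicitation contract: both constraints reproduced to 1e-6 relative
    assert abs(prior.mean_rate - spec.mean_rate) <= 1e-6 * spec.mean_rate
    q_check = prior.quantile_rate(q)
    if abs(q_check - spec.quantile_rate) > 1e-6 * spec.quantile_rate:
        raise BracketExhaustedError(
            f"elicited prior reproduces the quantile only to {q_check:.6g} "
            f"(target {spec.quantile_rate})", (alpha, alpha))
    return prior


def reference_priors() -> dict[str, BetaPrior]:
    """Weakly-informative reference priors for sensitivity spreads.

    ``flat`` is Beta(1, 1) (uniform on the probability); ``jeffreys`` is
    Beta(1/2, 1/2).  Both are dominated by even small surveys and anchor
    the data-driven end of a community-of-priors report.
    """
    return {
        "flat": BetaPrior(1.0, 1.0, provenance="reference"),
        "jeffreys": BetaPrior(0.5, 0.5, provenance="reference"),
    }


def quantile_table(prior: BetaPrior,
                   levels: tuple[float, ...] = (0.025, 0.05, 0.25, 0.5, 0.75, 0.95, 0.975),
                   ) -> dict[float, float]:
    """Prior quantiles in deaths/10,000/day at the given levels."""
    ps = stats.beta.ppf(np.asarray(levels), prior.alpha, prior.beta)
    return {lvl: prob_to_rate(p) for lvl, p in zip(levels, ps)}
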