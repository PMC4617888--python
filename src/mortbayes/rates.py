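"""Survey-level mortality data and classical (frequentist) rate estimation.

A retrospective mortality survey is summarised by a death count ``d`` and
the person-days at risk ``T`` accumulated over the recall period.  The
crude rate is ``10,000 * d / T`` deaths/10,000/day.  Two generic
confidence-interval methods are provided — the exact (Garwood) Poisson
interval and a log-scale Wald interval with optional design-effect
inflation — together with the Prudhon–Spiegel precision-adequacy rule
(the width of the 95% CI should be within 50% of the point estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from scipy import stats

from .exceptions import (
    InvalidInputError,
    MethodNotApplicableError,
    UndefinedPrecisionError,
)
from .units import RATE_SCALE

#: canonical region codes — the rows of the embedded Sphere baseline table
REGIONS: tuple[str, ...] = (
    "sub_saharan_africa",
    "middle_east_north_africa",
    "south_asia",
    "east_asia_pacific",
    "latin_america_caribbean",
    "cee_cis_baltic",
    "industrialized_countries",
    "developing_countries",
    "least_developed_countries",
    "world",
)

#: age strata for which Sphere defines baselines (CDR vs U5DR)
GROUPS: tuple[str, ...] = ("all_ages", "under_five")


@dataclass(frozen=True)
class SurveyObservation:
    """One survey's aggregated deaths and person-time for one age group.

    Parameters
    ----------
    label : str
        Free-text identifier for the survey.
    region : str
        One of :data:`REGIONS` (snake_case Sphere table row).
    group : str
        ``"all_ages"`` (CDR) or ``"under_five"`` (U5DR).
    deaths : int
        Non-negative death count ``d`` during the recall period.
    person_days : float
        Person-days at risk ``T`` (> 0); fractional values accepted.
    recall_days : int, optional
        Length of the retrospective recall window.
    design_effect : float, optional
        Variance inflation of the cluster design relative to simple
        random sampling; must be >= 1 when given.
    """

    label: str
    region: str
    group: str
    deaths: int
    person_days: float
    recall_days: Optional[int] = None
    design_effect: Optional[float] = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InvalidInputError(
                f"unknown region {self.region!r}; valid codes: {', '.join(REGIONS)}")
        if self.group not in GROUPS:
            raise InvalidInputError(
                f"unknown group {self.group!r}; valid groups: {', '.join(GROUPS)}")
        if self.deaths < 0 or self.deaths != int(self.deaths):
            raise InvalidInputError(f"deaths must be a non-negative integer, got {self.deaths}")
        if not self.person_days > 0:
            raise InvalidInputError(f"person_days must be positive, got {self.person_days}")
        if self.deaths > self.person_days:
            raise InvalidInputError(
                f"deaths ({self.deaths}) cannot exceed person-days at risk ({self.person_days})")
        if self.recall_days is not None and not self.recall_days > 0:
            raise InvalidInputError(f"recall_days must be positive, got {self.recall_days}")
        if self.design_effect is not None and not self.design_effect >= 1:
            raise InvalidInputError(
                f"design_effect must be >= 1, got {self.design_effect}")

    def with_deaths(self, deaths: int) -> "SurveyObservation":
        return replace(self, deaths=deaths)


@dataclass(frozen=True)
class ClassicalEstimate:
    """A frequentist rate estimate with its confidence interval.

    All values in deaths/10,000/day.  ``method`` is one of
    ``exact_poisson``, ``wald_log``, ``wald_deff``.
    """

    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "exact_poisson"

    @property
    def width(self) -> float:
        return self.ci_high - self.ci_low


def person_time(n_mid: float, recall_days: float) -> float:
    """Approximate person-days at risk as mid-period population x recall days.

    Survey-specific adjustments (births, arrivals, departures during the
    recall window) are the caller's responsibility.
    """
    if n_mid <= 0 or recall_days <= 0:
        raise InvalidInputError("n_mid and recall_days must be positive")
    return n_mid * recall_days


def _validate_counts(deaths: float, person_days: float) -> None:
    if not person_days > 0:
        raise InvalidInputError(f"person_days must be positive, got {person_days}")
    if deaths < 0:
        raise InvalidInputError(f"deaths must be non-negative, got {deaths}")
    if deaths > person_days:
        raise InvalidInputError(
            f"deaths ({deaths}) cannot exceed person-days ({person_days})")


def point_rate(deaths: float, person_days: float) -> float:
    """Crude death rate ``10,000 * deaths / person_days`` (deaths/10,000/day)."""
    _validate_counts(deaths, person_days)
    return RATE_SCALE * deaths / person_days


def exact_poisson_ci(deaths: int, person_days: float,
                     level: float = 0.95) -> ClassicalEstimate:
    """Exact (Garwood) Poisson confidence interval for the death rate.

    Bounds come from gamma quantiles on the count scale: the lower bound is
    the Poisson mean whose upper tail at ``d`` is (1-level)/2 (zero when
    ``d = 0``), the upper bound the mean whose lower tail at ``d`` is the
    same; both are then divided by person-time and scaled to
    deaths/10,000/day.
    """
    _validate_counts(deaths, person_days)
    if not 0 < level < 1:
        raise InvalidInputError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    lo_count = 0.0 if deaths == 0 else stats.gamma.ppf(tail, deaths)
    hi_count = stats.gamma.ppf(1.0 - tail, deaths + 1)
    scale = RATE_SCALE / person_days
    return ClassicalEstimate(point=point_rate(deaths, person_days),
                             ci_low=lo_count * scale, ci_high=hi_count * scale,
                             level=level, method="exact_poisson")


def wald_ci(deaths: int, person_days: float, level: float = 0.95,
            design_effect: float = 1.0) -> ClassicalEstimate:
    """Log-scale Wald interval with design-effect inflation.

    The standard error of the log rate under a Poisson count is
    ``1/sqrt(d)``; cluster designs inflate it by ``sqrt(deff)``.  Computed
    on the log scale so bounds stay positive, mirroring how cluster-survey
    reports widen their intervals.
    """
    _validate_counts(deaths, person_days)
    if deaths == 0:
        raise MethodNotApplicableError(
            "the log-scale Wald interval requires deaths >= 1; "
            "use exact_poisson_ci for zero counts")
    if design_effect < 1:
        raise InvalidInputError(f"design_effect must be >= 1, got {design_effect}")
    if not 0 < level < 1:
        raise InvalidInputError(f"level must be in (0, 1), got {level}")
    rate = point_rate(deaths, person_days)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    half = z * (design_effect / deaths) ** 0.5
    import math
    method = "wald_deff" if design_effect > 1 else "wald_log"
    return ClassicalEstimate(point=rate, ci_low=rate * math.exp(-half),
                             ci_high=rate * math.exp(half), level=level,
                             method=method)


def assess_precision(estimate: ClassicalEstimate) -> str:
    """Prudhon–Spiegel precision adequacy: CI width within 50% of the point.

    Returns ``"adequate"`` iff ``ci_high - ci_low <= 0.5 * point`` (the
    boundary counts as adequate), else ``"inadequate"``.
    """
    if estimate.point <= 0:
        raise UndefinedPrecisionError(
            "precision adequacy is undefined for a zero point estimate")
    return "adequate" if estimate.width <= 0.5 * estimate.point else "inadequate"
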