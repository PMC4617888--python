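"""Model/Results interface over the conjugate machinery.

:class:`MortalityModel` binds one survey's (deaths, person-days) to a
beta prior; ``fit()`` performs the conjugate update and returns a
:class:`MortalityResults` carrying the classical estimate, the posterior
mean and HDI, exceedance probability against the regional emergency
threshold, classification and trigger decision, with a ``summary()``
table in the style of statistical modelling packages.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import decision as _decision
from .conjugate import PosteriorRate, posterior_update
from .decision import BaselineTable, classify, evidence_trigger
from .exceptions import InvalidInputError, MethodNotApplicableError
from .priors import BetaPrior, reference_priors
from .rates import (ClassicalEstimate, SurveyObservation, assess_precision,
                    exact_poisson_ci, point_rate, wald_ci)
from .units import RATE_UNIT, round_half_up


class MortalityModel:
    """Beta-binomial mortality model for one survey.

    Parameters
    ----------
    observation : SurveyObservation
        Aggregated deaths and person-days for one age group.
    prior : BetaPrior, optional
        Prior on the daily death probability; defaults to the flat
        Beta(1, 1) reference prior.
    baselines : BaselineTable, optional
        Sphere baseline table; defaults to the embedded one.
    """

    def __init__(self, observation: SurveyObservation,
                 prior: Optional[BetaPrior] = None,
                 baselines: Optional[BaselineTable] = None):
        self.observation = observation
        self.prior = prior if prior is not None else reference_priors()["flat"]
        self.baselines = baselines if baselines is not None else _decision.default_baselines()

    @classmethod
    def from_counts(cls, deaths: int, person_days: float, *, region: str,
                    group: str, label: str = "survey",
                    prior: Optional[BetaPrior] = None,
                    design_effect: Optional[float] = None,
                    baselines: Optional[BaselineTable] = None) -> "MortalityModel":
        obs = SurveyObservation(label=label, region=region, group=group,
                                deaths=deaths, person_days=person_days,
                                design_effect=design_effect)
        return cls(obs, prior=prior, baselines=baselines)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, prior: Optional[BetaPrior] = None,
                       baselines: Optional[BaselineTable] = None
                       ) -> list["MortalityModel"]:
        """One model per row of a survey table (same columns as the CSV schema)."""
        from .io import observations_from_frame
        return [cls(obs, prior=prior, baselines=baselines)
                for obs in observations_from_frame(df)]

    def fit(self, hdi_mass: float = 0.95, ci_level: float = 0.95,
            required_evidence: float = 0.95,
            threshold_rate: Optional[float] = None) -> "MortalityResults":
        """Conjugate update plus classical estimation and decision summaries."""
        obs = self.observation
        posterior = posterior_update(self.prior, obs, hdi_mass=hdi_mass)
        if obs.design_effect is not None and obs.deaths >= 1:
            classical = wald_ci(obs.deaths, obs.person_days, level=ci_level,
                                design_effect=obs.design_effect)
        else:
            classical = exact_poisson_ci(obs.deaths, obs.person_days, level=ci_level)
        tau = (threshold_rate if threshold_rate is not None
               else self.baselines[obs.region].threshold(obs.group))
        return MortalityResults(model=self, posterior=posterior, classical=classical,
                                threshold_rate=tau, required_evidence=required_evidence)


class MortalityResults:
    """Fitted posterior, classical estimate and decision summaries."""

    def __init__(self, model: MortalityModel, posterior: PosteriorRate,
                 classical: ClassicalEstimate, threshold_rate: float,
                 required_evidence: float):
        self.model = model
        self.posterior = posterior
        self.classical = classical
        self.threshold_rate = threshold_rate
        self.required_evidence = required_evidence

    # -- point estimates -------------------------------------------------
    @property
    def crude_rate(self) -> float:
        obs = self.model.observation
        return point_rate(obs.deaths, obs.person_days)

    @property
    def posterior_mean(self) -> float:
        return self.posterior.mean_rate

    @property
    def hdi(self) -> tuple[float, float]:
        return (self.posterior.hdi_low, self.posterior.hdi_high)

    # -- decision quantities ---------------------------------------------
    def exceedance(self, threshold_rate: Optional[float] = None) -> float:
        tau = self.threshold_rate if threshold_rate is None else threshold_rate
        return self.posterior.exceedance(tau)

    def triggered(self) -> bool:
        return evidence_trigger(self.exceedance(), self.required_evidence)

    def classification(self, use: str = "posterior_mean") -> str:
        obs = self.model.observation
        if use == "posterior_mean":
            rate = self.posterior_mean
        elif use == "crude":
            rate = self.crude_rate
        else:
            raise InvalidInputError(f"use must be 'posterior_mean' or 'crude', got {use!r}")
        return classify(rate, obs.region, obs.group, self.model.baselines)

    def precision(self) -> str:
        return assess_precision(self.classical)

    # -- presentation ------------------------------------------------------
    def to_dict(self) -> dict:
        obs = self.model.observation
        return {
            "label": obs.label,
            "region": obs.region,
            "group": obs.group,
            "deaths": obs.deaths,
            "person_days": obs.person_days,
            "unit": RATE_UNIT,
            "classical": {
                "point": self.classical.point,
                "ci_low": self.classical.ci_low,
                "ci_high": self.classical.ci_high,
                "level": self.classical.level,
                "method": self.classical.method,
                "precision": self.precision(),
            },
            "prior": {
                "alpha": self.model.prior.alpha,
                "beta": self.model.prior.beta,
                "provenance": self.model.prior.provenance,
            },
            "posterior": {
                "alpha": self.posterior.alpha_post,
                "beta": self.posterior.beta_post,
                "mean": self.posterior_mean,
                "hdi_low": self.posterior.hdi_low,
                "hdi_high": self.posterior.hdi_high,
                "hdi_mass": self.posterior.hdi_mass,
            },
            "decision": {
                "threshold_rate": self.threshold_rate,
                "exceedance": self.exceedance(),
                "required_evidence": self.required_evidence,
                "triggered": self.triggered(),
                "classification": self.classification(),
            },
        }

    def summary(self) -> str:
        """Human-readable summary table (rates to 2 decimals, percents to 1)."""
        obs = self.model.observation
        r2 = lambda x: f"{round_half_up(x, 2):.2f}"
        lines = [
            f"Mortality assessment: {obs.label}",
            "=" * 58,
            f"Region / group        {obs.region} / {obs.group}",
            f"Deaths / person-days  {obs.deaths} / {obs.person_days:g}",
            f"Unit                  {RATE_UNIT}",
            "-" * 58,
            f"Crude rate            {r2(self.crude_rate)}",
            (f"Classical ({self.classical.method}) {r2(self.classical.point)} "
             f"({self.classical.level:.0%} CI {r2(self.classical.ci_low)}"
             f"-{r2(self.classical.ci_high)})  [{self.precision()}]"),
            (f"Prior Beta(a,b)       ({self.model.prior.alpha:.4g}, "
             f"{self.model.prior.beta:.6g})  mean {r2(self.model.prior.mean_rate)}"),
            (f"Posterior mean        {r2(self.posterior_mean)} "
             f"({self.posterior.hdi_mass:.0%} HDI {r2(self.posterior.hdi_low)}"
             f"-{r2(self.posterior.hdi_high)})"),
            "-" * 58,
            f"Emergency threshold   {self.threshold_rate:g}",
            (f"P(rate > threshold)   "
             f"{round_half_up(100 * self.exceedance(), 1):.1f}%"),
            (f"Trigger (>= {self.required_evidence:.0%})       "
             f"{'YES' if self.triggered() else 'no'}"),
            f"Classification        {self.classification()}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_posterior(self, ax=None, rate_max: Optional[float] = None):
        """Sketch prior and posterior densities on the rate scale."""
        import matplotlib.pyplot as plt
        from scipy import stats

        from .units import rate_to_prob
        if ax is None:
            _, ax = plt.subplots()
        if rate_max is None:
            rate_max = 1.5 * self.posterior.hdi_high
        rates = np.linspace(1e-9, rate_max, 500)
        p = rate_to_prob(rates)
        prior = self.model.prior
        ax.plot(rates, stats.beta.pdf(p, prior.alpha, prior.beta) / 10_000.0,
                label="prior", linestyle="--")
        ax.plot(rates, self.posterior.density_rate(rates), label="posterior")
        ax.axvline(self.threshold_rate, color="red", alpha=0.6, label="threshold")
        ax.set_xlabel(f"rate ({RATE_UNIT})")
        ax.set_ylabel("density")
        ax.legend()
        return ax
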