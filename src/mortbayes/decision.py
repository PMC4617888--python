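"""Sphere baseline/threshold lookups, emergency classification and the
community-of-priors sensitivity report.

The embedded table carries, per region, baseline crude (CDR) and
under-five (U5DR) death rates and the corresponding emergency thresholds
in deaths/10,000/day.  Operationally a threshold is about twice the
baseline rounded to one decimal; the printed values are authoritative
(they are the internationally agreed cut-offs), and
:func:`doubling_rule_mismatches` reports where printed thresholds deviate
from exact doubling.

A *community of priors* runs the same survey through a spectrum of prior
beliefs (skeptical, high-mortality, reference) and tabulates, per prior,
the posterior mean, HDI, threshold-exceedance probability and whether the
evidence-trigger rule fires.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .conjugate import PosteriorRate, posterior_update
from .exceptions import InvalidInputError, MortBayesError, UnknownRegionError
from .priors import BetaPrior
from .rates import GROUPS, REGIONS, SurveyObservation, point_rate
from .units import round_half_up


@dataclass(frozen=True)
class RegionBaseline:
    """One baseline-table row: CDR/U5DR baselines and emergency thresholds."""

    region: str
    cdr_baseline: float
    cdr_threshold: float
    u5dr_baseline: float
    u5dr_threshold: float

    def __post_init__(self) -> None:
        for name in ("cdr_baseline", "cdr_threshold", "u5dr_baseline", "u5dr_threshold"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive for {self.region}")

    def baseline(self, group: str) -> float:
        return self.cdr_baseline if group == "all_ages" else self.u5dr_baseline

    def threshold(self, group: str) -> float:
        return self.cdr_threshold if group == "all_ages" else self.u5dr_threshold


class BaselineTable:
    """Region-indexed collection of :class:`RegionBaseline` rows."""

    def __init__(self, rows: Mapping[str, RegionBaseline]):
        self._rows = dict(rows)

    def __getitem__(self, region: str) -> RegionBaseline:
        try:
            return self._rows[region]
        except KeyError:
            raise UnknownRegionError(
                f"unknown region {region!r}; valid codes: {', '.join(self._rows)}") from None

    def __iter__(self):
        return iter(self._rows.values())

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self._rows)


def load_baselines(path: Optional[Path] = None) -> BaselineTable:
    """Load the baseline table (embedded Sphere table by default).

    Users may point ``path`` at an updated table in the same CSV dialect
    (columns region, cdr_baseline, cdr_threshold, u5dr_baseline,
    u5dr_threshold).
    """
    if path is None:
        source = importlib.resources.files("mortbayes.data") / "sphere_baselines.csv"
        with importlib.resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"region", "cdr_baseline", "cdr_threshold", "u5dr_baseline", "u5dr_threshold"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"baseline table missing columns: {sorted(missing)}")
    rows = {r.region: RegionBaseline(r.region, r.cdr_baseline, r.cdr_threshold,
                                     r.u5dr_baseline, r.u5dr_threshold)
            for r in df.itertuples(index=False)}
    return BaselineTable(rows)


_DEFAULT_TABLE: Optional[BaselineTable] = None


def default_baselines() -> BaselineTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_baselines()
    return _DEFAULT_TABLE


def doubling_rule_mismatches(table: Optional[BaselineTable] = None
                             ) -> list[tuple[str, str, float, float]]:
    """Cells where the printed threshold differs from round(2 x baseline, 1).

    Returns (region, group, printed_threshold, doubled_baseline) tuples;
    an empty list means every cell follows the doubling-with-rounding rule.
    """
    table = table if table is not None else default_baselines()
    out = []
    for row in table:
        for group in GROUPS:
            doubled = round_half_up(2.0 * row.baseline(group), 1)
            printed = row.threshold(group)
            if abs(printed - doubled) > 1e-9:
                out.append((row.region, group, printed, doubled))
    return out


def emergency_threshold(region: str, group: str,
                        table: Optional[BaselineTable] = None) -> float:
    """Printed emergency threshold for (region, group), deaths/10,000/day."""
    if group not in GROUPS:
        raise InvalidInputError(f"unknown group {group!r}; valid groups: {', '.join(GROUPS)}")
    table = table if table is not None else default_baselines()
    return table[region].threshold(group)


def classify(rate: float, region: str, group: str,
             table: Optional[BaselineTable] = None) -> str:
    """Classify a rate against the regional baseline and threshold.

    ``emergency`` iff rate >= threshold, ``below_baseline`` iff rate <
    baseline, ``elevated`` otherwise.  Ties classify upward — the more
    cautious reading for humanitarian response.
    """
    if rate < 0:
        raise InvalidInputError(f"rate must be non-negative, got {rate}")
    if group not in GROUPS:
        raise InvalidInputError(f"unknown group {group!r}; valid groups: {', '.join(GROUPS)}")
    table = table if table is not None else default_baselines()
    row = table[region]
    if rate >= row.threshold(group):
        return "emergency"
    if rate < row.baseline(group):
        return "below_baseline"
    return "elevated"


def evidence_trigger(exceedance: float, required: float = 0.95) -> bool:
    """True iff the exceedance probability meets the required evidence level.

    The required level (default 0.95) encodes how much posterior
    probability of being above the emergency threshold should trigger an
    international response; the boundary fires the trigger.
    """
    if not 0 <= exceedance <= 1:
        raise InvalidInputError(f"exceedance must be in [0, 1], got {exceedance}")
    if not 0 <= required <= 1:
        raise InvalidInputError(f"required must be in [0, 1], got {required}")
    return exceedance >= required


@dataclass(frozen=True)
class PriorRow:
    """One prior's line in a community-of-priors report."""

    prior_name: str
    posterior: PosteriorRate
    exceedance: float
    triggered: bool
    classification: str


@dataclass(frozen=True)
class CommunityReport:
    """Per-prior posterior summaries for one survey.

    Shows both the posterior-mean classification and the evidence-trigger
    decision; when they disagree the call is left to the reader.
    """

    label: str
    region: str
    group: str
    threshold_rate: float
    required_level: float
    crude_rate: float
    rows: tuple[PriorRow, ...] = field(default_factory=tuple)


def community_of_priors(obs: SurveyObservation, priors: Mapping[str, BetaPrior],
                        required: float = 0.95,
                        table: Optional[BaselineTable] = None,
                        threshold_rate: Optional[float] = None,
                        hdi_mass: float = 0.95) -> CommunityReport:
    """Analyse one survey under a named spectrum of priors.

    The exceedance threshold defaults to the survey's (region, group)
    emergency threshold; ``threshold_rate`` overrides it.  Per-prior
    failures propagate with the prior's name attached.
    """
    if not priors:
        raise InvalidInputError("at least one prior is required")
    table = table if table is not None else default_baselines()
    tau = (threshold_rate if threshold_rate is not None
           else emergency_threshold(obs.region, obs.group, table))
    rows = []
    for name, prior in priors.items():
        try:
            post = posterior_update(prior, obs, hdi_mass=hdi_mass)
            exc = post.exceedance(tau)
            rows.append(PriorRow(
                prior_name=name, posterior=post, exceedance=exc,
                triggered=evidence_trigger(exc, required),
                classification=classify(post.mean_rate, obs.region, obs.group, table)))
        except MortBayesError as err:
            raise type(err)(f"prior {name!r}: {err}") from err
        except Exception as err:
            raise MortBayesError(f"prior {name!r}: {err}") from err
    return CommunityReport(label=obs.label, region=obs.region, group=obs.group,
                           threshold_rate=tau, required_level=required,
                           crude_rate=point_rate(obs.deaths, obs.person_days),
                           rows=tuple(rows))
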