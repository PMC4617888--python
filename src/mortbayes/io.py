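"""CSV / YAML / JSON input-output and report writing.

Survey CSV schema (UTF-8, header required): columns ``label``,
``region``, ``group``, ``deaths``, ``person_days`` plus optional
``recall_days`` and ``design_effect`` (blank allowed).  Priors come from
a YAML or JSON config with named blocks of ``mean_rate``,
``quantile_level``, ``quantile_rate`` (or explicit ``alpha``/``beta``).
Reports are JSON documents mirroring the in-memory results, with a
human-readable table printed alongside.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .exceptions import InvalidInputError, SchemaError
from .priors import BetaPrior, ElicitationSpec, elicit_beta, reference_priors
from .rates import SurveyObservation

logger = logging.getLogger("mortbayes")

_REQUIRED_COLUMNS = ("label", "region", "group", "deaths", "person_days")
_OPTIONAL_COLUMNS = ("recall_days", "design_effect")


def observations_from_frame(df: pd.DataFrame) -> list[SurveyObservation]:
    """Validate a survey table and build one observation per row."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey table is missing required column(s): {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            recall = getattr(row, "recall_days", None)
            deff = getattr(row, "design_effect", None)
            obs = SurveyObservation(
                label=str(row.label), region=str(row.region), group=str(row.group),
                deaths=int(row.deaths), person_days=float(row.person_days),
                recall_days=None if recall is None or pd.isna(recall) else int(recall),
                design_effect=None if deff is None or pd.isna(deff) else float(deff))
        except (InvalidInputError, ValueError) as err:
            raise SchemaError(f"survey table row {i}: {err}") from err
        out.append(obs)
    return out


def read_surveys(path: Path | str) -> list[SurveyObservation]:
    """Read survey observations from a CSV file."""
    df = pd.read_csv(path)
    obs = observations_from_frame(df)
    logger.info("read %d survey observation(s) from %s", len(obs), path)
    return obs


def write_surveys(observations: Sequence[SurveyObservation], path: Path | str) -> None:
    """Write observations back to the survey CSV schema (round-trip safe)."""
    rows = [{
        "label": o.label, "region": o.region, "group": o.group,
        "deaths": o.deaths, "person_days": o.person_days,
        "recall_days": o.recall_days, "design_effect": o.design_effect,
    } for o in observations]
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS + _OPTIONAL_COLUMNS).to_csv(
        path, index=False)


def read_priors_config(path: Path | str) -> dict[str, BetaPrior]:
    """Load named priors from a YAML/JSON config.

    Each top-level key names a prior given either by elicitation
    constraints (``mean_rate``, ``quantile_level``, ``quantile_rate``) or
    by explicit shapes (``alpha``, ``beta``).  The special value
    ``"reference"`` expands to the built-in flat and Jeffreys priors.
    """
    text = Path(path).read_text(encoding="utf-8")
    config = yaml.safe_load(text)
    if not isinstance(config, Mapping) or not config:
        raise SchemaError("prior config must be a non-empty mapping of named priors")
    priors: dict[str, BetaPrior] = {}
    for name, block in config.items():
        if block == "reference":
            priors.update(reference_priors())
            continue
        if not isinstance(block, Mapping):
            raise SchemaError(f"prior {name!r}: expected a mapping of fields")
        if {"alpha", "beta"} <= set(block):
            priors[name] = BetaPrior(float(block["alpha"]), float(block["beta"]),
                                     provenance=str(block.get("provenance", "explicit")))
        elif {"mean_rate", "quantile_level", "quantile_rate"} <= set(block):
            priors[name] = elicit_beta(ElicitationSpec(
                mean_rate=float(block["mean_rate"]),
                quantile_level=float(block["quantile_level"]),
                quantile_rate=float(block["quantile_rate"])))
        else:
            raise SchemaError(
                f"prior {name!r}: give either alpha/beta or "
                "mean_rate/quantile_level/quantile_rate")
        logger.info("prior %r: %s", name, priors[name].provenance)
    return priors


def report_payload(reports: Iterable) -> dict:
    """JSON-serialisable payload for a collection of community reports."""
    surveys = []
    for rep in reports:
        surveys.append({
            "label": rep.label,
            "region": rep.region,
            "group": rep.group,
            "crude_rate": rep.crude_rate,
            "threshold_rate": rep.threshold_rate,
            "required_evidence": rep.required_level,
            "priors": [{
                "name": row.prior_name,
                "posterior_mean": row.posterior.mean_rate,
                "hdi_low": row.posterior.hdi_low,
                "hdi_high": row.posterior.hdi_high,
                "hdi_mass": row.posterior.hdi_mass,
                "exceedance": row.exceedance,
                "triggered": row.triggered,
                "classification": row.classification,
            } for row in rep.rows],
        })
    return {"unit": "deaths/10,000/day", "surveys": surveys}


def format_report_table(reports: Iterable) -> str:
    """Plain-text table of a collection of community reports."""
    lines = []
    for rep in reports:
        lines.append(f"{rep.label} [{rep.region}/{rep.group}] "
                     f"crude {rep.crude_rate:.2f}, threshold {rep.threshold_rate:g}")
        lines.append(f"  {'prior':<16}{'post.mean':>10}{'HDI':>16}"
                     f"{'P(>thr)':>9}{'trigger':>9}  class")
        for row in rep.rows:
            hdi = f"{row.posterior.hdi_low:.2f}-{row.posterior.hdi_high:.2f}"
            lines.append(f"  {row.prior_name:<16}{row.posterior.mean_rate:>10.2f}"
                         f"{hdi:>16}{100 * row.exceedance:>8.1f}%"
                         f"{'YES' if row.triggered else 'no':>9}  {row.classification}")
    return "\n".join(lines)


def write_report(reports: Sequence, path: Path | str,
                 echo: Optional[callable] = None) -> dict:
    """Write the JSON report and print the text table.

    Raises on empty results before touching the filesystem; returns the
    payload that was written.
    """
    reports = list(reports)
    if not reports:
        raise InvalidInputError("no results to report; refusing to write an empty file")
    payload = report_payload(reports)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    table = format_report_table(reports)
    (echo or print)(table)
    logger.info("wrote report for %d survey(s) to %s", len(reports), path)
    return payload
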