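"""Synthetic country datasets with known ground truth.

Generates internally consistent bundles of service statistics, population,
reporting rates and survey benchmarks from a declarative scenario, so the
whole pipeline is testable end to end without any external data.

The ground-truth user series comes from an explicit **per-cohort ledger**:
every insertion cohort is followed individually through its continuation
curve, year by year, including cohorts inserted before the observed data
window. This is deliberately a second, independent implementation of the
carryover arithmetic — direct enumeration rather than the pipeline's
summation formulas — so it can catch algebra errors in the estimator.

Observed counts are ``true counts × covered_share × lognormal noise``: the
HMIS only sees the covered fraction of provision, with multiplicative
errors that scale with volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    NATIONAL,
    PopulationSeries,
    ReportingRateSeries,
    ServiceStatisticsTable,
    SurveyBenchmarkTable,
)
from .method_registry import (
    MethodCategory,
    MethodRegistry,
    SSType,
    load_registry,
)
from .user_estimation import UserSeries

__all__ = ["MethodScenario", "ScenarioSpec", "SyntheticBundle", "generate", "cohort_ledger_users"]

_PATTERNS = {"flat", "linear", "impulse"}


@dataclass(frozen=True)
class MethodScenario:
    """True provision trajectory for one method.

    ``base`` is the annual service volume (insertions for long-acting
    methods, commodity units for short-term ones) in the first observed
    year. ``pattern`` shapes the trajectory over the window: ``flat``
    (constant), ``linear`` (grows by ``growth`` units each year) or
    ``impulse`` (``base`` in the first year, zero afterwards).
    ``pre_window_years`` cohorts of size ``pre_window_level`` (default
    ``base``) are inserted before the window, invisible to the observed
    statistics but present in the ground truth — the situation the
    historic-user back-cast addresses.
    """

    base: float
    pattern: str = "flat"
    growth: float = 0.0
    covered_share: float = 1.0
    pre_window_years: int = 0
    pre_window_level: float | None = None

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {sorted(_PATTERNS)}")
        if not 0.0 < self.covered_share <= 1.0:
            raise ValueError(f"covered_share must be in (0, 1], got {self.covered_share}")
        if self.base < 0:
            raise ValueError("base volume must be non-negative")

    def volume(self, offset: int) -> float:
        """True service volume ``offset`` years into the observed window."""
        if self.pattern == "flat":
            return self.base
        if self.pattern == "linear":
            return self.base + self.growth * offset
        return self.base if offset == 0 else 0.0


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete synthetic country: methods, population, noise and seed."""

    start_year: int
    n_years: int
    methods: Mapping[str, MethodScenario]
    ss_type: str = SSType.COMMODITIES_CLIENTS.value
    wra_start: float = 1_000_000.0
    wra_growth: float = 0.02
    reporting_rates: Sequence[float] | float = 95.0
    noise_sigma: float = 0.05
    seed: int = 0
    survey_years: Sequence[int] = ()

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("scenario must span at least one year")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class SyntheticBundle:
    """Everything a pipeline run needs, plus the ledger ground truth."""

    stats: ServiceStatisticsTable
    population: PopulationSeries
    reporting_rates: ReportingRateSeries
    surveys: SurveyBenchmarkTable
    true_users: UserSeries
    true_emu: pd.DataFrame  # year, users, wra, emu
    registry: MethodRegistry


def cohort_ledger_users(
    insertions_by_year: Mapping[int, float],
    curve_values: Sequence[float],
    years: Sequence[int],
) -> dict[int, float]:
    """Follow each insertion cohort through the curve, one cohort at a time.

    Cohort inserted in year ``y`` contributes ``C_y × Con(t − y + 1)`` users
    in year ``t``; contributions beyond the curve's support are zero. This
    enumerates cohorts explicitly and never uses the estimator's formulas.
    """
    users = {t: 0.0 for t in years}
    for y, c in insertions_by_year.items():
        for t in years:
            age = t - y + 1  # year-of-use, 1-based
            if 1 <= age <= len(curve_values):
                users[t] += c * curve_values[age - 1]
    return users


def generate(spec: ScenarioSpec, registry: MethodRegistry | None = None) -> SyntheticBundle:
    """Generate a reproducible synthetic bundle for a scenario.

    Identical spec + seed give identical outputs. True users for
    long-acting methods come from the per-cohort ledger; short-term truth is
    the CYP conversion of the true (not observed) volumes. The synthetic
    "survey" mCP in each requested survey year is true users / WRA.
    """
    registry = registry or load_registry()
    years = spec.years
    rng = np.random.default_rng(spec.seed)

    unknown = sorted(set(spec.methods) - set(registry.names))
    if unknown:
        raise KeyError(f"scenario methods not in registry: {unknown}")

    wra = {t: spec.wra_start * (1.0 + spec.wra_growth) ** i for i, t in enumerate(years)}

    if isinstance(spec.reporting_rates, (int, float)):
        rates = {t: float(spec.reporting_rates) for t in years}
    else:
        if len(spec.reporting_rates) != spec.n_years:
            raise ValueError("reporting_rates length must match n_years")
        rates = dict(zip(years, map(float, spec.reporting_rates)))

    stat_rows = []
    truth_rows = []
    true_total = {t: 0.0 for t in years}
    for name, ms in sorted(spec.methods.items()):
        mspec = registry[name]
        true_volumes = {t: ms.volume(i) for i, t in enumerate(years)}
        # pre-window cohorts exist in truth but never in observed statistics
        pre_level = ms.pre_window_level if ms.pre_window_level is not None else ms.base
        all_cohorts = dict(true_volumes)
        for k in range(1, ms.pre_window_years + 1):
            all_cohorts[spec.start_year - k] = pre_level

        if mspec.category is MethodCategory.SHORT_TERM:
            upc = mspec.units_per_cyp[spec.ss_type]
            true_u = {t: true_volumes[t] / upc for t in years}
        else:
            true_u = cohort_ledger_users(all_cohorts, mspec.continuation.values, years)

        for t in years:
            noise = float(rng.lognormal(mean=0.0, sigma=spec.noise_sigma)) if spec.noise_sigma else 1.0
            observed = true_volumes[t] * ms.covered_share * noise
            stat_rows.append(
                {"year": t, "month": 0, "method": name, "ss_type": spec.ss_type,
                 "count": observed, "region": NATIONAL}
            )
            truth_rows.append(
                {"year": t, "method": name, "ss_type": spec.ss_type, "region": NATIONAL,
                 "current": true_u[t], "continuing": 0.0, "historic": 0.0,
                 "total": true_u[t], "cyp": 0.0}
            )
            true_total[t] += true_u[t]

    stats = ServiceStatisticsTable(pd.DataFrame(stat_rows))
    population = PopulationSeries(
        pd.DataFrame({"year": years, "wra": [wra[t] for t in years], "region": NATIONAL})
    )
    reporting = ReportingRateSeries(
        pd.DataFrame({"year": years, "rate": [rates[t] for t in years], "region": NATIONAL})
    )

    survey_rows = []
    for sy in spec.survey_years:
        if sy not in wra:
            raise ValueError(f"survey year {sy} outside scenario window")
        mcp = true_total[sy] / wra[sy]
        survey_rows.append(
            {"year": sy, "source": "synthetic_survey", "mcp": mcp,
             "method": "", "prevalence": np.nan, "covered_share": np.nan}
        )
        for name, ms in sorted(spec.methods.items()):
            m_users = next(
                r["total"] for r in truth_rows if r["year"] == sy and r["method"] == name
            )
            survey_rows.append(
                {"year": sy, "source": "synthetic_survey", "mcp": mcp, "method": name,
                 "prevalence": m_users / wra[sy], "covered_share": ms.covered_share}
            )
    surveys = SurveyBenchmarkTable(
        pd.DataFrame(
            survey_rows,
            columns=["year", "source", "mcp", "method", "prevalence", "covered_share"],
        )
    )

    true_users = UserSeries(pd.DataFrame(truth_rows))
    true_emu = pd.DataFrame(
        {
            "year": years,
            "users": [true_total[t] for t in years],
            "wra": [wra[t] for t in years],
            "emu": [true_total[t] / wra[t] for t in years],
        }
    )
    return SyntheticBundle(
        stats=stats,
        population=population,
        reporting_rates=reporting,
        surveys=surveys,
        true_users=true_users,
        true_emu=true_emu,
        registry=registry,
    )
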