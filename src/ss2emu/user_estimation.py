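"""The EMU numerator engine: service statistics → estimated users.

Converts annual counts into estimated modern contraceptive users per
(year, method, service-statistic type), decomposed into three components:

* **current** — women using a method in the year it was provided. Short-term
  methods convert commodities/visits through CYP factors (e.g. 4 DMPA-IM
  doses = 1 user-year); a long-acting insertion counts ``Con(1)`` of a user
  to absorb first-year discontinuation.
* **continuing** — women still using a long-acting/permanent method inserted
  in an earlier observed year, carried forward along the method's
  continuation curve.
* **historic** — women assumed to still be using a method provided *before*
  the first year of available data, back-cast from the first observed
  year's volume under a declared program-maturity scenario.

Totals are exact sums of the three components; users remain real-valued
throughout (no rounding until presentation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .data_io import NATIONAL, ServiceStatisticsTable
from .method_registry import (
    ContinuationCurve,
    HistoricScenario,
    MethodCategory,
    MethodRegistry,
    MethodSpec,
    SSType,
    continuation_at,
)

__all__ = [
    "UserSeries",
    "short_term_users",
    "ltm_current_users",
    "ltm_continuing_users",
    "ltm_historic_users",
    "cyp_credited",
    "estimate_users",
]

logger = logging.getLogger(__name__)

_COLUMNS = ["year", "method", "ss_type", "region", "current", "continuing", "historic", "total", "cyp"]


@dataclass
class UserSeries:
    """Estimated users per (year, method, ss_type, region), decomposed.

    ``total = current + continuing + historic`` holds exactly for every row;
    short-term methods have zero continuing and historic components. The
    auxiliary ``cyp`` column carries the classic couple-years-of-protection
    credit for the same counts (all allocated to the year of provision),
    kept for CYP-vs-EMU comparison only.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in _COLUMNS:
            if col not in df.columns:
                if col == "cyp":
                    df["cyp"] = 0.0
                elif col == "region":
                    df["region"] = NATIONAL
                else:
                    raise ValueError(f"user series missing column {col!r}")
        df["region"] = df["region"].fillna(NATIONAL).astype(str)
        self.data = df[_COLUMNS].reset_index(drop=True)

    def numerator(self, include: Iterable[str] | None = None) -> pd.DataFrame:
        """EMU numerator per (year, ss_type, region): users summed over methods."""
        df = self.data
        if include is not None:
            df = df[df["method"].isin(set(include))]
        return (
            df.groupby(["year", "ss_type", "region"], as_index=False)[
                ["current", "continuing", "historic", "total", "cyp"]
            ].sum()
        )

    def component(self, year: int, method: str, ss_type: str, which: str, region: str = NATIONAL) -> float:
        df = self.data
        m = (
            (df["year"] == year)
            & (df["method"] == method)
            & (df["ss_type"] == ss_type)
            & (df["region"] == region)
        )
        sub = df.loc[m, which]
        return float(sub.sum())


def short_term_users(count: float, units_per_cyp: float) -> float:
    """Users from a short-term method count: ``count / units_per_cyp``.

    One CYP's worth of commodities or visits equals one estimated user-year.
    """
    if units_per_cyp <= 0:
        raise ValueError(f"units_per_cyp must be positive, got {units_per_cyp}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count * (1.0 / units_per_cyp)


def ltm_current_users(insertions: float, curve: ContinuationCurve) -> float:
    """Current-year users from long-acting insertions: ``insertions × Con(1)``."""
    if insertions < 0:
        raise ValueError(f"insertions must be non-negative, got {insertions}")
    return insertions * continuation_at(curve, 1)


def ltm_continuing_users(
    cohorts: Mapping[int, float],
    curve: ContinuationCurve,
    t: int,
    t0: int | None = None,
) -> float:
    """Users in year ``t`` still using a method inserted in an earlier observed year.

    ``cohorts`` maps insertion year → insertions; the cohort inserted ``x``
    years before ``t`` contributes ``C[t-x] × Con(x+1)``. Years absent from
    ``cohorts`` contribute nothing. Only years strictly before ``t`` (and at
    or after ``t0`` when given) are summed.
    """
    if any(y >= t for y in cohorts):
        bad = min(y for y in cohorts if y >= t)
        raise ValueError(f"cohort year {bad} is not before estimation year {t}")
    if t0 is None:
        if not cohorts:
            return 0.0
        t0 = min(cohorts)
    total = 0.0
    for x in range(1, t - t0 + 1):
        total += cohorts.get(t - x, 0.0) * continuation_at(curve, x + 1)
    return total


def ltm_historic_users(
    first_year_count: float,
    curve: ContinuationCurve,
    scenario: HistoricScenario,
    t: int,
    t0: int,
    l_max: int,
) -> float:
    """Back-cast users from provision before the first year of data.

    ``at_scale`` assumes pre-window provision matched the first observed
    year: ``C[t0] × Σ_{x=t-t0}^{L_max} Con(x+2)``. ``scaling_up`` takes half
    that. Terms beyond the curve's support are zero, so the historic
    component washes out entirely once ``t - t0 ≥ L_max - 1``.
    """
    if t < t0:
        raise ValueError(f"estimation year {t} before first data year {t0}")
    scenario = HistoricScenario(scenario)
    if scenario is HistoricScenario.NO_HISTORIC:
        return 0.0
    s = sum(continuation_at(curve, x + 2) for x in range(t - t0, l_max + 1))
    if scenario is HistoricScenario.AT_SCALE:
        return first_year_count * s
    return 0.5 * first_year_count * s


def cyp_credited(count: float, spec: MethodSpec, ss_type: str) -> float:
    """Classic CYP credit for a count, all allocated to the year of provision."""
    if SSType(ss_type) is SSType.USERS:
        return 0.0  # true user counts carry no commodity-based CYP credit
    if spec.category is MethodCategory.SHORT_TERM:
        return short_term_users(count, spec.units_per_cyp[ss_type])
    if spec.cyp_per_service is None:
        return 0.0
    return count * spec.cyp_per_service


def estimate_users(
    stats: ServiceStatisticsTable,
    registry: MethodRegistry,
    scenarios: Mapping[str, HistoricScenario | str] | None = None,
    exclusions: Iterable[str] = (),
) -> UserSeries:
    """Run the full numerator decomposition over a service-statistics table.

    Monthly records are aggregated to annual totals first. For each
    (method, ss_type, region) the first year with any record defines t0;
    every year from t0 through the latest observed year in the table gets a
    row (gap years contribute zero current users but still accrue continuing
    and historic users). Methods listed in ``exclusions`` are dropped
    entirely. The ``users`` statistic type bypasses conversion: counts pass
    through as current users.
    """
    scenarios = {k: HistoricScenario(v) for k, v in (scenarios or {}).items()}
    excluded = set(exclusions)
    annual = stats.annual().data
    annual = annual[~annual["method"].isin(excluded)]

    unknown = sorted(set(annual["method"]) - set(registry.names))
    if unknown:
        raise KeyError(f"methods not in registry: {unknown}; valid: {registry.names}")

    rows: list[tuple] = []
    if annual.empty:
        return UserSeries(pd.DataFrame(columns=_COLUMNS))
    global_t_max = int(annual["year"].max())

    for (method, ss_type, region), grp in annual.groupby(["method", "ss_type", "region"]):
        spec = registry[method]
        counts = dict(zip(grp["year"].astype(int), grp["count"].astype(float)))
        t0 = min(counts)
        if SSType(ss_type) is SSType.USERS:
            # true longitudinal user counts: no conversion, no carryover
            for t in range(t0, global_t_max + 1):
                c = counts.get(t, 0.0)
                rows.append((t, method, ss_type, region, c, 0.0, 0.0, c, 0.0))
            continue
        if spec.category is MethodCategory.SHORT_TERM:
            upc = spec.units_per_cyp.get(ss_type)
            if upc is None:
                raise KeyError(
                    f"method {method!r} has no units_per_cyp for ss_type {ss_type!r}"
                )
            for t in range(t0, global_t_max + 1):
                c = counts.get(t, 0.0)
                u = short_term_users(c, upc)
                rows.append((t, method, ss_type, region, u, 0.0, 0.0, u, u))
            continue
        # long-acting or permanent
        curve = spec.continuation
        scenario = scenarios.get(method)
        if scenario is None:
            scenario = HistoricScenario.NO_HISTORIC
            logger.warning(
                "no historic scenario declared for long-acting method %r; "
                "defaulting to no_historic",
                method,
            )
        first_count = counts[t0]
        for t in range(t0, global_t_max + 1):
            cur = ltm_current_users(counts.get(t, 0.0), curve)
            cont = ltm_continuing_users(
                {y: c for y, c in counts.items() if y < t}, curve, t, t0
            )
            hist = ltm_historic_users(
                first_count, curve, scenario, t, t0, spec.duration_years
            )
            cyp = cyp_credited(counts.get(t, 0.0), spec, ss_type)
            rows.append((t, method, ss_type, region, cur, cont, hist, cur + cont + hist, cyp))

    return UserSeries(pd.DataFrame(rows, columns=_COLUMNS))
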