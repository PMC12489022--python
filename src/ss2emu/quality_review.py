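"""The embedded data-quality review: completeness, internal and external benchmarks.

The review never adjusts numbers. Completeness is a gate (years with low
facility reporting are excluded from the trend, not corrected); internal
benchmarking cross-checks the relationships between service-statistic
types; external benchmarking compares estimated users and their growth
against survey prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .adjustment_emu import EMUSeries
from .data_io import (
    NATIONAL,
    PopulationSeries,
    ReportingRateSeries,
    ServiceStatisticsTable,
    SurveyBenchmarkTable,
)
from .method_registry import MethodCategory, MethodRegistry, SSType
from .user_estimation import UserSeries

__all__ = [
    "QualityReport",
    "completeness_gate",
    "apply_completeness",
    "internal_benchmarks",
    "external_benchmarks",
    "run_review",
    "SINGLE_DOSE_METHODS",
]

# methods where one commodity unit is distributed per visit, so
# commodities-to-clients and visits should track each other closely
SINGLE_DOSE_METHODS = frozenset({"iud_copper_t", "implant", "injectable_dmpa_im"})

_FLAG_COLUMNS = ["year", "method", "ss_type", "check", "observed", "expected", "severity"]
_COMPLETENESS_COLUMNS = ["year", "region", "rate", "included", "reason"]


@dataclass
class QualityReport:
    """Findings from the three-part review, with every flag carrying its values."""

    completeness: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_COMPLETENESS_COLUMNS)
    )
    internal_flags: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_FLAG_COLUMNS)
    )
    external_comparison: pd.DataFrame = field(default_factory=pd.DataFrame)
    growth_comparison: pd.DataFrame = field(default_factory=pd.DataFrame)
    notices: list[str] = field(default_factory=list)

    def verdict(self) -> dict[str, str]:
        """One-line verdict per service-statistic type."""
        verdicts: dict[str, str] = {}
        flags = self.internal_flags
        for ss in sorted(set(flags["ss_type"].dropna())) or []:
            n = int((flags["ss_type"] == ss).sum())
            verdicts[ss] = f"{n} internal flag(s)"
        return verdicts

    def narrative(self) -> str:
        lines = ["Data quality review summary", "=" * 27, ""]
        excl = self.completeness[~self.completeness["included"].astype(bool)]
        lines.append(
            f"Completeness: {len(self.completeness)} year(s) reviewed, "
            f"{len(excl)} excluded from the trend."
        )
        for _, r in excl.iterrows():
            lines.append(f"  - {int(r['year'])}: {r['reason']}")
        lines.append(f"Internal benchmarking: {len(self.internal_flags)} flag(s).")
        for _, r in self.internal_flags.iterrows():
            lines.append(
                f"  - {int(r['year'])} {r['method']} [{r['check']}]: "
                f"observed {r['observed']}, expected {r['expected']} ({r['severity']})"
            )
        if self.external_comparison.empty:
            lines.append("External benchmarking: no overlapping survey years.")
        else:
            lines.append(
                f"External benchmarking: {self.external_comparison['survey_year'].nunique()} "
                "survey year(s) compared."
            )
        for n in self.notices:
            lines.append(f"Note: {n}")
        return "\n".join(lines) + "\n"


def completeness_gate(
    rates: ReportingRateSeries, threshold: float = 80.0
) -> pd.DataFrame:
    """Per-year trend inclusion decisions from facility reporting rates.

    Years reporting below ``threshold`` percent (default 80) are marked
    excluded from the EMU trend. This is a gate, not an adjustment: no
    numerator is rescaled for low reporting.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    rows = []
    for _, r in rates.data.sort_values(["region", "year"]).iterrows():
        ok = r["rate"] >= threshold
        rows.append(
            {
                "year": int(r["year"]),
                "region": r["region"],
                "rate": float(r["rate"]),
                "included": bool(ok),
                "reason": "" if ok else f"reporting rate {r['rate']:g}% below {threshold:g}%",
            }
        )
    return pd.DataFrame(rows, columns=_COMPLETENESS_COLUMNS)


def apply_completeness(emu: EMUSeries, decisions: pd.DataFrame) -> EMUSeries:
    """Mark excluded years on an EMU series; numerators are left untouched."""
    df = emu.data.copy()
    excluded = {
        (int(r["year"]), r["region"])
        for _, r in decisions.iterrows()
        if not bool(r["included"])
    }
    df["included"] = [
        (int(y), reg) not in excluded for y, reg in zip(df["year"], df["region"])
    ]
    return EMUSeries(df)


def _robust_outliers(values: pd.Series, mad_factor: float, yoy_threshold: float) -> list[int]:
    """Indices of outlying annual values: |x − median| > mad_factor × MAD,
    or year-over-year relative change above yoy_threshold."""
    v = values.to_numpy(dtype=float)
    flagged: set[int] = set()
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad > 0:
        flagged.update(np.nonzero(np.abs(v - med) > mad_factor * mad)[0].tolist())
    for i in range(1, len(v)):
        prev = v[i - 1]
        if prev > 0 and abs(v[i] - prev) / prev > yoy_threshold:
            flagged.add(i)
    return sorted(flagged)


def internal_benchmarks(
    stats: ServiceStatisticsTable,
    registry: MethodRegistry,
    similarity_tolerance: float = 0.10,
    mad_factor: float = 3.0,
    yoy_threshold: float = 0.50,
) -> pd.DataFrame:
    """Cross-checks between service-statistic types plus outlier screening.

    Emits flags for: (a) commodities-to-facilities below commodities-to-
    clients for the same method-year (facilities stock should exceed what
    reaches clients); (b) single-dose methods where clients and visits
    diverge by more than ``similarity_tolerance`` relative difference;
    (c) sterilization present in visits/users but absent from commodities
    (informational — an expected recording gap); (d) robust year-over-year
    outliers per method × statistic type. Checks needing a statistic type
    that is absent are skipped, never failed; the review never aborts.
    """
    annual = stats.annual().data
    flags: list[dict] = []

    def flag(year, method, ss_type, check, observed, expected, severity="warning"):
        flags.append(
            {
                "year": int(year),
                "method": method,
                "ss_type": ss_type,
                "check": check,
                "observed": observed,
                "expected": expected,
                "severity": severity,
            }
        )

    wide = annual.pivot_table(
        index=["year", "method", "region"], columns="ss_type", values="count", aggfunc="sum"
    )
    cc, cf = SSType.COMMODITIES_CLIENTS.value, SSType.COMMODITIES_FACILITIES.value
    vis, usr = SSType.VISITS.value, SSType.USERS.value

    if cc in wide.columns and cf in wide.columns:
        both = wide[[cc, cf]].dropna()
        for (year, method, _region), r in both.iterrows():
            if r[cf] < r[cc]:
                flag(
                    year, method, cf, "facilities_below_clients",
                    f"facilities={r[cf]:g}, clients={r[cc]:g}",
                    "commodities to facilities >= commodities to clients",
                )

    if cc in wide.columns and vis in wide.columns:
        both = wide[[cc, vis]].dropna()
        for (year, method, _region), r in both.iterrows():
            if method not in SINGLE_DOSE_METHODS:
                continue
            hi = max(r[cc], r[vis])
            if hi > 0 and abs(r[cc] - r[vis]) / hi > similarity_tolerance:
                flag(
                    year, method, cc, "clients_visits_divergence",
                    f"clients={r[cc]:g}, visits={r[vis]:g}",
                    f"relative difference <= {similarity_tolerance:g} for single-dose methods",
                )

    sterilization = [
        m.name for m in registry if m.category is MethodCategory.PERMANENT
    ]
    commodity_cols = [c for c in (cc, cf) if c in wide.columns]
    service_cols = [c for c in (vis, usr) if c in wide.columns]
    if commodity_cols and service_cols:
        for (year, method, _region), r in wide.iterrows():
            if method not in sterilization:
                continue
            in_services = any(r.get(c, np.nan) > 0 for c in service_cols)
            in_commodities = any(r.get(c, np.nan) > 0 for c in commodity_cols)
            if in_services and not in_commodities:
                flag(
                    year, method, "commodities", "sterilization_commodity_gap",
                    "recorded in visits/users only",
                    "expected recording gap for permanent methods",
                    severity="info",
                )

    for (method, ss_type, region), grp in annual.groupby(["method", "ss_type", "region"]):
        grp = grp.sort_values("year")
        if len(grp) < 3:
            continue
        for i in _robust_outliers(grp["count"], mad_factor, yoy_threshold):
            r = grp.iloc[i]
            flag(
                r["year"], method, ss_type, "annual_outlier",
                f"count={r['count']:g}",
                f"within {mad_factor:g} MAD of median and <{yoy_threshold:.0%} year-over-year change",
            )

    return pd.DataFrame(flags, columns=_FLAG_COLUMNS)


def external_benchmarks(
    emu: EMUSeries,
    users: UserSeries,
    surveys: SurveyBenchmarkTable,
    population: PopulationSeries,
    adjusted_users: UserSeries | None = None,
    growth_tolerance_pp: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Compare estimated users and EMU growth against survey benchmarks.

    Per overlapping survey year and method: survey users = survey prevalence
    × WRA, reported beside unadjusted (and adjusted, when supplied)
    estimated users with their ratios. Unadjusted estimates are expected to
    run below survey-based users; the private-sector adjustment should bring
    them closer. Per consecutive survey pair: annualized percentage-point
    change in survey mCP versus annualized change in adjusted EMU over the
    same years, flagged when they diverge by more than
    ``growth_tolerance_pp`` points per year.
    """
    notices: list[str] = []
    emu_years = set(emu.data["year"])
    overlap = [y for y in surveys.survey_years if y in emu_years]
    if not overlap:
        notices.append("no survey years overlap the EMU series; external benchmarking skipped")
        return pd.DataFrame(), pd.DataFrame(), notices

    comp_rows = []
    for year in overlap:
        wra = population.wra(year)
        svy = surveys.data[(surveys.data["year"] == year) & (surveys.data["method"] != "")]
        for _, s in svy.dropna(subset=["prevalence"]).iterrows():
            survey_users = s["prevalence"] * wra
            # report per ss_type so the user can judge each data stream
            sub = users.data[(users.data["year"] == year) & (users.data["method"] == s["method"])]
            for ss_type, grp in sub.groupby("ss_type"):
                est_u = float(grp["total"].sum())
                est_a = np.nan
                if adjusted_users is not None:
                    suba = adjusted_users.data[
                        (adjusted_users.data["year"] == year)
                        & (adjusted_users.data["method"] == s["method"])
                        & (adjusted_users.data["ss_type"] == ss_type)
                    ]
                    est_a = float(suba["total"].sum())
                comp_rows.append(
                    {
                        "survey_year": year,
                        "source": s["source"],
                        "method": s["method"],
                        "ss_type": ss_type,
                        "survey_users": survey_users,
                        "estimated_users_unadjusted": est_u,
                        "estimated_users_adjusted": est_a,
                        "ratio_unadjusted": est_u / survey_users if survey_users else np.nan,
                        "ratio_adjusted": est_a / survey_users if survey_users else np.nan,
                    }
                )
    external_comparison = pd.DataFrame(comp_rows)

    growth_rows = []
    mcp_by_year = (
        surveys.data.groupby("year")["mcp"].first().sort_index()
    )
    svy_years = [y for y in mcp_by_year.index]
    for y0, y1 in zip(svy_years, svy_years[1:]):
        span = y1 - y0
        mcp_change_pp = (mcp_by_year[y1] - mcp_by_year[y0]) * 100.0 / span
        for ss_type, grp in emu.data.groupby("ss_type"):
            g = grp.set_index("year")["emu_adjusted"]
            if y0 not in g.index or y1 not in g.index:
                continue
            emu_change_pp = (g[y1] - g[y0]) * 100.0 / span
            diff = emu_change_pp - mcp_change_pp
            growth_rows.append(
                {
                    "interval": f"{y0}-{y1}",
                    "ss_type": ss_type,
                    "survey_mcp_change_pp_per_year": mcp_change_pp,
                    "emu_change_pp_per_year": emu_change_pp,
                    "difference_pp_per_year": diff,
                    "flagged": bool(abs(diff) > growth_tolerance_pp),
                }
            )
    growth_comparison = pd.DataFrame(growth_rows)
    return external_comparison, growth_comparison, notices


def run_review(
    stats: ServiceStatisticsTable,
    registry: MethodRegistry,
    rates: ReportingRateSeries | None = None,
    emu: EMUSeries | None = None,
    users: UserSeries | None = None,
    adjusted_users: UserSeries | None = None,
    surveys: SurveyBenchmarkTable | None = None,
    population: PopulationSeries | None = None,
    threshold: float = 80.0,
    **kwargs,
) -> QualityReport:
    """Run every applicable part of the review and assemble a report."""
    report = QualityReport()
    if rates is not None:
        report.completeness = completeness_gate(rates, threshold=threshold)
    report.internal_flags = internal_benchmarks(stats, registry, **kwargs)
    if emu is not None and users is not None and surveys is not None and population is not None:
        ext, growth, notices = external_benchmarks(
            emu, users, surveys, population, adjusted_users=adjusted_users
        )
        report.external_comparison = ext
        report.growth_comparison = growth
        report.notices.extend(notices)
    return report
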