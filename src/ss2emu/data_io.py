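"""Readers and writers for the tabular inputs and outputs of the EMU engine.

Everything is UTF-8 CSV with a header row. Readers validate against the type
invariants and reject — never silently coerce — bad rows; a column-mapping
option accommodates exports from HMIS platforms whose headers differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .method_registry import MethodRegistry, SSType

__all__ = [
    "ServiceStatisticsTable",
    "PopulationSeries",
    "ReportingRateSeries",
    "SurveyBenchmarkTable",
    "DataValidationError",
    "read_service_statistics",
    "read_population",
    "read_reporting_rates",
    "read_survey_benchmarks",
    "write_results",
]

NATIONAL = ""  # sentinel region label for national-level records


class DataValidationError(ValueError):
    """An input file violates a table invariant."""


def _normalise_region(series: pd.Series | None, n: int) -> pd.Series:
    if series is None:
        return pd.Series([NATIONAL] * n)
    return series.fillna(NATIONAL).astype(str)


@dataclass
class ServiceStatisticsTable:
    """Raw service counts by year (× month) × method × statistic type (× region).

    Columns: ``year``, ``month`` (0 = annual record), ``method``,
    ``ss_type``, ``count``, ``region`` ("" = national).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("year", "method", "ss_type", "count"):
            if col not in df.columns:
                raise DataValidationError(f"service statistics missing column {col!r}")
        if "month" not in df.columns:
            df["month"] = 0
        df["month"] = df["month"].fillna(0).astype(int)
        if (~df["month"].between(0, 12)).any():
            bad = df.index[~df["month"].between(0, 12)][0]
            raise DataValidationError(f"row {bad}: month outside 1-12")
        df["region"] = _normalise_region(df.get("region"), len(df))
        df["year"] = df["year"].astype(int)
        df["count"] = df["count"].astype(float)
        neg = df.index[df["count"] < 0]
        if len(neg):
            raise DataValidationError(f"row {neg[0]}: negative count {df.loc[neg[0], 'count']}")
        bad_type = ~df["ss_type"].isin([t.value for t in SSType])
        if bad_type.any():
            i = df.index[bad_type][0]
            raise DataValidationError(
                f"row {i}: unknown ss_type {df.loc[i, 'ss_type']!r}; valid: "
                f"{[t.value for t in SSType]}"
            )
        key = ["year", "month", "method", "ss_type", "region"]
        if df.duplicated(subset=key).any():
            i = df.index[df.duplicated(subset=key)][0]
            raise DataValidationError(f"row {i}: duplicate (year, month, method, ss_type, region)")
        self.data = df[key[:2] + ["method", "ss_type", "count", "region"]].reset_index(drop=True)

    def annual(self) -> "ServiceStatisticsTable":
        """Aggregate monthly records to annual totals by summation."""
        df = (
            self.data.groupby(["year", "method", "ss_type", "region"], as_index=False)["count"]
            .sum()
        )
        df["month"] = 0
        return ServiceStatisticsTable(df)

    @property
    def methods(self) -> list[str]:
        return sorted(self.data["method"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())


@dataclass
class PopulationSeries:
    """Women of reproductive age (15-49) by year (× region), strictly positive.

    Missing years inside the observed range are linearly interpolated;
    requests outside the range raise rather than extrapolate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("year", "wra"):
            if col not in df.columns:
                raise DataValidationError(f"population series missing column {col!r}")
        df["region"] = _normalise_region(df.get("region"), len(df))
        df["year"] = df["year"].astype(int)
        df["wra"] = df["wra"].astype(float)
        bad = df.index[~(df["wra"] > 0)]
        if len(bad):
            raise DataValidationError(f"row {bad[0]}: population must be strictly positive")
        if df.duplicated(subset=["year", "region"]).any():
            raise DataValidationError("duplicate (year, region) in population series")
        self.data = df[["year", "wra", "region"]].reset_index(drop=True)

    def wra(self, year: int, region: str = NATIONAL) -> float:
        """WRA count for a year, interpolating linearly inside the known range."""
        sub = self.data[self.data["region"] == region].sort_values("year")
        if sub.empty:
            raise DataValidationError(f"no population data for region {region!r}")
        years = sub["year"].to_numpy()
        if year < years.min() or year > years.max():
            raise DataValidationError(
                f"population for year {year} outside known range "
                f"[{years.min()}, {years.max()}]; extrapolation is not performed"
            )
        return float(np.interp(year, years, sub["wra"].to_numpy()))


@dataclass
class ReportingRateSeries:
    """Facility reporting rates (percent, 0-100) by year (× region)."""

    data: pd.DataFrame
    fp_specific: bool = True  # provenance tag only; no behavioural difference

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("year", "rate"):
            if col not in df.columns:
                raise DataValidationError(f"reporting rates missing column {col!r}")
        df["region"] = _normalise_region(df.get("region"), len(df))
        df["year"] = df["year"].astype(int)
        df["rate"] = df["rate"].astype(float)
        bad = df.index[~df["rate"].between(0, 100)]
        if len(bad):
            raise DataValidationError(
                f"row {bad[0]}: reporting rate {df.loc[bad[0], 'rate']} outside [0, 100]"
            )
        self.data = df[["year", "rate", "region"]].reset_index(drop=True)


@dataclass
class SurveyBenchmarkTable:
    """Survey benchmarks: per survey year, mCP and optional per-method detail.

    Columns: ``year``, ``source``, ``mcp`` (proportion), ``method`` ("" for
    the all-methods row), ``prevalence`` (per-method, proportion),
    ``covered_share`` (per-method source-of-supply share reporting to HMIS).
    """

    data: pd.DataFrame
    _TOL = 1e-6

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("year", "source", "mcp"):
            if col not in df.columns:
                raise DataValidationError(f"survey benchmarks missing column {col!r}")
        for col, default in (("method", ""), ("prevalence", np.nan), ("covered_share", np.nan)):
            if col not in df.columns:
                df[col] = default
        df["year"] = df["year"].astype(int)
        df["method"] = df["method"].fillna("").astype(str)
        for col in ("mcp", "prevalence", "covered_share"):
            df[col] = df[col].astype(float)
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise DataValidationError(f"{col} must be a proportion in [0, 1]")
        for (year, source), grp in df.groupby(["year", "source"]):
            mcp = grp["mcp"].iloc[0]
            per_method = grp.loc[grp["method"] != "", "prevalence"].dropna()
            if len(per_method) and per_method.sum() > mcp + 1e-3:
                raise DataValidationError(
                    f"survey {source!r} {year}: per-method prevalences sum to "
                    f"{per_method.sum():.4f} > mCP {mcp:.4f}"
                )
        self.data = df[["year", "source", "mcp", "method", "prevalence", "covered_share"]]

    @property
    def survey_years(self) -> list[int]:
        return sorted(self.data["year"].unique())


def _read_csv(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_service_statistics(
    path: str | Path,
    registry: MethodRegistry | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ServiceStatisticsTable:
    """Read a service-statistics CSV, optionally validating methods against a registry."""
    table = ServiceStatisticsTable(_read_csv(path, column_map))
    if registry is not None:
        unknown = [m for m in table.methods if m not in registry]
        if unknown:
            raise DataValidationError(
                f"methods not in registry: {unknown}; valid methods: {registry.names}"
            )
    return table


def read_population(path: str | Path, column_map: Mapping[str, str] | None = None) -> PopulationSeries:
    return PopulationSeries(_read_csv(path, column_map))


def read_reporting_rates(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    fp_specific: bool = True,
) -> ReportingRateSeries:
    return ReportingRateSeries(_read_csv(path, column_map), fp_specific=fp_specific)


def read_survey_benchmarks(path: str | Path, column_map: Mapping[str, str] | None = None) -> SurveyBenchmarkTable:
    return SurveyBenchmarkTable(_read_csv(path, column_map))


_FLOAT_FMT = "%.6f"


def write_results(emu_series, user_series, quality_report, out_dir: str | Path) -> dict[str, Path]:
    """Write EMU, user-decomposition and quality-review tables as CSV.

    Column order is deterministic and floats are written at 6 decimal
    places, so a written file read back reproduces its values exactly at
    that precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _dump(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written[name] = p

    if emu_series is not None:
        _dump(emu_series.data, "emu.csv")
    if user_series is not None:
        _dump(user_series.data, "users.csv")
    if quality_report is not None:
        _dump(quality_report.completeness, "quality_completeness.csv")
        _dump(quality_report.internal_flags, "quality_internal_flags.csv")
        _dump(quality_report.external_comparison, "quality_external.csv")
        _dump(quality_report.growth_comparison, "quality_growth.csv")
        (out / "quality_summary.txt").write_text(quality_report.narrative(), encoding="utf-8")
        written["quality_summary.txt"] = out / "quality_summary.txt"
    return written
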