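"""End-to-end orchestration: statistics in, EMU series and review out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .adjustment_emu import CoverageShares, EMUSeries, apply_adjustment, compute_emu
from .data_io import (
    PopulationSeries,
    ReportingRateSeries,
    ServiceStatisticsTable,
    SurveyBenchmarkTable,
)
from .method_registry import HistoricScenario, MethodRegistry
from .quality_review import QualityReport, apply_completeness, run_review
from .user_estimation import UserSeries, estimate_users

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    users_unadjusted: UserSeries
    users_adjusted: UserSeries
    emu: EMUSeries
    report: QualityReport


def run_pipeline(
    stats: ServiceStatisticsTable,
    population: PopulationSeries,
    registry: MethodRegistry,
    scenarios: Mapping[str, HistoricScenario | str] | None = None,
    shares: CoverageShares | None = None,
    reporting_rates: ReportingRateSeries | None = None,
    surveys: SurveyBenchmarkTable | None = None,
    exclusions: Iterable[str] = (),
    completeness_threshold: float = 80.0,
) -> PipelineResult:
    """Estimate users, adjust for the private sector, compute EMU and review.

    Covered shares default to full coverage (adjusted = unadjusted) and the
    completeness gate only applies when reporting rates are supplied.
    """
    shares = shares or CoverageShares({})
    users = estimate_users(stats, registry, scenarios=scenarios, exclusions=exclusions)
    adjusted = apply_adjustment(users, shares)
    emu = compute_emu(adjusted, users, population)
    report = run_review(
        stats,
        registry,
        rates=reporting_rates,
        emu=emu,
        users=users,
        adjusted_users=adjusted,
        surveys=surveys,
        population=population,
        threshold=completeness_threshold,
    )
    if reporting_rates is not None:
        emu = apply_completeness(emu, report.completeness)
    return PipelineResult(users_unadjusted=users, users_adjusted=adjusted, emu=emu, report=report)
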