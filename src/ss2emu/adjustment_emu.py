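"""Private-sector adjustment and the final EMU series.

Routine HMIS data rarely captures the full family planning market: shops
and pharmacies supplying pills and condoms, private clinics inserting
implants. The adjustment scales each method's estimated users by the
reciprocal of its *covered share* — the proportion of that method's users
whose source of supply reports into the HMIS — before aggregating the EMU
numerator and dividing by women of reproductive age (WRA, 15-49).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .data_io import PopulationSeries
from .user_estimation import UserSeries

__all__ = ["CoverageShares", "EMUSeries", "adjustment_factor", "apply_adjustment", "compute_emu"]

logger = logging.getLogger(__name__)


def adjustment_factor(covered_share: float) -> float:
    """Multiplier 1 / covered_share; ≥ 1 since shares are in (0, 1]."""
    if not 0.0 < covered_share <= 1.0:
        raise ValueError(f"covered share must be in (0, 1], got {covered_share}")
    return 1.0 / covered_share


@dataclass
class CoverageShares:
    """Per-method proportion of users whose supply source reports into HMIS.

    ``covered_share = public_share + capture_fraction × (1 − public_share)``:
    the public-sector market share from survey source-of-supply data plus
    whatever fraction of private provision the HMIS captures (default 0).
    Methods without a declared share default to full coverage (factor 1)
    with a logged warning.
    """

    shares: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, s in self.shares.items():
            adjustment_factor(s)  # validates range, raising on bad shares
        self.shares = dict(self.shares)

    @classmethod
    def from_public_shares(
        cls,
        public_shares: Mapping[str, float],
        capture_fractions: Mapping[str, float] | float = 0.0,
    ) -> "CoverageShares":
        shares = {}
        for m, p in public_shares.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"public share for {m!r} must be in [0, 1], got {p}")
            cap = capture_fractions if isinstance(capture_fractions, (int, float)) else capture_fractions.get(m, 0.0)
            if not 0.0 <= cap <= 1.0:
                raise ValueError(f"capture fraction for {m!r} must be in [0, 1], got {cap}")
            shares[m] = p + cap * (1.0 - p)
        return cls(shares)

    def factor(self, method: str) -> float:
        if method not in self.shares:
            logger.warning("no covered share for method %r; assuming full coverage", method)
            return 1.0
        return adjustment_factor(self.shares[method])


def apply_adjustment(user_series: UserSeries, shares: CoverageShares) -> UserSeries:
    """Scale each method's user components by its private-sector factor.

    Adjustment is applied method by method *before* any aggregation, so the
    adjusted aggregate equals the sum of individually adjusted methods.
    """
    df = user_series.data.copy()
    factors = df["method"].map(lambda m: shares.factor(m))
    for col in ("current", "continuing", "historic", "total"):
        df[col] = df[col] * factors
    return UserSeries(df)


_EMU_COLUMNS = [
    "year",
    "ss_type",
    "region",
    "numerator_unadjusted",
    "numerator_adjusted",
    "population",
    "emu_unadjusted",
    "emu_adjusted",
    "included",
    "validation_flag",
]


@dataclass
class EMUSeries:
    """Per (year, ss_type, region): numerators, WRA denominator and EMU rates.

    EMU values are proportions. ``included`` is the data-quality trend gate
    (True until a completeness review excludes the year); ``validation_flag``
    marks the pathological case of an EMU above 1 (more estimated users than
    women of reproductive age).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in _EMU_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"EMU series missing column {col!r}")
        self.data = df[_EMU_COLUMNS].reset_index(drop=True)

    def as_percent(self) -> pd.DataFrame:
        """Presentation rendering with EMU in percent."""
        df = self.data.copy()
        df["emu_unadjusted"] *= 100.0
        df["emu_adjusted"] *= 100.0
        return df


def compute_emu(
    adjusted: UserSeries,
    unadjusted: UserSeries,
    population: PopulationSeries,
) -> EMUSeries:
    """Divide adjusted and unadjusted numerators by the WRA population.

    Regional rows use regional WRA denominators. A missing population year
    (outside the interpolation range) raises, naming the year.
    """
    adj = adjusted.numerator().rename(columns={"total": "numerator_adjusted"})
    unadj = unadjusted.numerator().rename(columns={"total": "numerator_unadjusted"})
    merged = pd.merge(
        unadj[["year", "ss_type", "region", "numerator_unadjusted"]],
        adj[["year", "ss_type", "region", "numerator_adjusted"]],
        on=["year", "ss_type", "region"],
        how="outer",
    ).fillna({"numerator_unadjusted": 0.0, "numerator_adjusted": 0.0})
    rows = []
    for _, r in merged.sort_values(["ss_type", "region", "year"]).iterrows():
        wra = population.wra(int(r["year"]), r["region"])
        emu_u = r["numerator_unadjusted"] / wra
        emu_a = r["numerator_adjusted"] / wra
        rows.append(
            {
                "year": int(r["year"]),
                "ss_type": r["ss_type"],
                "region": r["region"],
                "numerator_unadjusted": r["numerator_unadjusted"],
                "numerator_adjusted": r["numerator_adjusted"],
                "population": wra,
                "emu_unadjusted": emu_u,
                "emu_adjusted": emu_a,
                "included": True,
                "validation_flag": bool(emu_u > 1.0 or emu_a > 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=_EMU_COLUMNS)
    if out["validation_flag"].any():
        bad = out.loc[out["validation_flag"], "year"].tolist()
        logger.warning("EMU exceeds 1.0 (more users than WRA) in years %s", bad)
    return EMUSeries(out)
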