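"""Method definitions, CYP factors and continuation curves.

The registry is the parameter store for the whole EMU engine: every other
module looks up a method's category, its couple-years-of-protection (CYP)
conversion factors, and — for long-acting and permanent methods — its
continuation curve ``Con(x)``, the proportion of adopters still using the
method in their *x*-th year of use.

Parameters ship as a versioned YAML document (one per country/program) so
that curves and factors remain editable data, not code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SSType",
    "MethodCategory",
    "HistoricScenario",
    "ContinuationCurve",
    "MethodSpec",
    "MethodRegistry",
    "RegistryValidationError",
    "load_registry",
    "continuation_at",
]


class SSType(str, enum.Enum):
    """The four kinds of routine family planning service statistics."""

    COMMODITIES_CLIENTS = "commodities_clients"
    COMMODITIES_FACILITIES = "commodities_facilities"
    VISITS = "visits"
    USERS = "users"


class MethodCategory(str, enum.Enum):
    SHORT_TERM = "short_term"
    LONG_ACTING_REVERSIBLE = "long_acting_reversible"
    PERMANENT = "permanent"


class HistoricScenario(str, enum.Enum):
    """Program maturity for a long-acting method in the first year of data.

    Determines how users provided *before* the data window are back-cast:
    ``no_historic`` (provision began with the data), ``scaling_up``
    (half the at-scale back-cast) or ``at_scale`` (pre-window provision
    assumed similar to the first observed year).
    """

    NO_HISTORIC = "no_historic"
    SCALING_UP = "scaling_up"
    AT_SCALE = "at_scale"


class RegistryValidationError(ValueError):
    """A method definition violates a registry invariant."""


@dataclass(frozen=True)
class ContinuationCurve:
    """Ordered continuation rates Con(1..K); Con(x) = 0 for x > K.

    Values are proportions in [0, 1] and must be non-increasing: fewer
    adopters remain with each additional year of use.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise RegistryValidationError("continuation curve must be non-empty")
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        for i, v in enumerate(vals):
            if not (0.0 <= v <= 1.0):
                raise RegistryValidationError(
                    f"continuation value out of [0,1] at index {i}: {v}"
                )
            if i and v > vals[i - 1]:
                raise RegistryValidationError(
                    f"continuation curve increases at index {i}: "
                    f"{vals[i - 1]} -> {v}"
                )

    def __len__(self) -> int:
        return len(self.values)

    def at(self, x: int) -> float:
        """Continuation rate in year-of-use ``x`` (1-based); 0 beyond support."""
        return continuation_at(self, x)

    @property
    def person_years(self) -> float:
        """Total expected person-years of use per adopter, sum of Con(x)."""
        return float(sum(self.values))


def continuation_at(curve: ContinuationCurve, x: int) -> float:
    """Return Con(x) for 1-based year-of-use ``x``; 0 for x beyond the curve."""
    if x < 1:
        raise ValueError(f"year of use must be >= 1, got {x}")
    if x > len(curve.values):
        return 0.0
    return curve.values[x - 1]


@dataclass(frozen=True)
class MethodSpec:
    """A contraceptive method's conversion parameters.

    Short-term methods carry ``units_per_cyp`` per service-statistic type
    (e.g. 4 DMPA-IM doses per CYP). Long-acting/permanent methods carry a
    continuation curve, a maximum protection duration ``duration_years``
    (L_max, at most 10 years) and a ``cyp_per_service`` credit used for CYP
    reporting (e.g. 4.6 per Copper-T insertion).
    """

    name: str
    category: MethodCategory
    duration_years: int = 1
    units_per_cyp: Mapping[str, float] = field(default_factory=dict)
    cyp_per_service: float | None = None
    continuation: ContinuationCurve | None = None
    excludable: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.duration_years <= 10:
            raise RegistryValidationError(
                f"{self.name}: duration_years must be in [1, 10], "
                f"got {self.duration_years}"
            )
        if self.category is MethodCategory.SHORT_TERM:
            conv = {k for k in self.units_per_cyp}
            if not conv:
                raise RegistryValidationError(
                    f"{self.name}: short-term method needs units_per_cyp for "
                    "every accepted service-statistic type"
                )
            for s, u in self.units_per_cyp.items():
                if s not in {t.value for t in SSType} or s == SSType.USERS.value:
                    raise RegistryValidationError(
                        f"{self.name}: units_per_cyp keyed by unknown "
                        f"service-statistic type {s!r}"
                    )
                if not u > 0:
                    raise RegistryValidationError(
                        f"{self.name}: units_per_cyp[{s}] must be positive, got {u}"
                    )
        else:
            if self.continuation is None:
                raise RegistryValidationError(
                    f"{self.name}: long-acting/permanent method requires a "
                    "continuation curve"
                )
            if len(self.continuation) < self.duration_years:
                raise RegistryValidationError(
                    f"{self.name}: continuation curve length "
                    f"{len(self.continuation)} shorter than duration_years "
                    f"{self.duration_years}"
                )
            if self.cyp_per_service is not None and not self.cyp_per_service > 0:
                raise RegistryValidationError(
                    f"{self.name}: cyp_per_service must be positive"
                )

    @property
    def is_long_acting(self) -> bool:
        return self.category is not MethodCategory.SHORT_TERM

    def accepts(self, ss_type: SSType | str) -> bool:
        """Whether this method can be estimated from the given statistic type."""
        s = SSType(ss_type)
        if s is SSType.USERS:
            return True  # true user counts pass through for any method
        if self.category is MethodCategory.SHORT_TERM:
            return s.value in self.units_per_cyp
        return True


_KNOWN_METHOD_FIELDS = {
    "name",
    "category",
    "duration_years",
    "units_per_cyp",
    "cyp_per_service",
    "continuation",
    "excludable",
}


class MethodRegistry:
    """Validated collection of :class:`MethodSpec`, keyed by method name."""

    def __init__(self, methods: Mapping[str, MethodSpec] | None = None):
        self._methods: dict[str, MethodSpec] = dict(methods or {})

    def __contains__(self, name: str) -> bool:
        return name in self._methods

    def __getitem__(self, name: str) -> MethodSpec:
        try:
            return self._methods[name]
        except KeyError:
            raise KeyError(
                f"unknown method {name!r}; registry has: "
                f"{sorted(self._methods)}"
            ) from None

    def __iter__(self):
        return iter(self._methods.values())

    def __len__(self) -> int:
        return len(self._methods)

    @property
    def names(self) -> list[str]:
        return sorted(self._methods)

    def add(self, spec: MethodSpec) -> None:
        if spec.name in self._methods:
            raise RegistryValidationError(f"duplicate method {spec.name!r}")
        self._methods[spec.name] = spec


def _parse_method(entry: Mapping) -> MethodSpec:
    if not isinstance(entry, Mapping):
        raise RegistryValidationError(f"method entry is not a mapping: {entry!r}")
    unknown = set(entry) - _KNOWN_METHOD_FIELDS
    if unknown:
        raise RegistryValidationError(
            f"method {entry.get('name', '?')!r}: unknown fields {sorted(unknown)}"
        )
    if "name" not in entry or "category" not in entry:
        raise RegistryValidationError(f"method entry missing name/category: {entry!r}")
    try:
        category = MethodCategory(entry["category"])
    except ValueError:
        raise RegistryValidationError(
            f"method {entry['name']!r}: unknown category {entry['category']!r}"
        ) from None
    curve = None
    if entry.get("continuation") is not None:
        try:
            curve = ContinuationCurve(tuple(entry["continuation"]))
        except RegistryValidationError as exc:
            raise RegistryValidationError(f"method {entry['name']!r}: {exc}") from None
    kwargs = dict(
        name=str(entry["name"]),
        category=category,
        units_per_cyp={str(k): float(v) for k, v in (entry.get("units_per_cyp") or {}).items()},
        cyp_per_service=(
            float(entry["cyp_per_service"]) if entry.get("cyp_per_service") is not None else None
        ),
        continuation=curve,
        excludable=bool(entry.get("excludable", False)),
    )
    if "duration_years" in entry:
        kwargs["duration_years"] = int(entry["duration_years"])
    elif curve is not None:
        kwargs["duration_years"] = len(curve)
    return MethodSpec(**kwargs)


def default_config_path() -> Path:
    """Path of the YAML parameter file shipped with the package."""
    return Path(resources.files("ss2emu").joinpath("data/default_methods.yaml"))  # type: ignore[arg-type]


def load_registry(config: str | Path | None = None) -> MethodRegistry:
    """Load and validate a method registry from a YAML parameter file.

    With no argument, loads the shipped default registry (standard CYP
    factors and the Copper-T anchored continuation curves).
    """
    path = Path(config) if config is not None else default_config_path()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise RegistryValidationError(f"{path}: top level must be a mapping")
    unknown = set(doc) - {"schema_version", "methods"}
    if unknown:
        raise RegistryValidationError(f"{path}: unknown top-level fields {sorted(unknown)}")
    registry = MethodRegistry()
    for entry in doc.get("methods") or []:
        registry.add(_parse_method(entry))
    return registry
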