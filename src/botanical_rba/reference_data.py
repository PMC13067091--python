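"""Registry of printed study constants with unit-aware validation.

Holds everything the assessment consumes as fixed input: the ten elements
and their canonical units, baseline dietary intake summaries for Italian
adults, per-element concentration summaries across the 25 botanical
extracts (with their best-fitting distribution family), botanical
consumption patterns, and the benefit/risk reference values (EFSA DRVs,
HBGVs, reference points and US EPA RfDs).

All values are bundled in ``data/registry.yml`` and validated on load:
exactly the ten expected elements, a complete set of reference triples,
the three consumption patterns, and resolvable canonical units.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ELEMENTS",
    "ESSENTIALS",
    "TOXICS",
    "SummaryMoments",
    "ElementSpec",
    "HealthReference",
    "ConsumptionPattern",
    "Registry",
    "load_registry",
    "canonicalize_units",
    "RegistryError",
    "UnitError",
]

ESSENTIALS = ("K", "P", "Ca", "Mg", "Fe", "Zn")
TOXICS = ("Al", "Ni", "As", "Pb")
ELEMENTS = ESSENTIALS + TOXICS

#: reference triples that must be present for the assessment to run
REQUIRED_REFERENCES = frozenset(
    [
        ("K", "AI", "adequate intake"),
        ("P", "AI", "adequate intake"),
        ("Ca", "PRI", "population reference intake"),
        ("Mg", "AI", "adequate intake"),
        ("Fe", "PRI", "population reference intake"),
        ("Zn", "PRI", "population reference intake"),
        ("Al", "TWI", "neurotoxicity"),
        ("Ni", "TDI", "reproductive and developmental toxicity"),
        ("Ni", "LOAEL", "systemic contact dermatitis"),
        ("As", "BMDL", "skin cancer"),
        ("Pb", "BMDL", "cardiovascular effects"),
        ("Pb", "BMDL", "nephrotoxicity"),
        ("Al", "RfD", "chronic oral reference dose"),
        ("As", "RfD", "chronic oral reference dose"),
        ("Fe", "RfD", "chronic oral reference dose"),
        ("Ni", "RfD", "chronic oral reference dose"),
        ("Zn", "RfD", "chronic oral reference dose"),
    ]
)


class RegistryError(ValueError):
    """Raised when the bundled configuration is incomplete or inconsistent."""


class UnitError(ValueError):
    """Raised on unresolvable or dimensionally incompatible units."""


# ---------------------------------------------------------------------------
# units
#
# A unit is decomposed into (mass scale in mg, per-kg-extract?, per-kg-bw?,
# time basis). Conversions are powers of 10^3 on the mass prefix plus the
# factor 7 between daily and weekly bases; any change of dimension is an
# error. "ug"/"µg"/"μg" are accepted dialects for micrograms.

_MASS_MG = {"g": 1000.0, "mg": 1.0, "ug": 1e-3, "µg": 1e-3, "μg": 1e-3}
_TIME_TOKENS = {"day-1": "day", "week-1": "week"}


@dataclass(frozen=True)
class _UnitDim:
    mass_mg: float  # multiplicative factor to milligrams
    per_kg_extract: bool
    per_kg_bw: bool
    basis: str  # day | week | event


def _parse_units(units: str) -> _UnitDim:
    tokens = units.replace("^", " ").split()
    if not tokens or tokens[0] not in _MASS_MG:
        raise UnitError(f"unresolvable units: {units!r}")
    mass = _MASS_MG[tokens[0]]
    per_kg_extract = False
    per_kg_bw = False
    basis = "event"
    for tok in tokens[1:]:
        if tok == "kg-1":
            per_kg_extract = True
        elif tok == "kg_bw-1":
            per_kg_bw = True
        elif tok in _TIME_TOKENS:
            basis = _TIME_TOKENS[tok]
        else:
            raise UnitError(f"unresolvable unit token {tok!r} in {units!r}")
    return _UnitDim(mass, per_kg_extract, per_kg_bw, basis)


def canonicalize_units(value: float, from_units: str, to_units: str) -> float:
    """Convert ``value`` between unit dialects of the same dimension.

    Allowed conversions are mass-prefix rescalings (powers of 10^3) and the
    daily/weekly basis change (factor 7). A per-bodyweight dose can never be
    converted to a plain mass, nor a per-event dose to a daily one.
    """
    src, dst = _parse_units(from_units), _parse_units(to_units)
    if src.per_kg_extract != dst.per_kg_extract or src.per_kg_bw != dst.per_kg_bw:
        raise UnitError(f"incompatible dimensions: {from_units!r} -> {to_units!r}")
    out = value * src.mass_mg / dst.mass_mg
    if src.basis != dst.basis:
        if {src.basis, dst.basis} != {"day", "week"}:
            raise UnitError(f"incompatible time basis: {from_units!r} -> {to_units!r}")
        out = out * 7.0 if dst.basis == "week" else out / 7.0
    return out


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SummaryMoments:
    """Arithmetic mean +/- SD (optionally median, P5, P95) with units."""

    mean: float
    sd: float | None = None
    median: float | None = None
    p5: float | None = None
    p95: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise RegistryError(f"negative mean in {self}")
        if self.sd is not None and self.sd <= 0:
            raise RegistryError(f"non-positive sd in {self}")
        if self.p5 is not None and self.median is not None and self.p95 is not None:
            if not (self.p5 <= self.median <= self.p95):
                raise RegistryError(f"p5 <= median <= p95 violated in {self}")


@dataclass(frozen=True)
class ElementSpec:
    symbol: str
    element_class: str  # essential | toxic
    concentration_units: str
    intake_units: str

    @property
    def is_essential(self) -> bool:
        return self.element_class == "essential"


@dataclass(frozen=True)
class HealthReference:
    """One benefit or risk anchor (AI/PRI/UL/TDI/TWI/BMDL/LOAEL/RfD)."""

    element: str
    kind: str
    value: float
    units: str
    endpoint: str
    basis: str  # daily | weekly | per_event
    supplemental: bool = False

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise RegistryError(f"non-positive reference value: {self}")


@dataclass(frozen=True)
class ConsumptionPattern:
    mode: str  # chronic_total_g_per_day | chronic_g_per_kgbw_day | acute_g_per_kgbw
    moments: SummaryMoments


@dataclass(frozen=True)
class Registry:
    """Immutable, validated bundle of every printed input."""

    elements: Mapping[str, ElementSpec]
    baseline_intakes: Mapping[str, SummaryMoments]
    concentrations: Mapping[str, tuple[str, SummaryMoments]]
    consumption: Mapping[str, ConsumptionPattern]
    references: tuple[HealthReference, ...]
    products: tuple[str, ...]
    body_weight_kg: float
    exposure_factor: Mapping[str, Mapping[str, float]]
    source: str = ""

    def reference(self, element: str, kind: str, endpoint: str | None = None) -> HealthReference:
        """Look up a unique reference by (element, kind[, endpoint])."""
        hits = [
            r
            for r in self.references
            if r.element == element
            and r.kind == kind
            and (endpoint is None or r.endpoint == endpoint)
        ]
        if not hits:
            raise RegistryError(f"no reference ({element}, {kind}, {endpoint})")
        if len(hits) > 1:
            raise RegistryError(
                f"ambiguous reference ({element}, {kind}): specify endpoint among "
                f"{[r.endpoint for r in hits]}"
            )
        return hits[0]

    def rfd(self, element: str) -> HealthReference:
        return self.reference(element, "RfD")

    def to_dict(self) -> dict:
        """Re-serialize the registry (round-trips through the loader)."""
        return {
            "body_weight_kg": self.body_weight_kg,
            "elements": {
                s: {
                    "class": e.element_class,
                    "concentration_units": e.concentration_units,
                    "intake_units": e.intake_units,
                }
                for s, e in self.elements.items()
            },
            "baseline_intakes": {
                s: {"mean": m.mean, "sd": m.sd, "units": m.units}
                for s, m in self.baseline_intakes.items()
            },
            "concentrations": {
                s: {
                    "family": fam,
                    "mean": m.mean,
                    "sd": m.sd,
                    "median": m.median,
                    "p5": m.p5,
                    "p95": m.p95,
                    "units": m.units,
                }
                for s, (fam, m) in self.concentrations.items()
            },
            "consumption": {
                mode: {"mean": p.moments.mean, "sd": p.moments.sd, "units": p.moments.units}
                for mode, p in self.consumption.items()
            },
            "health_references": [
                {
                    "element": r.element,
                    "kind": r.kind,
                    "value": r.value,
                    "units": r.units,
                    "endpoint": r.endpoint,
                    "basis": r.basis,
                    **({"supplemental": True} if r.supplemental else {}),
                }
                for r in self.references
            ],
            "products": list(self.products),
            "exposure_factor": {k: dict(v) for k, v in self.exposure_factor.items()},
        }


# ---------------------------------------------------------------------------
# loading


def _moments(raw: Mapping, context: str) -> SummaryMoments:
    try:
        return SummaryMoments(
            mean=float(raw["mean"]),
            sd=None if raw.get("sd") is None else float(raw["sd"]),
            median=None if raw.get("median") is None else float(raw["median"]),
            p5=None if raw.get("p5") is None else float(raw["p5"]),
            p95=None if raw.get("p95") is None else float(raw["p95"]),
            units=str(raw.get("units", "")),
        )
    except KeyError as exc:  # pragma: no cover - config authoring error
        raise RegistryError(f"missing field {exc} in {context}") from exc


def default_config_path() -> Path:
    return Path(str(importlib.resources.files("botanical_rba") / "data" / "registry.yml"))


def load_registry(config_path: str | Path | None = None) -> Registry:
    """Load and validate the registry from a YAML config.

    With no argument the bundled default is used. Raises
    :class:`RegistryError` naming the offending entry on any missing
    element, missing/duplicate reference triple, or unresolvable unit.
    """
    path = Path(config_path) if config_path is not None else default_config_path()
    raw = yaml.safe_load(path.read_text())
    return registry_from_dict(raw, source=str(path))


def registry_from_dict(raw: Mapping, source: str = "<dict>") -> Registry:
    elements = {}
    for sym, e in dict(raw.get("elements", {})).items():
        spec = ElementSpec(sym, e["class"], e["concentration_units"], e["intake_units"])
        _parse_units(spec.concentration_units)
        _parse_units(spec.intake_units)
        elements[sym] = spec
    missing = set(ELEMENTS) - set(elements)
    extra = set(elements) - set(ELEMENTS)
    if missing or extra:
        raise RegistryError(f"element set mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
    for sym in ESSENTIALS:
        if not elements[sym].is_essential:
            raise RegistryError(f"{sym} must be classed essential")
    for sym in TOXICS:
        if elements[sym].is_essential:
            raise RegistryError(f"{sym} must be classed toxic")

    baseline = {
        sym: _moments(m, f"baseline_intakes[{sym}]")
        for sym, m in dict(raw.get("baseline_intakes", {})).items()
    }
    concentrations = {}
    for sym, c in dict(raw.get("concentrations", {})).items():
        fam = c.get("family")
        if fam not in ("lognormal", "exponential"):
            raise RegistryError(f"concentrations[{sym}]: unsupported family {fam!r}")
        concentrations[sym] = (fam, _moments(c, f"concentrations[{sym}]"))
    if set(concentrations) != set(ELEMENTS):
        raise RegistryError("concentration summaries must cover all 10 elements")

    consumption = {
        mode: ConsumptionPattern(mode, _moments(m, f"consumption[{mode}]"))
        for mode, m in dict(raw.get("consumption", {})).items()
    }
    for mode in ("chronic_total_g_per_day", "chronic_g_per_kgbw_day", "acute_g_per_kgbw"):
        if mode not in consumption:
            raise RegistryError(f"missing consumption pattern {mode!r}")

    references = []
    seen = set()
    for r in raw.get("health_references", []):
        ref = HealthReference(
            element=r["element"],
            kind=r["kind"],
            value=float(r["value"]),
            units=str(r["units"]),
            endpoint=str(r["endpoint"]),
            basis=str(r["basis"]),
            supplemental=bool(r.get("supplemental", False)),
        )
        _parse_units(ref.units)
        if ref.element not in elements:
            raise RegistryError(f"reference for unknown element {ref.element!r}")
        triple = (ref.element, ref.kind, ref.endpoint)
        if triple in seen:
            raise RegistryError(f"duplicate reference triple {triple}")
        seen.add(triple)
        references.append(ref)
    missing_refs = REQUIRED_REFERENCES - seen
    if missing_refs:
        name = ", ".join(str(t) for t in sorted(missing_refs))
        raise RegistryError(f"missing required reference(s): {name}")

    return Registry(
        elements=elements,
        baseline_intakes=baseline,
        concentrations=concentrations,
        consumption=consumption,
        references=tuple(references),
        products=tuple(raw.get("products", [])),
        body_weight_kg=float(raw.get("body_weight_kg", 70.0)),
        exposure_factor={k: dict(v) for k, v in dict(raw.get("exposure_factor", {})).items()},
        source=source,
    )
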