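"""Benefit and risk metrics derived from exposure draws.

* %DRV — percentage contribution of an intake to a dietary reference
  value (benefit, essentials), with exact iteration-wise additivity
  between the baseline and botanicals contributions;
* %TDI / %TWI — percentage of a tolerable daily/weekly intake (risk,
  Ni and Al);
* MOE — margin of exposure, reference point (BMDL or LOAEL) divided by
  the intake, evaluated per iteration;
* exceedance fractions against annotated concern thresholds (MOE < 10
  for BMDL-based endpoints, < 30 for Ni sensitization, < 1 where the
  exposure exceeds the reference point).

Basis mismatches (e.g. daily Al draws against the weekly TWI) raise
immediately rather than silently mis-scaling by 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exposure import ExposureDraws, combine
from .reference_data import HealthReference, UnitError, canonicalize_units

__all__ = [
    "MetricDraws",
    "percent_reference",
    "percent_drv_total",
    "margin_of_exposure",
    "exceedance_fraction",
    "MOE_THRESHOLDS",
]

#: interpretation cutpoints carried as data, not code
MOE_THRESHOLDS = {"bmdl_concern": 10.0, "ni_sensitization": 30.0, "exceeds_reference": 1.0}

_BASIS_MAP = {"daily": "daily", "weekly": "weekly", "per_event": "per_event"}


@dataclass(frozen=True)
class MetricDraws:
    """Per-iteration values of a derived metric with its defining reference."""

    element: str
    scenario: str
    metric: str  # pct_drv | pct_tdi | pct_twi | moe | thq
    reference: HealthReference
    values: np.ndarray
    thresholds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.reference.element != self.element:
            raise ValueError(
                f"reference element {self.reference.element!r} does not match {self.element!r}"
            )
        if np.any(v < 0):
            raise ValueError("metric draws must be non-negative")


def _check_basis(draws: ExposureDraws, reference: HealthReference) -> float:
    """Validate draw/reference pairing; return the reference value in draw units."""
    if _BASIS_MAP[draws.basis] != reference.basis:
        raise UnitError(
            f"{draws.element}: draws on basis {draws.basis!r} cannot be compared with a "
            f"{reference.kind} on basis {reference.basis!r}"
        )
    try:
        return canonicalize_units(reference.value, reference.units, draws.units)
    except UnitError as exc:
        raise UnitError(f"{draws.element} {reference.kind}: {exc}") from exc


def _pct_metric_name(reference: HealthReference) -> str:
    return {
        "TDI": "pct_tdi",
        "TWI": "pct_twi",
    }.get(reference.kind, "pct_drv")


def percent_reference(draws: ExposureDraws, reference: HealthReference) -> MetricDraws:
    """100 x intake / reference, per iteration (benefit %DRV or risk %TDI/%TWI)."""
    ref_value = _check_basis(draws, reference)
    return MetricDraws(
        element=draws.element,
        scenario=draws.scenario,
        metric=_pct_metric_name(reference),
        reference=reference,
        values=100.0 * draws.values / ref_value,
    )


def percent_drv_total(
    baseline: ExposureDraws, botanicals: ExposureDraws, reference: HealthReference
) -> MetricDraws:
    """Combined-scenario %DRV; identically equal to %baseline + %botanicals."""
    combined = combine(baseline, botanicals)
    out = percent_reference(combined, reference)
    return MetricDraws(
        element=out.element,
        scenario="combined",
        metric=out.metric,
        reference=reference,
        values=out.values,
        thresholds=dict(out.thresholds),
    )


def margin_of_exposure(draws: ExposureDraws, reference: HealthReference) -> MetricDraws:
    """MOE = reference point / intake, per iteration.

    Satisfies MOE_i x intake_i = reference exactly, hence the quantile
    duality Q_p(MOE) = reference / Q_(1-p)(intake).
    """
    if reference.kind not in ("BMDL", "LOAEL"):
        raise ValueError(f"MOE needs a BMDL or LOAEL reference, got {reference.kind}")
    ref_value = _check_basis(draws, reference)
    thresholds = (
        {"concern": MOE_THRESHOLDS["ni_sensitization"]}
        if reference.kind == "LOAEL"
        else {"concern": MOE_THRESHOLDS["bmdl_concern"],
              "exceeds_reference": MOE_THRESHOLDS["exceeds_reference"]}
    )
    return MetricDraws(
        element=draws.element,
        scenario=draws.scenario,
        metric="moe",
        reference=reference,
        values=ref_value / draws.values,
        thresholds=thresholds,
    )


def exceedance_fraction(metric: MetricDraws | np.ndarray, cut: float, direction: str = "below") -> float:
    """Fraction of iterations strictly below (or above) a cutpoint."""
    values = metric.values if isinstance(metric, MetricDraws) else np.asarray(metric, dtype=float)
    if values.size == 0:
        raise ValueError("empty draw vector")
    if direction == "below":
        return float(np.mean(values < cut))
    if direction == "above":
        return float(np.mean(values > cut))
    raise ValueError("direction must be 'below' or 'above'")
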