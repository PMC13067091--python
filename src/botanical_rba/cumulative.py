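"""Cumulative non-carcinogenic risk: target hazard quotients and hazard index.

For each element with a US EPA chronic oral reference dose (Al, iAs — total
As used as its proxy — Fe, Ni and Zn) the target hazard quotient is

    THQ_i = (EDI_i / RfD) x ExposureFactor_i

where the exposure factor Ef x Ed / At reduces to Ef/365 because the
averaging time At equals Ed x 365 (the exposure duration cancels). Ef, the
days per year on which botanicals are consumed, is truncated normal
(mean 182.5, SD 70, range 1-365 days). Under dose addition the hazard
index is the iteration-wise sum of the THQs; HI > 1 flags potential
non-carcinogenic risk.

Within one iteration a single consumption draw and a single exposure-factor
draw are shared across all elements (one consumer's habits apply to every
co-ingested element); concentrations stay independent per element.
Botanicals-only intakes use the body-weight-normalized chronic consumption
for all five elements, so no body-weight assumption enters that scenario;
the configurable body weight (default 70 kg) is needed only to convert the
Fe/Zn baseline mg/day intakes in the combined scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import distributions as dist
from ._seeding import substream
from .exposure import ExposureDraws, consumption_distribution
from .metrics import MetricDraws
from .reference_data import HealthReference, Registry, UnitError
from .synthetic_data import concentration_spec

__all__ = [
    "HI_ELEMENTS",
    "ExposureFactorModel",
    "HazardDecomposition",
    "sample_exposure_factor",
    "thq",
    "hazard_index",
    "cumulative_assessment",
]

#: elements entering the hazard index (those with a US EPA RfD; Pb has none)
HI_ELEMENTS = ("Al", "As", "Fe", "Ni", "Zn")


@dataclass(frozen=True)
class ExposureFactorModel:
    """Stochastic Ef/Ed model with At = Ed x 365 (Ed cancels)."""

    ef_days_per_year: dist.DistributionSpec
    ed_years: dist.DistributionSpec

    @classmethod
    def from_registry(cls, registry: Registry) -> "ExposureFactorModel":
        ef = registry.exposure_factor["ef_days_per_year"]
        ed = registry.exposure_factor["ed_years"]
        return cls(
            ef_days_per_year=dist.truncated_normal(ef["mean"], ef["sd"], ef["lower"], ef["upper"]),
            ed_years=dist.truncated_normal(ed["mean"], ed["sd"], ed["lower"], ed["upper"]),
        )


def sample_exposure_factor(
    model: ExposureFactorModel, n_iter: int, seed: int = 0
) -> np.ndarray:
    """Per-iteration factor Ef x Ed / (Ed x 365) = Ef/365, all in (0, 1].

    Ed is sampled (and algebraically cancelled) so the stream layout is
    invariant to the Ed settings — asserting that invariance is a test of
    the averaging-time rule.
    """
    ef = dist.sample(model.ef_days_per_year, n_iter, rng=substream(seed, "exposure_factor", "ef"))
    # Ed is sampled for stream-layout transparency but cancels exactly:
    # Ef x Ed / (Ed x 365) = Ef / 365, applied algebraically to keep the
    # result bit-identical across Ed settings.
    dist.sample(model.ed_years, n_iter, rng=substream(seed, "exposure_factor", "ed"))
    return ef / 365.0


def thq(
    draws: ExposureDraws,
    rfd: HealthReference,
    factor: np.ndarray,
    body_weight_kg: float | None = None,
) -> MetricDraws:
    """Target hazard quotient: (EDI / RfD) x exposure factor, per iteration.

    The RfD is in mg/kg bw/day; draws in ug/kg bw/day are rescaled by 1/1000,
    draws in mg/kg bw/day pass through, and total-diet draws in mg/day
    require ``body_weight_kg`` for the per-bodyweight conversion.
    """
    if rfd.kind != "RfD":
        raise ValueError(f"THQ needs an RfD reference, got {rfd.kind}")
    if draws.basis != "daily":
        raise UnitError("THQ is defined on daily draws")
    factor = np.asarray(factor, dtype=float)
    if factor.shape != draws.values.shape:
        raise ValueError("exposure-factor stream length must match n_iter")
    if np.any(factor <= 0) or np.any(factor > 1):
        raise ValueError("exposure factors must lie in (0, 1]")
    if draws.units == "ug kg_bw-1 day-1":
        edi_mg_kgbw = draws.values / 1000.0
    elif draws.units == "mg kg_bw-1 day-1":
        edi_mg_kgbw = draws.values
    elif draws.units == "mg day-1":
        if body_weight_kg is None or body_weight_kg <= 0:
            raise UnitError("mg/day draws need a positive body weight for THQ")
        edi_mg_kgbw = draws.values / body_weight_kg
    else:
        raise UnitError(f"cannot form THQ from draws in {draws.units!r}")
    return MetricDraws(
        element=draws.element,
        scenario=draws.scenario,
        metric="thq",
        reference=rfd,
        values=(edi_mg_kgbw / rfd.value) * factor,
        thresholds={"concern": 1.0},
    )


@dataclass(frozen=True)
class HazardDecomposition:
    """Per-element THQs, iteration-wise HI, and mean-HI shares."""

    thqs: Mapping[str, MetricDraws]
    hi: np.ndarray
    shares: Mapping[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.shares.values()) - 1.0) > 1e-9:
            raise ValueError("mean-HI shares must sum to 1")


def hazard_index(thqs: Sequence[MetricDraws]) -> HazardDecomposition:
    """Dose-addition hazard index: HI_i = sum of element THQ_i per iteration."""
    if not thqs:
        raise ValueError("need at least one THQ stream")
    n = {t.values.size for t in thqs}
    if len(n) != 1:
        raise ValueError("THQ streams must share n_iter")
    hi = np.sum([t.values for t in thqs], axis=0)
    mean_hi = float(hi.mean())
    shares = {t.element: float(t.values.mean()) / mean_hi for t in thqs}
    return HazardDecomposition(thqs={t.element: t for t in thqs}, hi=hi, shares=shares)


# ---------------------------------------------------------------------------
# high-level assessment


def _botanicals_edi_mg_kgbw(
    registry: Registry, element: str, cons: np.ndarray, seed: int
) -> np.ndarray:
    """Botanicals-only chronic dose in mg/kg bw/day with a shared consumption stream."""
    family, moments = registry.concentrations[element]
    spec_units = moments.units
    conc = dist.sample(
        concentration_spec(family, moments),
        cons.size,
        rng=substream(seed, "cumulative", element, "conc"),
    )
    # to mg/kg extract, then x g/kg bw/day / 1000 -> mg/kg bw/day
    scale = 1.0 if spec_units == "mg kg-1" else 1e-3
    return conc * scale * cons / 1000.0


def cumulative_assessment(
    registry: Registry,
    scenario: str = "botanicals",
    n_iter: int = 100_000,
    seed: int = 0,
    body_weight_kg: float | None = None,
) -> HazardDecomposition:
    """Full THQ/HI assessment for the botanicals-only or combined scenario."""
    if scenario not in ("botanicals", "combined"):
        raise ValueError("scenario must be 'botanicals' or 'combined'")
    bw = body_weight_kg if body_weight_kg is not None else registry.body_weight_kg
    model = ExposureFactorModel.from_registry(registry)
    factor = sample_exposure_factor(model, n_iter, seed=seed)
    pattern = registry.consumption["chronic_g_per_kgbw_day"]
    cons = dist.sample(
        consumption_distribution(pattern), n_iter, rng=substream(seed, "cumulative", "cons")
    )
    thq_list = []
    for sym in HI_ELEMENTS:
        edi = _botanicals_edi_mg_kgbw(registry, sym, cons, seed)
        if scenario == "combined":
            base = registry.baseline_intakes[sym]
            base_spec = dist.lognormal_from_moments(base.mean, base.sd)
            base_draws = dist.sample(
                base_spec, n_iter, rng=substream(seed, "cumulative", sym, "baseline")
            )
            if base.units == "ug kg_bw-1 day-1":
                edi = edi + base_draws / 1000.0
            elif base.units == "mg day-1":
                edi = edi + base_draws / bw
            else:  # pragma: no cover - registry validation precludes this
                raise UnitError(f"unexpected baseline units {base.units!r}")
        draws = ExposureDraws(
            element=sym,
            scenario=scenario,
            basis="daily",
            units="mg kg_bw-1 day-1",
            values=edi,
            seed=seed,
            n_iter=n_iter,
        )
        thq_list.append(thq(draws, registry.rfd(sym), factor))
    return hazard_index(thq_list)
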