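"""End-to-end study orchestration and result rendering.

``run_full_study`` reproduces every result surface of the assessment from
one root seed: per-element exposure summaries under the three chronic
scenarios plus the acute Ni scenario, benefit (%DRV) and risk (%TDI/%TWI,
MOE) metric summaries, threshold-exceedance fractions, the cumulative
THQ/HI decomposition for both scenarios, and the sensitivity analysis of
botanicals-only estimates. Each surface is a list of plain dict rows, so
the bundle serializes directly to CSV/JSON; full run provenance (seed,
n_iter, package version, config digest) is embedded.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import cumulative as cum
from . import exposure as exp
from . import metrics as met
from .reference_data import ESSENTIALS, Registry, load_registry
from .sensitivity import spearman_sensitivity
from .synthetic_data import concentration_spec

__all__ = ["summarize", "summary_row", "run_full_study", "write_bundle"]

#: primary benefit reference per essential element
BENEFIT_KIND = {"K": "AI", "P": "AI", "Ca": "PRI", "Mg": "AI", "Fe": "PRI", "Zn": "PRI"}


def summarize(values: np.ndarray) -> dict[str, float]:
    """Mean, SD, median, P5 and P95 (linear-interpolation percentiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty draw vector")
    p5, median, p95 = np.percentile(v, [5, 50, 95])
    return {
        "mean": float(v.mean()),
        "sd": float(v.std()),
        "median": float(median),
        "p5": float(p5),
        "p95": float(p95),
    }


def summary_row(element: str, scenario: str, metric: str, units: str, values: np.ndarray,
                **extra) -> dict:
    row = {"element": element, "scenario": scenario, "metric": metric, "units": units}
    row.update(summarize(values))
    row.update(extra)
    return row


def _config_digest(registry: Registry) -> str:
    blob = json.dumps(registry.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _conc_spec(registry: Registry, sym: str):
    family, moments = registry.concentrations[sym]
    return concentration_spec(family, moments)


def run_full_study(
    registry: Registry | None = None,
    seed: int = 42,
    n_iter: int = 100_000,
    out_dir: str | Path | None = None,
    body_weight_kg: float | None = None,
) -> dict:
    """Run the complete probabilistic assessment; optionally write CSV/JSON."""
    registry = registry if registry is not None else load_registry()
    chronic_total = registry.consumption["chronic_total_g_per_day"]
    chronic_bw = registry.consumption["chronic_g_per_kgbw_day"]
    acute_bw = registry.consumption["acute_g_per_kgbw"]

    exposure_rows: list[dict] = []
    metric_rows: list[dict] = []
    exceedance_rows: list[dict] = []
    sensitivity_rows: list[dict] = []

    def record_metric(m: met.MetricDraws) -> None:
        metric_rows.append(
            summary_row(m.element, m.scenario, m.metric, "%" if m.metric != "moe" else "",
                        m.values, endpoint=m.reference.endpoint, reference_kind=m.reference.kind)
        )

    def record_exceedance(m: met.MetricDraws, cut: float, label: str) -> None:
        exceedance_rows.append(
            {
                "element": m.element,
                "scenario": m.scenario,
                "metric": m.metric,
                "endpoint": m.reference.endpoint,
                "cut": cut,
                "direction": "below",
                "fraction": met.exceedance_fraction(m, cut, "below"),
                "label": label,
            }
        )

    for sym in registry.elements:
        element = registry.elements[sym]
        botanicals = exp.simulate_botanicals_edi(
            element,
            _conc_spec(registry, sym),
            chronic_total if element.is_essential else chronic_bw,
            n_iter=n_iter,
            seed=seed,
        )
        baseline = exp.simulate_baseline(element, registry, n_iter=n_iter, seed=seed)
        combined = exp.combine(baseline, botanicals)
        for draws in (baseline, botanicals, combined):
            reported = draws
            if sym == "Al":
                reported = exp.weekly_from_daily(draws)
            exposure_rows.append(
                summary_row(sym, reported.scenario, "intake", reported.units, reported.values)
            )
        exposure_rows[-1]["botanical_contribution_pct_mean"] = float(
            100.0 * combined.components["botanical_share"].mean()
        )
        exposure_rows[-1]["botanical_contribution_pct_sd"] = float(
            100.0 * combined.components["botanical_share"].std()
        )

        if element.is_essential:
            ref = registry.reference(sym, BENEFIT_KIND[sym])
            for draws in (baseline, botanicals):
                record_metric(met.percent_reference(draws, ref))
            record_metric(met.percent_drv_total(baseline, botanicals, ref))
        elif sym == "Al":
            ref = registry.reference("Al", "TWI")
            for draws in (baseline, botanicals, combined):
                record_metric(met.percent_reference(exp.weekly_from_daily(draws), ref))
        elif sym == "Ni":
            ref = registry.reference("Ni", "TDI")
            for draws in (baseline, botanicals, combined):
                record_metric(met.percent_reference(draws, ref))
        else:  # As, Pb: margin of exposure per endpoint
            endpoints = [r for r in registry.references if r.element == sym and r.kind == "BMDL"]
            for ref in endpoints:
                for draws in (baseline, botanicals, combined):
                    moe = met.margin_of_exposure(draws, ref)
                    record_metric(moe)
                    record_exceedance(moe, met.MOE_THRESHOLDS["bmdl_concern"], "MOE < 10")

    # acute Ni: single-event exposure against the sensitization LOAEL
    ni = registry.elements["Ni"]
    acute = exp.simulate_acute(ni, _conc_spec(registry, "Ni"), acute_bw, n_iter=n_iter, seed=seed)
    exposure_rows.append(summary_row("Ni", acute.scenario, "intake", acute.units, acute.values))
    loael = registry.reference("Ni", "LOAEL")
    acute_moe = met.margin_of_exposure(acute, loael)
    record_metric(acute_moe)
    record_exceedance(acute_moe, met.MOE_THRESHOLDS["ni_sensitization"], "MOE < 30")

    # sensitivity of the botanicals-only headline metrics to their inputs
    as_bot = exp.simulate_botanicals_edi(
        registry.elements["As"], _conc_spec(registry, "As"), chronic_bw, n_iter=n_iter, seed=seed
    )
    as_moe = met.margin_of_exposure(as_bot, registry.reference("As", "BMDL"))
    for target, streams in (
        (as_moe, as_bot.components),
        (acute_moe, acute.components),
    ):
        report = spearman_sensitivity(streams, target)
        for name, rho in report.rho.items():
            sensitivity_rows.append(
                {"output": report.output, "input": name, "rho": rho, "n_iter": report.n_iter}
            )

    # cumulative THQ/HI for both scenarios
    cumulative_section: dict[str, dict] = {}
    for scenario in ("botanicals", "combined"):
        decomp = cum.cumulative_assessment(
            registry, scenario=scenario, n_iter=n_iter, seed=seed, body_weight_kg=body_weight_kg
        )
        cumulative_section[scenario] = {
            "thq": [
                summary_row(sym, scenario, "thq", "", t.values, share_of_mean_hi_pct=100 * decomp.shares[sym])
                for sym, t in decomp.thqs.items()
            ],
            "hi": summary_row("all", scenario, "hi", "", decomp.hi),
        }

    bundle = {
        "metadata": {
            "seed": int(seed),
            "n_iter": int(n_iter),
            "package_version": __version__,
            "config_digest": _config_digest(registry),
            "body_weight_kg": float(
                body_weight_kg if body_weight_kg is not None else registry.body_weight_kg
            ),
        },
        "exposure": exposure_rows,
        "metrics": metric_rows,
        "exceedance": exceedance_rows,
        "cumulative": cumulative_section,
        "sensitivity": sensitivity_rows,
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: Mapping, out_dir: str | Path) -> None:
    """Write the bundle as one JSON file plus per-section CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    for section in ("exposure", "metrics", "exceedance", "sensitivity"):
        pd.DataFrame(bundle[section]).to_csv(out / f"{section}.csv", index=False)
    thq_rows = []
    for scenario, block in bundle["cumulative"].items():
        thq_rows.extend(block["thq"])
        thq_rows.append(block["hi"])
    pd.DataFrame(thq_rows).to_csv(out / "cumulative.csv", index=False)
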