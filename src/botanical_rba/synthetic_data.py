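"""Synthetic concentration tables emulating the analysed botanical extracts.

The raw per-extract measurements behind the study are unpublished; only
per-element summary statistics and best-fitting families are available.
This module generates a 25-sample x 10-element concentration matrix (or an
arbitrary-n variant) by drawing each element column independently from its
assigned family, moment-matched to the printed mean +/- SD. Columns use
each element's canonical concentration units (mg/kg or ug/kg dry extract)
and all cells are strictly positive.

The default row labels are the commercial product names of the 25 analysed
extracts — cosmetic metadata only; no per-product parameterization is
attempted. Inter-element correlation is not modelled (none is reported),
which is a documented limitation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import distributions as dist
from ._seeding import substream
from .reference_data import ELEMENTS, Registry, SummaryMoments

__all__ = ["concentration_spec", "generate_concentrations", "write_concentrations", "read_concentrations"]


def concentration_spec(family: str, moments: SummaryMoments) -> dist.DistributionSpec:
    """Sampling distribution for one element's concentration column."""
    if family == "lognormal":
        if moments.sd is None:
            raise ValueError("lognormal concentration targets need an SD")
        return dist.lognormal_from_moments(moments.mean, moments.sd)
    if family == "exponential":
        return dist.exponential_from_mean(moments.mean)
    raise ValueError(f"unsupported concentration family {family!r}")


def generate_concentrations(
    registry: Registry,
    n_samples: int = 25,
    seed: int = 0,
    elements: tuple[str, ...] = ELEMENTS,
) -> pd.DataFrame:
    """Draw a synthetic n_samples x 10 concentration table.

    Each column is an independent seeded draw from the element's assigned
    family (lognormal via moment matching, exponential via rate = 1/mean).
    Reproducible: the same (registry, n_samples, seed) gives the same table.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    unknown = set(elements) - set(registry.concentrations)
    if unknown:
        raise ValueError(f"unknown element(s): {sorted(unknown)}")
    cols = {}
    for sym in elements:
        family, moments = registry.concentrations[sym]
        spec = concentration_spec(family, moments)
        rng = substream(seed, "concentrations", sym)
        cols[sym] = dist.sample(spec, n_samples, rng=rng)
    if n_samples == len(registry.products):
        index = pd.Index(registry.products, name="product")
    else:
        index = pd.Index([f"sample_{i + 1}" for i in range(n_samples)], name="product")
    return pd.DataFrame(cols, index=index)


def _units_banner(registry: Registry, columns) -> list[str]:
    units = ", ".join(f"{sym}: {registry.concentrations[sym][1].units}" for sym in columns)
    return [
        "# synthetic concentration table (one realization; not measured data)",
        f"# units: {units}",
    ]


def write_concentrations(path: str | Path, table: pd.DataFrame, registry: Registry) -> None:
    """Write the table as CSV with a units metadata banner; round-trips losslessly."""
    path = Path(path)
    with path.open("w") as fh:
        for line in _units_banner(registry, table.columns):
            fh.write(line + "\n")
        table.to_csv(fh, float_format="%.17g")


def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Read a concentration CSV, rejecting missing or non-positive cells."""
    table = pd.read_csv(path, comment="#", index_col="product")
    if table.isna().any().any():
        bad = [(r, c) for r, c in zip(*np.asarray(table.isna()).nonzero())]
        r, c = bad[0]
        raise ValueError(f"missing cell at row {table.index[r]!r}, column {table.columns[c]!r}")
    nonpos = np.asarray(table <= 0)
    if nonpos.any():
        r, c = [(int(r), int(c)) for r, c in zip(*nonpos.nonzero())][0]
        raise ValueError(
            f"non-positive concentration at row {table.index[r]!r}, column {table.columns[c]!r}"
        )
    return table
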