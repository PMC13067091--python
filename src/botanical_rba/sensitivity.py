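"""Spearman rank-correlation sensitivity analysis.

Attributes variability in a simulated output (an intake or a derived
metric) to the modelled input streams (consumption rate, element
concentration) by the Spearman rank correlation between paired
iterations. Rho is computed as the Pearson correlation of midranks
(average ranks under ties), which is exact in the presence of ties.
Restricted by design to botanicals-only estimates, where the input
streams are retained alongside the draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .exposure import ExposureDraws
from .metrics import MetricDraws

__all__ = ["SensitivityReport", "spearman_sensitivity"]


@dataclass(frozen=True)
class SensitivityReport:
    """Per-input Spearman rho for one output, on paired iterations."""

    output: str
    rho: Mapping[str, float]  # NaN marks an undefined (zero-variance) input
    n_iter: int

    def __post_init__(self) -> None:
        for name, r in self.rho.items():
            if np.isfinite(r) and abs(r) > 1.0 + 1e-12:
                raise ValueError(f"|rho| > 1 for input {name!r}")


def spearman_sensitivity(
    inputs: Mapping[str, np.ndarray],
    output: MetricDraws | ExposureDraws | np.ndarray,
    output_label: str | None = None,
) -> SensitivityReport:
    """Spearman rho of each named input stream against the output draws.

    All vectors must be index-aligned (the output computed from these
    exact input iterations). A zero-variance input has no rank ordering;
    its rho is reported as NaN.
    """
    if isinstance(output, (MetricDraws, ExposureDraws)):
        label = output_label or f"{output.element}:{getattr(output, 'metric', 'intake')}"
        y = output.values
    else:
        label = output_label or "output"
        y = np.asarray(output, dtype=float)
    rho = {}
    for name, x in inputs.items():
        x = np.asarray(x, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"input {name!r} is not aligned with the output")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho[name] = float("nan")
            continue
        rho[name] = float(stats.spearmanr(x, y).statistic)
    return SensitivityReport(output=label, rho=rho, n_iter=int(y.size))
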