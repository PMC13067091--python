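"""Parametric distribution toolkit for probabilistic exposure modelling.

Supports the candidate families used to describe element concentrations
(normal, lognormal, exponential, Weibull, Pareto) plus the truncated
normal used by the exposure-factor model. Provides:

* moment matching of a lognormal to a printed mean +/- SD, the standard
  way to turn summary statistics into a sampling distribution;
* maximum-likelihood fitting with AIC/dAIC model selection;
* seeded inverse-CDF sampling (reproducible, vectorized, exact for the
  truncated normal);
* closed-form CDF/PPF and analytic moments, used as oracles for the
  Monte Carlo machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._seeding import substream

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "FitResult",
    "FitError",
    "lognormal",
    "exponential_from_mean",
    "lognormal_from_moments",
    "truncated_normal",
    "fit_mle",
    "fit_candidates",
    "select_by_aic",
    "sample",
    "cdf",
    "ppf",
    "analytic_mean",
    "analytic_sd",
    "analytic_median",
]

FAMILIES = ("normal", "lognormal", "exponential", "weibull", "pareto", "truncated_normal")

#: families requiring strictly positive data for fitting
_POSITIVE_FAMILIES = {"lognormal", "exponential", "weibull", "pareto"}

#: number of estimated parameters entering the AIC penalty
_N_PARAMS = {"normal": 2, "lognormal": 2, "exponential": 1, "weibull": 2, "pareto": 2}


class FitError(ValueError):
    """Raised when a candidate family cannot be fitted to the data."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric family with its parameters.

    Parameter keys by family: lognormal ``mu``/``sigma`` (log scale);
    normal ``mean``/``sd``; exponential ``rate``; weibull ``shape``/
    ``scale``; pareto ``xm``/``alpha``; truncated_normal ``mean``/``sd``/
    ``lower``/``upper``.
    """

    family: str
    params: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}")
        p = self.as_dict()
        positives = {
            "normal": ["sd"],
            "lognormal": ["sigma"],
            "exponential": ["rate"],
            "weibull": ["shape", "scale"],
            "pareto": ["xm", "alpha"],
            "truncated_normal": ["sd"],
        }[self.family]
        for key in positives:
            if p[key] <= 0:
                raise ValueError(f"{self.family}: parameter {key} must be > 0, got {p[key]}")
        if self.family == "truncated_normal" and not p["lower"] < p["upper"]:
            raise ValueError("truncated_normal: lower must be < upper")

    def as_dict(self) -> dict[str, float]:
        return dict(self.params)

    def frozen(self):
        """The scipy frozen distribution backing this spec."""
        p = self.as_dict()
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        if self.family == "pareto":
            return stats.pareto(b=p["alpha"], scale=p["xm"])
        a = (p["lower"] - p["mean"]) / p["sd"]
        b = (p["upper"] - p["mean"]) / p["sd"]
        return stats.truncnorm(a, b, loc=p["mean"], scale=p["sd"])


def _spec(family: str, **params: float) -> DistributionSpec:
    return DistributionSpec(family, tuple(sorted((k, float(v)) for k, v in params.items())))


def lognormal(mu: float, sigma: float) -> DistributionSpec:
    return _spec("lognormal", mu=mu, sigma=sigma)


def exponential_from_mean(mean: float) -> DistributionSpec:
    if mean <= 0:
        raise ValueError("exponential mean must be > 0")
    return _spec("exponential", rate=1.0 / mean)


def truncated_normal(mean: float, sd: float, lower: float, upper: float) -> DistributionSpec:
    return _spec("truncated_normal", mean=mean, sd=sd, lower=lower, upper=upper)


def lognormal_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Moment-match a lognormal to an arithmetic mean and SD.

    Uses sigma^2 = ln(1 + (sd/mean)^2) and mu = ln(mean) - sigma^2/2, so the
    analytic mean and SD of the returned spec equal the inputs exactly. As
    sd -> 0+ the spec degenerates towards a point mass at ``mean``.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError(f"lognormal moments require mean > 0 and sd > 0, got {mean}, {sd}")
    sigma2 = np.log1p((sd / mean) ** 2)
    return lognormal(mu=float(np.log(mean) - sigma2 / 2.0), sigma=float(np.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# sampling and closed forms


def sample(
    spec: DistributionSpec,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` reproducible samples via inverse-CDF transform.

    Exactly one of ``seed``/``rng`` must be given; inverse-CDF sampling is
    exact for every supported family (including the truncated normal,
    which needs no rejection step).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if (seed is None) == (rng is None):
        raise ValueError("provide exactly one of seed or rng")
    if rng is None:
        rng = substream(seed, "sample", spec.family)
    u = rng.random(int(n))
    return np.asarray(spec.frozen().ppf(u), dtype=float)


def cdf(spec: DistributionSpec, x) -> np.ndarray | float:
    return spec.frozen().cdf(x)


def ppf(spec: DistributionSpec, q) -> np.ndarray | float:
    return spec.frozen().ppf(q)


def analytic_mean(spec: DistributionSpec) -> float:
    return float(spec.frozen().mean())


def analytic_sd(spec: DistributionSpec) -> float:
    return float(spec.frozen().std())


def analytic_median(spec: DistributionSpec) -> float:
    return float(spec.frozen().ppf(0.5))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting and AIC selection


@dataclass(frozen=True)
class FitResult:
    spec: DistributionSpec
    loglik: float
    aic: float
    n: int
    n_params: int
    delta_aic: float = float("nan")
    evidence: str = ""

    def as_row(self) -> dict:
        row = {"family": self.spec.family, "n": self.n, "k": self.n_params,
               "loglik": self.loglik, "aic": self.aic, "delta_aic": self.delta_aic,
               "evidence": self.evidence}
        row.update(self.spec.as_dict())
        return row


def fit_mle(data: Sequence[float], family: str) -> FitResult:
    """Fit one candidate family by maximum likelihood.

    Closed forms are used where they exist (exponential rate = 1/mean,
    lognormal from log-moments, normal from moments, Pareto shape with
    xm = min(data)); the Weibull fit is iterative via scipy with the
    location pinned at zero.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise FitError("need a 1-D sample with n >= 3")
    if not np.all(np.isfinite(x)):
        raise FitError("non-finite datum in sample")
    if family in _POSITIVE_FAMILIES and np.any(x <= 0):
        raise FitError(f"{family}: data must be strictly positive")
    n = x.size

    if family == "normal":
        spec = _spec("normal", mean=x.mean(), sd=x.std(ddof=0))
    elif family == "lognormal":
        logs = np.log(x)
        sd = logs.std(ddof=0)
        if sd == 0:
            raise FitError("lognormal: degenerate sample (zero log-variance)")
        spec = lognormal(mu=float(logs.mean()), sigma=float(sd))
    elif family == "exponential":
        spec = exponential_from_mean(float(x.mean()))
    elif family == "weibull":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, loc, scale = stats.weibull_min.fit(x, floc=0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
            raise FitError("weibull: optimizer failed to converge")
        spec = _spec("weibull", shape=shape, scale=scale)
    elif family == "pareto":
        xm = float(x.min())
        denom = float(np.sum(np.log(x / xm)))
        if denom <= 0:
            raise FitError("pareto: degenerate sample (all values equal)")
        spec = _spec("pareto", xm=xm, alpha=n / denom)
    else:
        raise FitError(f"cannot fit family {family!r}")

    loglik = float(np.sum(spec.frozen().logpdf(x)))
    if not np.isfinite(loglik):
        raise FitError(f"{family}: non-finite log-likelihood")
    k = _N_PARAMS[family]
    return FitResult(spec=spec, loglik=loglik, aic=2.0 * k - 2.0 * loglik, n=n, n_params=k)


def fit_candidates(
    data: Sequence[float],
    families: Iterable[str] = ("normal", "lognormal", "exponential", "weibull", "pareto"),
) -> list[FitResult]:
    """Fit every candidate family, excluding failures with a warning."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_mle(data, fam))
        except FitError as exc:
            warnings.warn(f"candidate {fam} excluded: {exc}", stacklevel=2)
    return fits


def _evidence_band(delta: float) -> str:
    # Burnham-Anderson bands: <3 minimal, 3-10 moderate, >10 strong
    if delta < 3:
        return "minimal"
    if delta <= 10:
        return "moderate"
    return "strong"


def select_by_aic(fits: Sequence[FitResult]) -> tuple[FitResult, list[FitResult]]:
    """Rank candidate fits by AIC and return (winner, ranked table).

    Ties within floating-point AIC equality break towards the family with
    fewer parameters, then lexicographic family order, so selection is
    deterministic. Each ranked entry is annotated with its dAIC relative
    to the winner and the evidence band for that dAIC.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise FitError("need >= 2 successful fits to select")
    if len({f.n for f in fits}) != 1:
        raise FitError("candidates were fitted on different sample sizes")
    ranked = sorted(fits, key=lambda f: (f.aic, f.n_params, f.spec.family))
    best_aic = ranked[0].aic
    ranked = [
        replace(f, delta_aic=f.aic - best_aic, evidence=_evidence_band(f.aic - best_aic))
        for f in ranked
    ]
    return ranked[0], ranked
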