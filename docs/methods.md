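# Methods

## Scope and design

The package implements a single-loop (one-dimensional) Monte Carlo
assessment: variability and uncertainty are propagated together, with
100 000 iterations by default. Each derived quantity is a deterministic
transform of per-iteration input draws, so every reported statistic
(mean, SD, median, P5, P95, exceedance fraction, Spearman ρ) is an
empirical functional of one simulated population. All randomness derives
from a single root seed through labelled sub-streams
(`SeedSequence(seed, spawn_key=crc32(labels))`), so any stage can be
re-simulated in isolation and full runs are bit-reproducible.

## Inputs

All inputs are summary statistics of published provenance, vendored in
`src/botanical_rba/data/registry.yml` and validated on load (exactly ten
elements, complete reference triples, three consumption patterns,
resolvable units). There is no network retrieval.

Two families of printed units required interpretation. The baseline
intakes of the toxic elements and several guidance values are printed
with an "mg" prefix that is inconsistent with the assessment's own
arithmetic (e.g. a baseline Al intake of 58.2/day against a tolerable
weekly intake of 1 mg/kg bw/week is stated to consume 41% of that TWI,
which requires µg/kg bw/day; the Ni acute reference point is elsewhere
stated as 4.3 µg/kg bw). The registry therefore stores these values in
canonical micrograms, and the unit layer (`canonicalize_units`) converts
only by powers of 10³ and the daily↔weekly factor 7, refusing any
dimension change (mass vs mass-per-bodyweight vs per-event). The
`%‑of‑guidance` consistency of the stored values with the published
percentages (41% Al TWI, 12% Ni TDI, 231% P AI) is asserted in the test
suite, which pins the unit interpretation.

Other registry choices: the Mg upper level (250 mg/day) applies to
supplemental Mg only and carries a `supplemental` flag so it is never
used as a total-diet cap; the Zn PRI is the single phytate-averaged value
11.5 mg/day.

## Distributions

Concentration and consumption distributions are constructed by **moment
matching**: a lognormal with σ² = ln(1 + (SD/mean)²), µ = ln(mean) − σ²/2
reproduces the printed arithmetic mean and SD exactly; exponential
columns use rate = 1/mean. This is the central modelling commitment of
the package: the original analysis fitted distributions to raw
measurements that are not public, so moment matching from the published
summaries is the only faithful reconstruction available. For most
elements the two parameterizations are close; for arsenic
(3026 ± 18 000 µg/kg, CV ≈ 6) the lognormal tail is extremely sensitive
to the parameterization, and arsenic-driven quantities (mean THQ, HI
median/P95) are therefore reproduced only to within tens of percent
rather than a few percent. This is a property of the available inputs,
not of the simulation.

The fitting toolkit covers five candidate families (normal, lognormal,
exponential, Weibull, Pareto) by maximum likelihood — closed forms where
they exist, scipy optimization for the Weibull (location pinned at 0),
classic Pareto with scale fixed at the sample minimum and the closed-form
shape MLE. Model selection is by AIC with ΔAIC evidence bands (<3
minimal, 3–10 moderate, >10 strong). Ties break to fewer parameters,
then lexicographic family order, so selection is deterministic. Note
that the Weibull nests the exponential at shape 1: on true exponential
data the Weibull wins the AIC comparison in roughly the fraction of
samples where its likelihood gain exceeds the one-parameter penalty
(~16%), which is correct behaviour of AIC on nested models, not a
recovery failure; the recovery guarantee (≥90%) applies to clearly
separated families.

Sampling is inverse-CDF throughout (`ppf` of a uniform stream), which is
exact for every family including the truncated normal (no rejection
step) and makes draws a pure function of (spec, seed).

## Exposure scenarios

Essential elements use the total-diet consumption rate (g/day), giving
intakes in mg/day; toxic elements use the body-weight-normalized rate
(g/kg bw/day), giving µg/kg bw/day — the pairing implied by the units of
the intake equations. Concentration and consumption are sampled
independently with one fresh draw of each per iteration, pooled across
extracts (one marginal concentration distribution per element; no
inter-element or concentration–consumption correlation is modelled, as
none is reported — a limitation noted below). The combined scenario adds
baseline and botanical draws iteration-wise and retains the per-iteration
botanical share. Al is converted to a weekly basis (×7, reported in
mg/kg bw/week) for comparison with its TWI; the basis check refuses a
daily-vs-weekly mismatch rather than silently mis-scaling by 7. The
acute scenario is defined only where a per-event reference exists (Ni
systemic contact dermatitis).

## Cumulative risk

THQ = (EDI/RfD) × Ef/365, where the exposure factor Ef×Ed/At with
At = Ed×365 reduces algebraically to Ef/365; Ed is still sampled so the
stream layout is transparent, and the cancellation is applied exactly, so
results are bit-identical under any Ed settings (asserted in tests). The
hazard index is the iteration-wise sum of THQs over Al, iAs (total As
used as its proxy — conservatively, since most As in botanicals is
inorganic), Fe, Ni and Zn; Pb has no US EPA RfD and is handled by MOE
only.

Within an iteration, one consumption draw and one Ef draw are shared
across all five elements: dose addition models one consumer co-ingesting
the mixture, so that consumer's intake rate and frequency apply to every
element simultaneously. Concentrations remain independent per element.
Sharing affects only the joint distribution (HI percentiles), never the
per-element means or the mean-HI shares.

Botanicals-only THQs use the body-weight-normalized consumption for all
five elements, so no body-weight assumption enters that scenario. The
combined scenario needs the Fe/Zn baselines (printed in mg/day) converted
to per-kg doses; a configurable point body weight (default 70 kg, the
standard adult value) is used — a distributional body weight was judged
unsupported by the available inputs.

## Sensitivity

Spearman ρ between each retained input stream and the output, computed
as the Pearson correlation of midranks (scipy's estimator), which is
exact under ties. It is restricted to botanicals-only outputs, whose
input streams are carried on the draw objects; for a ratio of independent
lognormals the closed form ρ = −(6/π)·arcsin(r/2),
r = σ_x/√(σ_x²+σ_y²), serves as the test oracle.

## Numerical conventions

Percentiles use linear interpolation of order statistics
(`numpy.percentile` default). Exceedance fractions use strict
inequality at the cutpoint (a measure-zero event under continuous
models). Summary SDs are population SDs of the draw vector. MOE
interpretation thresholds (10 for BMDL-based endpoints, 30 for Ni
sensitization, 1 for exposure at the reference point) are carried as
data annotations, not hard-coded logic.

## Synthetic data

`synthetic_data.generate_concentrations` draws n×10 concentration tables
from the per-element families at the registry moments. It emulates the
marginal distributions and right skew of the measured extracts (sample
mean above sample median for heavy-tailed columns at n = 25); it does not
emulate inter-element correlation within a product, species-level
differences between extracts, or censoring at the analytical
quantification limit (published P5 values of 0 are rounding artifacts;
generated support is strictly positive). Tests passing on synthetic
tables therefore validate the pipeline's statistical machinery, not any
claim about a particular botanical product.

## Problem sizes

Monte Carlo checks in the test suite and the acceptance script run at the
study's own scale of 100 000 iterations, which keeps every stochastic
statistic's Monte Carlo error an order of magnitude inside its tolerance;
structural and determinism checks use a few thousand iterations since
they are scale-invariant.

## Known limitations

- Moment-matched parameters are not MLE parameters; heavy-tailed
  (arsenic) results carry the widest reproduction bands.
- No inter-element copula, no concentration–consumption dependence, no
  per-product parameterization, no age/sex stratification, no
  bioavailability adjustment.
- One-dimensional Monte Carlo: variability and parameter uncertainty are
  not separated.
- Benefit and risk are reported side by side; no composite risk–benefit
  currency (DALY/QALY) is computed.
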