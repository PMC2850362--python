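# Methods

## Survival from outgrowth kinetics

The model underlying the pipeline is that, during exponential
outgrowth after a fixed-volume inoculation, the background-corrected
OD of a well is proportional to the number of viable cells inoculated.
If two wells differ only in their viable inoculum, their curves are
time-translates of each other: a culture with viable fraction *f*
reaches any fixed OD level `Δt = δ·log2(1/f)` hours later than a fully
viable one, where δ is the doubling time. Inverting this gives the
survival estimator

    s_n = 2 ** (−Δt_n / δ),

with Δt_n the time shift of age-point *n*'s curve relative to the
first age-point's curve of the same well. Assumptions: the compared
curves cross the measurement level while still in exponential phase;
the doubling time of the survivors does not change with age (δ is
estimated once, from the first age-point's curve, and reused — a
deliberate choice, since the reference curve is the best-measured one
and using per-age δ would conflate growth-rate changes with
viability); and the dilution at each age-point is identical.

## Curve primitives

**Background.** Every OD reading in a run is reduced by one scalar
background: the median of a named media-only well's full series
(median rather than mean so a single contaminated reading does not
shift it), a user-supplied value, or the default 0.15 (the approximate
reading of media alone in a honeycomb-plate well). Corrected ODs are
floored at ε = 1e−4 so logarithms stay finite on blank or dead wells;
the floor is far below any analysis threshold.

**Crossing times.** The earliest time the corrected OD reaches a level,
interpolated linearly in (time, log2 OD) between the bracketing
samples — exact for exponential growth between samples, which is the
regime where crossings are measured. A curve already above the level
at its first sample crosses at 0; a curve that never reaches it has no
crossing (dead culture or blank).

**Doubling time.** Two estimators over background-normalized OD
windows (defaults 0.2–0.5, within the reliable range of plate-reader
ODs and below saturation):

* *inflection* — reciprocal of the steepest per-sample-pair log2
  slope whose endpoints both lie in the window;
* *interval* (default) — traversal time between the crossings of the
  window bounds divided by the number of doublings spanned,
  `log2(od_max/od_min)`.

Both are exact for pure exponentials. Under read noise the interval
form is preferred and is the default: it averages over the whole
window, while the inflection form takes a maximum over noisy slopes
and is therefore biased fast (low δ) in proportion to the noise. No
smoothing is applied before estimation. An affine empirical
correction `δ' = a·δ + b` is available for calibrating against an
external growth-rate standard; its default (1, 0) is a no-op.

**Time-shift level.** Time shifts are measured at corrected OD 0.3
(default), inside the exponential window of both curves; the estimate
is insensitive to the exact level as long as both curves cross it
exponentially.

## Cleaning and the survival integral

Raw survival fractions can exceed 1 (negative shifts from measurement
noise) or rise late in life ("gasping", typically regrowth of a few
escapers). Cleaning replaces the series by `cleaned[0] = 1` and
`cleaned[i] = min(1, raw[i], cleaned[i−1])` — a single running-minimum
pass that enforces the defining properties of a survival curve
(starts at 1, never increases) and flattens terminal spikes. It is
idempotent and order-preserving. Raw values are retained alongside
cleaned ones; cleaning caps values only in the cleaned series.

The survival integral is the trapezoidal area under the cleaned curve
over age in days, so unevenly spaced age-points are weighted by the
time actually elapsed between them. Dead cultures (no crossing) score
survival 0 rather than missing, keeping the integral defined.

## Group statistics

Replicate groups are summarized by mean or median with the sample
standard deviation (n−1; 0 for a single replicate). Comparisons
versus a reference group: percent change and log2 ratio of centers
(by default of survival integrals), and a two-sample t-test on the
member values. The Welch form (unequal variances,
Welch–Satterthwaite degrees of freedom, two-sided p) is used because
typical designs have three biological replicates per group with no
reason to assume equal variances; at n = 3 it is mildly conservative
(empirical type-I error ≈ 0.03–0.05 at α = 0.05), which the
acceptance script measures rather than assumes. No multiple-testing
correction is applied across groups; apply your own when screening
many strains.

## The synthetic generator

`outgrowth.simulate` writes complete experiments in the exact file
dialects the reader consumes. Each well's corrected OD follows a
generalized-logistic (Richards) trajectory

    x(t) = K · (1 + ((K/x0)^ν − 1) · 2^(−ν t/δ))^(−1/ν),   x0 = inoculum_od · f,

parameterized in base 2 so δ is the literal exponential-phase
doubling time, plus the media background and additive Gaussian read
noise. The sharpness ν (default 8) makes growth exponential
throughout the 0.2–0.5 analysis window and then saturate abruptly, as
real post-diauxic outgrowth does; ν = 1 is the textbook logistic,
which decelerates measurably already at a fifth of its carrying
capacity and would contaminate threshold-based doubling-time
estimates with saturation bias. Defaults describe a typical yeast
outgrowth read: δ = 1.5 h, carrying capacity 1.4 corrected OD,
inoculum 0.05 OD (a ~1:30 dilution of a dense culture), background
0.15, noise 0.005 OD, readings every 0.5 h for 24 h, and a
chronological-aging viability schedule (days 2, 4, 6, 9, 11, 13 with
fractions 1 → 0.05). One media-only blank well is appended to every
simulated plate so the named-background workflow is exercised.

What the generator does *not* emulate: diauxic two-phase growth, lag
phases that depend on culture age, plate edge effects, evaporation
drift, well-to-well growth-rate variation, and OD nonlinearity at
high density. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under the stated generative model,
not robustness to every artifact of real plates.

## Numerical and design choices

* Interpolation for crossings is linear in log2 OD; time stamps are
  parsed exactly (H + M/60 + S/3600) with hours unbounded.
* Strictly increasing time stamps are required; duplicated stamps are
  an input error rather than silently averaged.
* The 200-well instrument capacity is enforced when parsing.
* Exported reals are written with 6 decimals; re-importing an
  exported table reproduces values to that precision.
* Survival conversion error propagates multiplicatively with the
  number of doublings of delay: a relative doubling-time error
  `u` inflates a recovered fraction `f` by roughly a factor
  `f^(−u)`. With 0.005 OD read noise the interval estimator carries
  ~2% noise on δ, so single-well fractions below ~1% are recovered
  with proportionally larger relative error; replicate and
  across-experiment averaging restores accuracy, which is how the
  recovery checks are framed.
* Analysis is fully deterministic; all randomness lives in the
  generator behind a seed.

## Problem sizes used in the checks

The test suite and acceptance script use plates of 4–7 wells, 6
age-points, 49 readings per curve, 10–50 seeded replicate experiments
for recovery statistics, 100 seeds for doubling-time error, and 1000
null simulations for t-test calibration; together they complete in
well under a minute.

## Known limitations

* Survival below ~0.1% is outside the usable range at default noise:
  the outgrowth delay approaches the read's duration and the
  doubling-time amplification dominates.
* A reference well that fails to grow aborts its lineage with an
  error (there is nothing to normalize to); it is reported with well
  and day context rather than imputed.
* Only the affine form of the doubling-time correction is supported.
* `.xls` (pre-2007 Excel) workbooks are not read; convert to CSV or
  `.xlsx`.
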