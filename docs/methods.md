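# Methods

## The measurement model

A fixed camera photographs a forest canopy on an hourly schedule during
daylight (the default emulates 11 frames/day, 07:05–17:05).  For each frame
and each region of interest (ROI) — a fixed rectangle or polygon of pixels —
the mean brightness of the red, green and blue channels is computed, and all
frames of a calendar day are averaged into one (R, G, B) triple per ROI per
day.  Averaging first and computing indices second (mean-then-index) is
deliberate: the chromatic indices are ratios, and the daily mean damps
illumination changes before the nonlinearity is applied.  Days with no
frames are gaps, never zero-filled; every downstream stage accepts irregular
day grids.  Frames are assumed registered; no exposure or white-balance
correction and no weather screening are applied.

Six indices are computed per day: GCC = G/(R+G+B), RCC = R/(R+G+B),
GEI = 2G − (R+B), GGR = G/R, GRVI = (G−R)/(G+R), and the HSV hue angle in
degrees.  Useful identities (all tested): GCC + RCC + B/(R+G+B) = 1; GRVI is
antisymmetric in (R, G); GEI is linear in the channels; GCC, RCC, GRVI, GGR
and HUE are invariant to a common brightness rescaling, GEI is not.
Degenerate denominators (e.g. an achromatic day for HUE, R = 0 for GGR)
yield NaN for that day and are logged, not raised — a single bad day should
not abort a year of data.  HUE uses the standard HSV case analysis on the
maximal channel with the result wrapped into [0, 360); a
`hue_as_printed=True` switch reproduces an alternative published constant
(+340 on the red-max, G &lt; B branch) for comparison.

## Seasonal model and transition dates

The annual index trajectory is modelled by the double logistic

    g(t) = w_min + (w_max − w_min) · [ σ(mS·(t−S)) + σ(−mA·(t−A)) − 1 ]

with σ the logistic function: `w_min`/`w_max` are the annual minimum and
maximum (index units), S and A the spring and autumn inflection days (DOY),
and mS, mA &gt; 0 the transition slopes (1/day).  The curve sits at `w_min`
in winter on both ends and at `w_max` on the mid-season plateau; at t = S
(with the autumn term saturated) it passes through the half-amplitude point.

Fitting is bounded nonlinear least squares (trust-region reflective, SSE
tolerance 1e-10).  Initialization: `w_min`/`w_max` from the 5th/95th
percentiles, S and A from the first/last half-amplitude crossings,
mS = mA = 0.1/day, plus 5 restarts jittered with a fixed seed; the best SSE
wins.  A series with no amplitude raises a fit error rather than returning a
meaningless curve.  Diagnostics are the residual RMSE and R² against the raw
(unsmoothed) data.  An optional pre-pass smoothing spline with roughness
parameter p ∈ (0, 1] is available (p = 1 interpolates, p → 0 tends to the
least-squares line); internally p maps to a second-derivative penalty weight
λ = (1 − p)/p.

Transition dates come from the curvature of the fitted curve,
K(t) = |g″| / (1 + g′²)^{3/2}, via the rate of change dK/dt, computed
analytically (first to third derivatives of g in closed form; both are
verified against finite differences in the tests).  The rate is
differentiated on the *signed* curvature so its extrema are well defined
where g″ crosses zero; an `on_unsigned` switch differentiates |K| instead.
On a dense grid (default step 0.1 day over [S − 8/mS, A + 8/mA]) the local
extrema of dK/dt bracket each inflection; they are assigned positionally:

* SOS — first extremum before S (green-up onset),
* MOE — last extremum between S and the mid-plateau (maturity onset),
* COS — first extremum between mid-plateau and A (senescence onset),
* EOS — last extremum after A (end of season),
* LOS = MOE − SOS (green-up length).

Dates are rounded to whole days and are stable within ±1 day under tenfold
grid refinement.  Note the extrema of the curvature rate do **not** coincide
with the inflections: for a slope of 0.15/day they sit roughly 20 days to
either side, which is the intended behavior of curvature-based dating —
they mark where the trajectory *begins* and *finishes* bending.

## Forecaster

The forecaster is a stacked long short-term memory network written directly
from the gate equations (forgetting gate f, in-gate i, candidate state C̄,
cell update C_t = f⊙C_{t−1} + i⊙C̄, out-gate O, h_t = O⊙tanh C_t) in numpy,
with analytic backpropagation through time.  The hidden state is mapped to
the scalar next-day prediction by a linear read-out layer — the gate
equations alone do not produce a scalar, so this head is a necessary
addition.  Defaults: window 30 days (30 days in, day 31 out), depth 2
(layer 2 consumes layer 1's hidden sequence), hidden size 16, weights
initialized U(−0.01, 0.01) from a fixed seed.

The series is min-max scaled to [0, 1] (linear, no clipping; constant series
rejected) and split chronologically 70/20/10 into training, test and
verification partitions with no shuffling across boundaries; a date-boundary
split can be expressed through the `start` argument of `forecast`.  Sliding
windows are built only within contiguous day runs — a window spanning a gap
would silently change the meaning of "30 days of input".

Training minimizes squared next-day error with one parameter update per
window per epoch, in chronological order, using adaptive moment estimation
(Adam, β₁ = 0.9, β₂ = 0.999) at learning rate 1e-5 decaying exponentially
(×0.999 per epoch).  Plain gradient descent at this learning rate cannot
train the recurrent weights on normalized data in any reasonable number of
epochs (the updates are orders of magnitude too small relative to the
parameter scale the read-out must reach), so the adaptive step-size
normalization is what makes the stated learning rate usable.  The default of
100 epochs is past the convergence knee on the synthetic series used
throughout (~1 minute on one CPU); the training history is retained on the
fitted object for inspection.  Training is exactly deterministic given seed,
data and configuration.

One-step forecasts predict each test-partition day from true observed
history; recursive forecasts feed predictions back for the requested horizon
(default 60 days) past the end of the series.  Both are reported in original
index units.

Quality metrics are MSE, RMSE = √MSE, MAE (mean *absolute* error; the signed
mean error is exposed separately as `bias`) and MAPE in percent, undefined
(NaN) when any true value is zero.  QQ diagnostics standardize the
residuals and pair their order statistics with standard-normal quantiles at
plotting positions (i − 0.5)/n.

## Synthetic data: what it emulates, and what it does not

The generator replaces an undeposited camera archive.  Index trajectories
are the double logistic plus i.i.d. Gaussian noise on the index scale;
multiple ROIs are produced by shifting S and A by per-ROI day offsets,
emulating micro-environment differences between canopy positions.  Image
archives render flat-filled scene regions (canopy, trunk, sky on a
background) at small frame sizes; the canopy color follows an invertible
ramp (R, G, B) = base_brown + s·(−60, +120, −30), with s solved per day so
the canopy GCC equals the requested trajectory value (attainable GCC roughly
0.33–0.55).  Per-frame illumination jitter is a multiplicative lognormal
factor applied to the whole frame; within-day variance has no published
magnitude, so the jitter default is 0 and it is a free parameter.  All
generators are deterministic under a fixed seed, byte-identical for images.

What passing the round-trip tests shows: the extraction, index, fitting and
dating stages are mutually consistent to 8-bit quantization on data whose
generating process matches the model.  What it does not show: robustness to
fog, snow, camera shake, exposure drift, mixed-species canopies or
non-logistic seasonal shapes — real archives violate the generator's
assumptions in all these ways, and the flat-filled frames carry no texture,
so registration and segmentation issues are out of scope by construction.

## Numerical and design choices

* The printed form of the double-logistic equation in some sources is
  internally inconsistent (sign of the autumn sigmoid, placement of the −1);
  the canonical form above is the one that actually produces a unimodal
  seasonal curve with minimum `w_min` and maximum `w_max`.
* Logistic and gate sigmoids are computed as 0.5·(1 + tanh(x/2)), which is
  overflow-free; the training path fuses the four gate activations into one
  tanh evaluation and is tested to be numerically identical to the
  plain cell equations.
* MAPE carries the ×100; MAE carries the absolute value.  RMSE² = MSE holds
  exactly by construction.
* Day-of-year is anchored to the year of the first observation and keeps
  increasing across a year boundary (day 366, 367, …) so multi-year series
  remain strictly ordered; rectangles are half-open [x0, x1) × [y0, y1) in
  0-based pixel coordinates.
* Fits on gappy grids use the points as given; no imputation anywhere.
* Simulation sizes used by the test suite and the acceptance script — one
  365-day season for fitting, 100 replicates for the recovery study, a
  426-day (14-month) series for the forecaster, 2 frames/day for the
  rendered archive — are the package's default study conditions, chosen to
  exercise every code path at desk scale.

## Known limitations

* The phenophase mapping assumes a single growing season per year; double
  cropping or evergreen systems with weak amplitude will not produce four
  well-separated curvature-rate extrema, and extraction raises an error
  rather than guessing.
* The LSTM is univariate; no meteorological covariates.
* The extraction stage trusts timestamps in filenames (EXIF as fallback) and
  performs no image registration.
* Recursive forecasts inherit the usual error accumulation of closed-loop
  prediction; they are reported without uncertainty bands.
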