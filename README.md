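# canopyphen

Canopy phenology from near-earth remote sensing: tower-mounted time-lapse
cameras photograph a forest canopy several times a day for a year or more,
and the seasonal green-up and senescence of the stand is read out of the
image colors.  `canopyphen` implements that analysis chain for ecologists and
forest scientists working with PhenoCam-style archives:

1. **ROI extraction** — per-frame mean R, G, B brightness over fixed regions
   of interest, averaged to one triple per ROI per day (the mean-value
   method, which damps within-day illumination changes).
2. **Color indices** — six greenness indices per day:
   GCC = G/(R+G+B), RCC = R/(R+G+B), GEI = 2G−(R+B), GGR = G/R,
   GRVI = (G−R)/(G+R), and the HSV hue angle.
3. **Seasonal model** — a double-logistic fit
   `g(t) = w_min + (w_max − w_min)·[σ(mS(t−S)) + σ(−mA(t−A)) − 1]`
   with spring/autumn inflection days S, A and slopes mS, mA, plus an
   optional smoothing-spline pre-pass.
4. **Phenophase dates** — local extrema of the rate of change of the fitted
   curve's curvature `K = |g″|/(1+g′²)^{3/2}` date the start of season
   (SOS), maturity onset (MOE), start of senescence (COS) and end of season
   (EOS); LOS = MOE − SOS.
5. **Forecasting** — a gate-equation LSTM (forgetting/in/out gates written
   out in numpy, trained with backpropagation through time) predicts the
   index from 30-day sliding windows, one-step and 60-day recursive.
6. **Metrics** — MSE, RMSE, MAE, MAPE, residual and normal-QQ diagnostics.

Because public canopy-camera archives of this kind are rarely deposited, the
package ships a first-class synthetic-data generator: seeded double-logistic
trajectories with Gaussian noise, and rendered image archives whose canopy
pixels follow an invertible brown→green color ramp, so every stage can be
validated against known ground truth.

## Worked example

```python
import numpy as np
import canopyphen as cp

# a GEI-scale season: dormant ~8, peak ~45, green-up day 67, senescence day 337
params = cp.DoubleLogisticParams(w_min=8, w_max=45, s=67, a=337, m_s=0.15, m_a=0.10)
spec = cp.TrajectorySpec(params, doy_start=1, doy_end=365,
                         noise_sd=0.02 * 37, seed=11)
series = cp.generate_trajectory(spec, index_name="GEI")

model = cp.DoubleLogisticModel().fit(series.doys, series.values)
print(model.params_)
print(model.diagnostics_)
print(model.transition_dates())
```

prints (seed 11):

```
DoubleLogisticParams(w_min=7.956..., w_max=45.015..., s=66.879..., a=337.192...,
                     m_s=0.15125..., m_a=0.10033...)
FitDiagnostics(rmse=0.7194..., r_squared=0.99747..., smoothing_p=None)
PhenoDates(sos=47, moe=87, cos=310, eos=365)
```

— the fit recovers the generating parameters to a fraction of a day on the
inflections, and the curvature-rate extrema bracket them (SOS 47 < S ≈ 67 <
MOE 87; COS 310 < A ≈ 337 < EOS 365).  `los` is `moe - sos` = 40 days of
green-up.

Forecasting the same kind of series:

```python
t = np.arange(1, 427)                      # 14 months, Nov year 0 .. Dec year 1
vals = cp.evaluate_model(cp.DoubleLogisticParams(8, 45, 128, 398, 0.15, 0.10), t)
lstm = cp.LSTMForecaster(seed=0).fit((t, vals))   # 30-day windows, depth 2
fr = lstm.forecast(horizon=85, mode="one-step")
m = cp.evaluate(fr.y_true, fr.y_pred)
print(f"test MAPE {m.mape:.2f}%  RMSE {m.rmse:.3f}")   # -> test MAPE 2.15%  RMSE 1.730
```

## Command line

```
canopyphen simulate --doy-start 1 --doy-end 365 --out archive/     # synthetic frames
canopyphen extract  --input archive/ --out daily.csv               # per-ROI daily RGB
canopyphen indices  --input daily.csv --out series.csv             # six indices
canopyphen phenophase --input series.csv --out dates.json          # fits + dates
canopyphen forecast --input series.csv --index GEI --out fc.csv    # LSTM
canopyphen evaluate --input fc.csv --out metrics.json              # MSE/RMSE/MAE/MAPE
canopyphen run-all  --input archive/ --out results/                # everything
```

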