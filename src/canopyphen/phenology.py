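"""Double-logistic seasonal model, curvature-change-rate phenophase extraction.

The annual trajectory of a canopy greenness index is modelled as the sum of a
rising spring sigmoid and a falling autumn sigmoid,

    g(t) = w_min + (w_max - w_min) * [ sig(mS*(t - S)) + sig(-mA*(t - A)) - 1 ]

with ``sig(x) = 1/(1+exp(-x))``, where ``w_min``/``w_max`` are the annual
minimum and maximum of the index, ``S`` and ``A`` are the spring and autumn
inflection days, and ``mS``/``mA`` the corresponding slopes (per day).  The
curve saturates at ``w_min`` in winter on both sides and at ``w_max`` during
the growing-season plateau.

Phenological transition dates are read off the rate of change of the curve's
curvature ``K(t) = |g''| / (1 + g'^2)^{3/2}``: local extrema of ``dK/dt``
(computed on the signed curvature so extrema are well defined) bracket each
inflection, giving the start of season (SOS), the maturity onset / time point
of exuberance (MOE), the start of the senescence ("corruption") stage (COS)
and the end of season (EOS).  LOS, the length of the green-up stage, is
``MOE - SOS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class FitError(RuntimeError):
    """Raised when the double-logistic fit fails; carries the best attempt."""

    def __init__(self, message, best_params=None, best_cost=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_cost = best_cost


class ExtractionError(RuntimeError):
    """Raised when too few curvature-rate extrema exist to date all phases."""


@dataclass(frozen=True)
class DoubleLogisticParams:
    """Parameters of the double-logistic seasonal curve.

    w_min / w_max : annual minimum / maximum of the index (index units)
    s, a          : spring / autumn inflection days (DOY)
    m_s, m_a      : spring / autumn slopes (1/day), both positive
    """

    w_min: float
    w_max: float
    s: float
    a: float
    m_s: float
    m_a: float

    def __post_init__(self):
        if not self.w_max > self.w_min:
            raise ValueError(f"w_max ({self.w_max}) must exceed w_min ({self.w_min})")
        if not self.s < self.a:
            raise ValueError(f"spring inflection S ({self.s}) must precede autumn A ({self.a})")
        if self.m_s <= 0 or self.m_a <= 0:
            raise ValueError("slopes m_s and m_a must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_min, self.w_max, self.s, self.a, self.m_s, self.m_a])

    @classmethod
    def from_array(cls, x) -> "DoubleLogisticParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class FitDiagnostics:
    rmse: float
    r_squared: float
    smoothing_p: float | None = None


@dataclass(frozen=True)
class PhenoDates:
    """Transition days: sos < moe <= cos < eos, los = moe - sos."""

    sos: int
    moe: int
    cos: int
    eos: int

    def __post_init__(self):
        if not (self.sos < self.moe <= self.cos < self.eos):
            raise ValueError(
                f"phenophase ordering violated: sos={self.sos} moe={self.moe} "
                f"cos={self.cos} eos={self.eos}"
            )

    @property
    def los(self) -> int:
        return self.moe - self.sos


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def evaluate_model(params: DoubleLogisticParams, t) -> np.ndarray | float:
    """Evaluate g(t) at day-of-year t (scalar or array)."""
    t = np.asarray(t, dtype=float)
    u = _sigmoid(params.m_s * (t - params.s))
    v = _sigmoid(-params.m_a * (t - params.a))
    out = params.w_min + (params.w_max - params.w_min) * (u + v - 1.0)
    return out if out.ndim else float(out)


def _derivatives(params: DoubleLogisticParams, t):
    """Analytic g', g'', g''' of the double logistic.

    Each sigmoid term s(c*(t-b)) has derivatives expressible through
    s(1-s):  d/dt = c*s(1-s);  d2 = c^2*s(1-s)(1-2s);
    d3 = c^3*s(1-s)(1-6s+6s^2).
    """
    t = np.asarray(t, dtype=float)
    amp = params.w_max - params.w_min
    out1 = np.zeros_like(t)
    out2 = np.zeros_like(t)
    out3 = np.zeros_like(t)
    for c, b in ((params.m_s, params.s), (-params.m_a, params.a)):
        s = _sigmoid(c * (t - b))
        s1 = s * (1.0 - s)
        out1 += c * s1
        out2 += c**2 * s1 * (1.0 - 2.0 * s)
        out3 += c**3 * s1 * (1.0 - 6.0 * s + 6.0 * s * s)
    return amp * out1, amp * out2, amp * out3


def curvature(params: DoubleLogisticParams, t):
    """Unsigned curvature K = |g''| / (1 + g'^2)^(3/2)."""
    g1, g2, _ = _derivatives(params, t)
    k = np.abs(g2) / (1.0 + g1 * g1) ** 1.5
    return k if k.ndim else float(k)


def signed_curvature(params: DoubleLogisticParams, t):
    g1, g2, _ = _derivatives(params, t)
    k = g2 / (1.0 + g1 * g1) ** 1.5
    return k if k.ndim else float(k)


def curvature_change_rate(params: DoubleLogisticParams, t, *, on_unsigned: bool = False):
    """dK/dt, by default on the signed curvature so extrema are well defined.

    ``on_unsigned=True`` differentiates |K| instead (sign(g'') * signed rate),
    kept for fidelity with the absolute-value form of the curvature formula.
    """
    g1, g2, g3 = _derivatives(params, t)
    q = 1.0 + g1 * g1
    rate = (g3 * q - 3.0 * g1 * g2 * g2) / q**2.5
    if on_unsigned:
        rate = np.sign(g2) * rate
    return rate if np.ndim(rate) else float(rate)


def extract_phenophases(
    params: DoubleLogisticParams,
    t_min: float | None = None,
    t_max: float | None = None,
    step: float = 0.1,
) -> PhenoDates:
    """Date the four transitions from local extrema of dK/dt.

    The grid defaults to [S - 8/mS, A + 8/mA], comfortably covering both
    transition regions.  Extrema are located by sign changes of the discrete
    derivative of dK/dt and assigned by position: SOS is the first extremum
    before S, MOE the last between S and the mid-plateau, COS the first
    between mid-plateau and A, EOS the last after A.
    """
    if t_min is None:
        t_min = params.s - 8.0 / params.m_s
    if t_max is None:
        t_max = params.a + 8.0 / params.m_a
    grid = np.arange(t_min, t_max + step / 2, step)
    rate = curvature_change_rate(params, grid)
    d = np.diff(rate)
    # sign change of the discrete slope marks a local extremum of dK/dt
    idx = np.nonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0)[0] + 1
    extrema = grid[idx]
    mid = 0.5 * (params.s + params.a)
    spring_pre = extrema[extrema < params.s]
    spring_post = extrema[(extrema > params.s) & (extrema < mid)]
    autumn_pre = extrema[(extrema >= mid) & (extrema < params.a)]
    autumn_post = extrema[extrema > params.a]
    if not (len(spring_pre) and len(spring_post) and len(autumn_pre) and len(autumn_post)):
        raise ExtractionError(
            f"found {len(extrema)} curvature-rate extrema on [{t_min:.1f}, {t_max:.1f}]; "
            "need one in each of the four transition regions"
        )
    return PhenoDates(
        sos=round(float(spring_pre[0])),
        moe=round(float(spring_post[-1])),
        cos=round(float(autumn_pre[0])),
        eos=round(float(autumn_post[-1])),
    )


def smooth_series(doys, values, smoothing_p: float):
    """Smoothing-spline pass with roughness parameter p in (0, 1].

    p = 1 interpolates the data; p -> 0+ approaches the least-squares line.
    Internally mapped onto a second-derivative roughness penalty with weight
    lam = (1 - p)/p.
    """
    if not 0.0 < smoothing_p <= 1.0:
        raise ValueError(f"smoothing_p must be in (0, 1], got {smoothing_p}")
    doys = np.asarray(doys, dtype=float)
    values = np.asarray(values, dtype=float)
    if doys.size < 4:
        raise ValueError("smoothing requires at least 4 points")
    lam = (1.0 - smoothing_p) / smoothing_p
    spline = make_smoothing_spline(doys, values, lam=lam)
    return spline(doys)


class DoubleLogisticModel(RegressorMixin, BaseEstimator):
    """Least-squares double-logistic fit of an index series against DOY.

    Parameters
    ----------
    n_restarts : extra fits from jittered initial guesses; the best SSE wins.
    random_state : seed for the restart jitter.
    smoothing_p : optional spline pre-smoothing parameter in (0, 1] applied to
        the series before fitting.
    ftol : SSE convergence tolerance passed to the optimizer.

    Attributes
    ----------
    params_ : fitted :class:`DoubleLogisticParams`
    diagnostics_ : :class:`FitDiagnostics` with rmse and R^2 on the raw data
    """

    def __init__(self, n_restarts: int = 5, random_state: int = 0,
                 smoothing_p: float | None = None, ftol: float = 1e-10):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.smoothing_p = smoothing_p
        self.ftol = ftol

    # -- initial guess -----------------------------------------------------
    @staticmethod
    def _initial_guess(t, y):
        w_lo, w_hi = np.percentile(y, [5, 95])
        if not w_hi > w_lo:
            raise FitError("series has no amplitude (flat input); nothing to fit")
        half = 0.5 * (w_lo + w_hi)
        above = y >= half
        # first and last crossings of the half-amplitude level
        rising = np.nonzero(above)[0]
        if rising.size == 0 or rising[0] == 0 and rising[-1] == len(y) - 1:
            s0, a0 = np.percentile(t, [25, 75])
        else:
            s0 = t[rising[0]]
            a0 = t[rising[-1]]
        if not s0 < a0:
            s0, a0 = np.percentile(t, [25, 75])
        return np.array([w_lo, w_hi, s0, a0, 0.1, 0.1])

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have the same length")
        mask = np.isfinite(y)
        t, y = t[mask], y[mask]
        if t.size < 6:
            raise ValueError(f"need at least 6 non-missing points, got {t.size}")
        y_fit_target = y
        if self.smoothing_p is not None:
            y_fit_target = smooth_series(t, y, self.smoothing_p)

        x0 = self._initial_guess(t, y_fit_target)
        span = t.max() - t.min()
        lo = [y.min() - 10 * np.ptp(y), y.min(), t.min() - span, t.min() - span, 1e-4, 1e-4]
        hi = [y.max(), y.max() + 10 * np.ptp(y), t.max() + span, t.max() + span, 5.0, 5.0]
        x0 = np.clip(x0, lo, hi)

        def resid(x):
            u = _sigmoid(x[4] * (t - x[2]))
            v = _sigmoid(-x[5] * (t - x[3]))
            return x[0] + (x[1] - x[0]) * (u + v - 1.0) - y_fit_target

        rng = np.random.default_rng(self.random_state)
        best = None
        starts = [x0]
        scale = np.array([np.ptp(y) * 0.1, np.ptp(y) * 0.1, span * 0.05, span * 0.05, 0.03, 0.03])
        for _ in range(self.n_restarts):
            starts.append(np.clip(x0 + rng.normal(0, 1, 6) * scale, lo, hi))
        for start in starts:
            try:
                sol = least_squares(resid, start, bounds=(lo, hi), ftol=self.ftol,
                                    xtol=1e-12, gtol=1e-12)
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            if sol.x[1] - sol.x[0] <= 0 or sol.x[2] >= sol.x[3]:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError("double-logistic fit did not converge from any start",
                           best_params=None)
        params = DoubleLogisticParams.from_array(best.x)
        pred = evaluate_model(params, t)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.params_ = params
        self.diagnostics_ = FitDiagnostics(
            rmse=math.sqrt(ss_res / t.size),
            r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
            smoothing_p=self.smoothing_p,
        )
        self.n_points_ = int(t.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return evaluate_model(self.params_, t)

    def transition_dates(self, step: float = 0.1) -> PhenoDates:
        check_is_fitted(self, "params_")
        return extract_phenophases(self.params_, step=step)


def fit_double_logistic(series, init: DoubleLogisticParams | None = None,
                        smoothing_p: float | None = None,
                        random_state: int = 0):
    """Functional wrapper: fit a series, return (params, diagnostics).

    ``series`` is anything with ``doys``/``values`` attributes or a
    ``(doys, values)`` pair.  ``init`` overrides the automatic initial guess.
    """
    if hasattr(series, "doys"):
        t, y = series.doys, series.values
    else:
        t, y = series
    model = DoubleLogisticModel(smoothing_p=smoothing_p, random_state=random_state)
    if init is not None:
        # seed the heuristic by fitting from the user-supplied start only
        model._initial_guess = lambda tt, yy: init.as_array()  # type: ignore[method-assign]
    model.fit(t, y)
    return model.params_, model.diagnostics_
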