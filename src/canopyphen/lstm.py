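"""Gate-equation LSTM forecaster for daily color-index series.

The recurrent cell is implemented directly from the gate equations

    f_t = sigmoid(W_f . [h_{t-1}, x_t] + b_f)          (forgetting gate)
    i_t = sigmoid(W_i . [h_{t-1}, x_t] + b_i)          (in-gate)
    Cbar_t = tanh(W_c . [h_{t-1}, x_t] + b_c)          (candidate state)
    C_t = f_t * C_{t-1} + i_t * Cbar_t                 (cell state update)
    O_t = sigmoid(W_o . [h_{t-1}, x_t] + b_o)          (out-gate)
    h_t = O_t * tanh(C_t)

with numpy forward/backward passes (backpropagation through time with
analytic gradients) rather than a deep-learning framework, so every
quantity above is inspectable.  The forecaster stacks ``depth`` cells
(layer 2 consumes layer 1's hidden sequence), adds a scalar linear read-out
on the final hidden state — the gate equations alone never produce a scalar
prediction — and trains by stochastic gradient descent with adaptive moment
estimation (Adam) on squared error over 30-day sliding windows, one update
per window per epoch in chronological order, the learning rate decaying
exponentially per epoch.

Series are min-max normalized to [0, 1] before windowing and predictions are
mapped back to index units.  Windows are built only over contiguous runs of
days: a window spanning a gap would silently change the meaning of
"30 days of input".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

_GATES = ("f", "i", "c", "o")


class TrainingError(RuntimeError):
    def __init__(self, message, epoch=None):
        super().__init__(message)
        self.epoch = epoch


@dataclass
class LSTMWeights:
    """Per-gate weight matrices over the concatenated [h_{t-1}, x_t] vector."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.hidden_size

    def __post_init__(self):
        h = self.W_f.shape[0]
        for g in _GATES:
            W = getattr(self, f"W_{g}")
            b = getattr(self, f"b_{g}")
            if W.shape != self.W_f.shape or b.shape != (h,):
                raise ValueError("inconsistent gate weight shapes")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValueError("non-finite weight entries")


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def lstm_cell_forward(x_t, h_prev, C_prev, weights: LSTMWeights):
    """One step of the gate equations; returns (h_t, C_t)."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.asarray(h_prev, dtype=float)
    C_prev = np.asarray(C_prev, dtype=float)
    if x_t.shape != (weights.input_size,) or h_prev.shape != (weights.hidden_size,) \
            or C_prev.shape != (weights.hidden_size,):
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, C {C_prev.shape} "
            f"vs hidden {weights.hidden_size}, input {weights.input_size}")
    cat = np.concatenate([h_prev, x_t])
    f = _sigmoid(weights.W_f @ cat + weights.b_f)
    i = _sigmoid(weights.W_i @ cat + weights.b_i)
    cbar = np.tanh(weights.W_c @ cat + weights.b_c)
    C_t = f * C_prev + i * cbar
    o = _sigmoid(weights.W_o @ cat + weights.b_o)
    h_t = o * np.tanh(C_t)
    return h_t, C_t


# ----------------------------------------------------------------------
# data plumbing

def normalize(values):
    """Min-max scale to [0, 1]; returns (scaled, scaler). Linear, no clipping."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    if np.ptp(values) == 0:
        raise ValueError("cannot min-max normalize a constant series")
    scaler = MinMaxScaler(clip=False).fit(values)
    return scaler.transform(values).ravel(), scaler


def denormalize(scaled, scaler) -> np.ndarray:
    return scaler.inverse_transform(np.asarray(scaled, dtype=float).reshape(-1, 1)).ravel()


def make_windows(doys, values, window: int):
    """Sliding supervised pairs: ``window`` days in, day ``window+1`` out.

    Windows never span a DOY gap; returns (X (n, window), y (n,),
    target_doys (n,)) in chronological order.
    """
    doys = np.asarray(doys, dtype=int)
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if values.size <= window:
        raise ValueError(f"series length {values.size} must exceed window {window}")
    # contiguous runs of consecutive days
    breaks = np.nonzero(np.diff(doys) != 1)[0] + 1
    X, y, td = [], [], []
    for run in np.split(np.arange(doys.size), breaks):
        v = values[run]
        for k in range(v.size - window):
            X.append(v[k:k + window])
            y.append(v[k + window])
            td.append(doys[run[k + window]])
    if not X:
        raise ValueError("no contiguous run longer than the window")
    return np.array(X), np.array(y), np.array(td)


@dataclass
class ForecastResult:
    doys: np.ndarray
    y_pred: np.ndarray
    y_true: np.ndarray | None
    mode: str

    def __post_init__(self):
        if len(self.doys) != len(self.y_pred):
            raise ValueError("doys and y_pred lengths differ")
        if self.y_true is not None and len(self.y_true) != len(self.y_pred):
            raise ValueError("y_true length differs")


# ----------------------------------------------------------------------
# the forecaster

class LSTMForecaster(RegressorMixin, BaseEstimator):
    """Stacked-LSTM next-day predictor trained on sliding windows.

    Parameters mirror the study configuration: 30-day window, depth-2 stack,
    weights initialized U(-0.01, 0.01), learning rate 1e-5 decaying
    exponentially per epoch, chronological 70/20/10 train/test/verification
    split (no shuffling across boundaries).

    Attributes (after fit)
    ----------------------
    layers_ : list of per-layer stacked gate matrices ``(W, b)`` with rows
        ordered f, i, c, o
    readout_w_, readout_b_ : linear head mapping the final hidden state to
        the scalar next-day value
    history_ : per-epoch mean training loss (normalized units)
    scaler_ : the min-max record; split_ : index bounds of the partitions
    """

    def __init__(self, window: int = 30, depth: int = 2, hidden_size: int = 16,
                 init_range: float = 0.01, learning_rate: float = 1e-5,
                 lr_decay: float = 0.999, epochs: int = 100, seed: int = 0,
                 split: tuple = (0.7, 0.2, 0.1)):
        self.window = window
        self.depth = depth
        self.hidden_size = hidden_size
        self.init_range = init_range
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.seed = seed
        self.split = split

    # -- internals ---------------------------------------------------------

    def _init_weights(self, rng):
        H, R = self.hidden_size, self.init_range
        layers = []
        for l in range(self.depth):
            d = 1 if l == 0 else H
            W = rng.uniform(-R, R, size=(4 * H, H + d))
            b = rng.uniform(-R, R, size=4 * H)
            layers.append([W, b])
        w_r = rng.uniform(-R, R, size=H)
        b_r = float(rng.uniform(-R, R))
        return layers, w_r, b_r

    def _forward(self, x, layers):
        """Run the stack over one window; returns per-layer step caches.

        Gate nonlinearities are fused into one tanh call per step
        (sigmoid(z) = 0.5 + 0.5*tanh(z/2)); numerically identical to
        :func:`lstm_cell_forward`.
        """
        H = self.hidden_size
        seq = x[:, None]  # (T, 1)
        caches = []
        half = np.full(4 * H, 0.5)
        half[2 * H:3 * H] = 1.0  # candidate state uses plain tanh
        for W, b in layers:
            d = W.shape[1] - H
            h = np.zeros(H)
            C = np.zeros(H)
            steps = []
            outs = np.empty((len(seq), H))
            cat_buf = np.empty(H + d)
            for t, x_t in enumerate(seq):
                cat_buf[:H] = h
                cat_buf[H:] = x_t
                cat = cat_buf.copy()
                a = np.tanh(half * (W @ cat + b))
                f = 0.5 + 0.5 * a[:H]
                i = 0.5 + 0.5 * a[H:2 * H]
                cbar = a[2 * H:3 * H]
                o = 0.5 + 0.5 * a[3 * H:]
                C_new = f * C + i * cbar
                tC = np.tanh(C_new)
                h_new = o * tC
                steps.append((cat, f, i, cbar, o, C, C_new, tC))
                h, C = h_new, C_new
                outs[t] = h
            caches.append((steps, outs))
            seq = outs
        return caches

    def _backward(self, x, caches, layers, dh_top_last):
        """BPTT through the stack; returns per-layer (dW, db) gradients."""
        H = self.hidden_size
        grads = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
        T = len(x)
        # incoming dh per timestep for the current (top-down) layer
        dh_seq = np.zeros((T, H))
        dh_seq[-1] = dh_top_last
        for l in range(self.depth - 1, -1, -1):
            W, b = layers[l]
            steps, _ = caches[l]
            dW, db = grads[l]
            d = W.shape[1] - H
            dx_seq = np.zeros((T, d))
            dh_next = np.zeros(H)
            dC_next = np.zeros(H)
            for t in range(T - 1, -1, -1):
                cat, f, i, cbar, o, C_prev, C_new, tC = steps[t]
                dh = dh_seq[t] + dh_next
                do = dh * tC
                dC = dh * o * (1.0 - tC * tC) + dC_next
                df = dC * C_prev
                di = dC * cbar
                dcbar = dC * i
                dC_next = dC * f
                da = np.concatenate([
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    dcbar * (1.0 - cbar * cbar),
                    do * o * (1.0 - o),
                ])
                dW += np.outer(da, cat)
                db += da
                dcat = W.T @ da
                dh_next = dcat[:H]
                dx_seq[t] = dcat[H:]
            dh_seq = dx_seq  # becomes the incoming dh of the layer below
        return grads

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y=None):
        """Train on a series. X is an IndexSeries, a (doys, values) pair, or a
        1-D value array (days then assumed consecutive)."""
        doys, values = _coerce_series(X)
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        scaled, self.scaler_ = normalize(values)
        n = scaled.size
        n_train = int(round(self.split[0] * n))
        n_test = int(round(self.split[1] * n))
        self.split_ = (n_train, n_train + n_test, n)
        Xw, yw, _ = make_windows(doys[:n_train], scaled[:n_train], self.window)

        rng = np.random.default_rng(self.seed)
        layers, w_r, b_r = self._init_weights(rng)
        params = [arr for pair in layers for arr in pair] + [w_r, np.array([b_r])]
        adam_m = [np.zeros_like(p) for p in params]
        adam_v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = []
        lr = self.learning_rate
        for epoch in range(self.epochs):
            total = 0.0
            for xw, target in zip(Xw, yw):
                caches = self._forward(xw, layers)
                h_last = caches[-1][1][-1]
                pred = float(w_r @ h_last + params[-1][0])
                err = pred - target
                total += err * err
                dy = 2.0 * err
                grads = self._backward(xw, caches, layers, dy * w_r)
                flat_grads = [g for pair in grads for g in pair] \
                    + [dy * h_last, np.array([dy])]
                step += 1
                c1 = 1.0 - beta1**step
                c2 = 1.0 - beta2**step
                for p, g, m, v in zip(params, flat_grads, adam_m, adam_v):
                    m *= beta1
                    m += (1.0 - beta1) * g
                    v *= beta2
                    v += (1.0 - beta2) * g * g
                    p -= lr * (m / c1) / (np.sqrt(v / c2) + eps)
            loss = total / len(Xw)
            if not np.isfinite(loss):
                raise TrainingError("training loss became non-finite", epoch=epoch)
            history.append(loss)
            lr *= self.lr_decay
        self.layers_ = layers
        self.readout_w_ = w_r
        self.readout_b_ = float(params[-1][0])
        self.history_ = np.array(history)
        self.doys_ = doys
        self.values_ = values
        return self

    def weights(self, layer: int = 0) -> LSTMWeights:
        """Expose a layer's stacked parameters as per-gate matrices."""
        check_is_fitted(self, "layers_")
        W, b = self.layers_[layer]
        H = self.hidden_size
        return LSTMWeights(
            W_f=W[:H], W_i=W[H:2 * H], W_c=W[2 * H:3 * H], W_o=W[3 * H:],
            b_f=b[:H], b_i=b[H:2 * H], b_c=b[2 * H:3 * H], b_o=b[3 * H:])

    def _predict_scaled(self, xw) -> float:
        caches = self._forward(np.asarray(xw, dtype=float), self.layers_)
        return float(self.readout_w_ @ caches[-1][1][-1] + self.readout_b_)

    def predict(self, X):
        """Next-day predictions (index units) for windows (n, window) given in
        index units."""
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.window:
            raise ValueError(f"windows must have length {self.window}")
        scaled = (X - self.scaler_.data_min_[0]) / (
            self.scaler_.data_max_[0] - self.scaler_.data_min_[0])
        preds = np.array([self._predict_scaled(row) for row in scaled])
        return denormalize(preds, self.scaler_)

    def forecast(self, horizon: int = 60, mode: str = "recursive",
                 start: int | None = None) -> ForecastResult:
        """Forecast from the fitted series.

        ``one-step``: predict each of the next ``horizon`` observed points
        after ``start`` (default: the train/test boundary), always from true
        history.  ``recursive``: roll forward ``horizon`` days past ``start``
        (default: end of series), feeding predictions back as inputs.
        """
        check_is_fitted(self, "layers_")
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        scaled = (self.values_ - self.scaler_.data_min_[0]) / (
            self.scaler_.data_max_[0] - self.scaler_.data_min_[0])
        n = scaled.size
        if mode == "one-step":
            start = self.split_[0] if start is None else start
            stop = min(start + horizon, n)
            if start < self.window:
                raise ValueError("not enough history before the forecast start")
            preds = [self._predict_scaled(scaled[t - self.window:t])
                     for t in range(start, stop)]
            return ForecastResult(
                doys=self.doys_[start:stop],
                y_pred=denormalize(preds, self.scaler_),
                y_true=self.values_[start:stop], mode=mode)
        if mode == "recursive":
            start = n if start is None else start
            if start < self.window:
                raise ValueError("not enough history before the forecast start")
            buf = list(scaled[start - self.window:start])
            preds = []
            for _ in range(horizon):
                p = self._predict_scaled(np.array(buf[-self.window:]))
                preds.append(p)
                buf.append(p)
            doys = self.doys_[start - 1] + 1 + np.arange(horizon) if start >= 1 \
                else np.arange(1, horizon + 1)
            y_true = None
            if start + horizon <= n:
                y_true = self.values_[start:start + horizon]
            return ForecastResult(doys=doys, y_pred=denormalize(preds, self.scaler_),
                                  y_true=y_true, mode=mode)
        raise ValueError(f"unknown mode {mode!r}")


def _coerce_series(X):
    if hasattr(X, "doys"):
        return np.asarray(X.doys, dtype=int), np.asarray(X.values, dtype=float)
    if isinstance(X, tuple) and len(X) == 2:
        return np.asarray(X[0], dtype=int), np.asarray(X[1], dtype=float)
    v = np.asarray(X, dtype=float).reshape(-1)
    return np.arange(1, v.size + 1), v


def train(series, config=None, **kwargs) -> LSTMForecaster:
    """Functional wrapper: build an :class:`LSTMForecaster` from a config
    mapping (or keyword overrides) and fit it on the series."""
    opts = dict(config or {})
    opts.update(kwargs)
    return LSTMForecaster(**opts).fit(series)
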