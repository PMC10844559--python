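"""Sequence-to-sequence LSTM surrogate of the viscoelastic forward model.

The network maps a per-timestep input vector — the five constitutive
parameters broadcast along the sequence, plus axial stretch, amount of
shear, and time — to the two stress channels ``(P, tau)`` at every
timestep.  Architecture: LSTM(64, sequences) -> dropout -> LSTM(64,
sequences) -> dropout -> per-timestep dense(2).  Training minimizes the
mean absolute error on z-score-normalized outputs with Adam; inputs and
outputs are normalized per feature with training-set statistics.

The implementation (forward pass, backpropagation through time, inverted
dropout, Adam) is written directly on NumPy arrays in float32; analytic
gradients are checked against finite differences in the test suite.
Dropout doubles as the uncertainty mechanism: repeated stochastic forward
passes (Monte-Carlo dropout) give a per-sample predictive variance used by
the active-learning acquisition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .forward_model import LoadingProtocol

__all__ = [
    "SurrogateConfig",
    "Normalizer",
    "LSTMSurrogate",
    "build_model",
    "build_inputs",
    "train",
    "mc_dropout_predict",
    "r_squared",
]


@dataclass
class SurrogateConfig:
    """Architecture and training hyperparameters of the surrogate."""

    lstm_layers: int = 2
    cells_per_layer: int = 64
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 1000
    batch_size: int = 32
    seed: int = 0
    include_time: bool = True

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


class Normalizer:
    """Per-feature z-score normalization with training-set statistics."""

    def __init__(self, mean=None, std=None):
        self.mean_ = None if mean is None else np.asarray(mean, dtype=np.float64)
        self.std_ = None if std is None else np.asarray(std, dtype=np.float64)

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, X: np.ndarray) -> "Normalizer":
        """Fit statistics over all leading axes; features are the last axis."""
        X = np.asarray(X, dtype=np.float64)
        flat = X.reshape(-1, X.shape[-1])
        self.mean_ = flat.mean(axis=0)
        std = flat.std(axis=0)
        if np.any(std == 0):
            warnings.warn("constant feature(s) in normalizer; std set to 1")
            std = np.where(std == 0, 1.0, std)
        self.std_ = std
        return self

    def _check(self):
        if not self.fitted:
            raise RuntimeError("normalizer statistics have not been fitted")

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.std_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(X, dtype=np.float64) * self.std_ + self.mean_

    def to_dict(self) -> dict:
        self._check()
        return {"mean": self.mean_.tolist(), "std": self.std_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(mean=d["mean"], std=d["std"])


def build_inputs(thetas: np.ndarray, protocol: LoadingProtocol, include_time: bool = True) -> np.ndarray:
    """Assemble raw per-timestep input sequences for a batch of parameter sets.

    ``thetas`` is (n, 5) in ``PARAM_NAMES`` order; the result is
    (n, len(protocol), 5 + 2 (+1)): parameters broadcast along time, then
    ``lambda(t)``, ``gamma(t)`` and optionally ``t`` itself.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=np.float64))
    n, N = thetas.shape[0], len(protocol)
    cols = [protocol.stretch, protocol.shear] + ([protocol.time] if include_time else [])
    drive = np.column_stack(cols)  # (N, 2 or 3)
    X = np.empty((n, N, thetas.shape[1] + drive.shape[1]))
    X[:, :, : thetas.shape[1]] = thetas[:, None, :]
    X[:, :, thetas.shape[1]:] = drive[None, :, :]
    return X


# ---------------------------------------------------------------------------
# LSTM layer forward / backward (batch, time, feature), float32 by default
# ---------------------------------------------------------------------------


# Gate layout in the fused weight matrices: columns [0:3H] are the sigmoid
# gates (input, forget, output) and [3H:4H] the tanh candidate, so each
# nonlinearity is applied to one contiguous block per step.


def _lstm_forward(X, Wx, Wh, b, want_cache: bool):
    """One LSTM layer over a (batch, time, feature) block.

    The input projection is a single GEMM for all timesteps; the recurrence
    loop works on time-major contiguous buffers.  Returns the hidden
    sequence time-major (N, B, H) plus the activation cache for BPTT.
    """
    B, N, D = X.shape
    H = Wh.shape[0]
    dtype = X.dtype
    Zx = (X.reshape(-1, D) @ Wx).reshape(B, N, 4 * H)
    Zx += b
    Zt = np.ascontiguousarray(Zx.transpose(1, 0, 2))  # (N, B, 4H)
    Ht = np.empty((N, B, H), dtype)
    S = np.empty((N, B, 3 * H), dtype)  # sigmoid gates i, f, o
    G = np.empty((N, B, H), dtype)  # tanh candidate
    C = np.empty((N, B, H), dtype)  # cell state
    TC = np.empty((N, B, H), dtype)  # tanh(cell)
    h = np.zeros((B, H), dtype)
    c = np.zeros((B, H), dtype)
    for t in range(N):
        z = Zt[t]
        z += h @ Wh
        s = expit(z[:, : 3 * H], out=S[t])
        g = np.tanh(z[:, 3 * H :], out=G[t])
        i, f, o = s[:, :H], s[:, H : 2 * H], s[:, 2 * H :]
        ct = np.multiply(f, c, out=C[t])
        ct += i * g
        tc = np.tanh(ct, out=TC[t])
        h = np.multiply(o, tc, out=Ht[t])
        c = ct
    return Ht, ((S, G, C, TC) if want_cache else None)


def _lstm_backward(X, Ht, cache, Wx, Wh, dHt):
    """BPTT through one layer.  ``dHt`` is time-major (N, B, H); returns the
    batch-major input gradient plus the weight gradients."""
    B, N, D = X.shape
    H = Wh.shape[0]
    dtype = X.dtype
    S, G, C, TC = cache
    dZt = np.empty((N, B, 4 * H), dtype)
    dh_next = np.zeros((B, H), dtype)
    dc_next = np.zeros((B, H), dtype)
    WhT = np.ascontiguousarray(Wh.T)
    for t in range(N - 1, -1, -1):
        s, g, tc = S[t], G[t], TC[t]
        i, f, o = s[:, :H], s[:, H : 2 * H], s[:, 2 * H :]
        c_prev = C[t - 1] if t > 0 else np.zeros((B, H), dtype)
        dh = dHt[t] + dh_next
        dc = dh * o
        dc *= 1.0 - tc * tc
        dc += dc_next
        dz = dZt[t]
        dz[:, :H] = dc * g
        dz[:, H : 2 * H] = dc * c_prev
        dz[:, 2 * H : 3 * H] = dh * tc
        dz[:, : 3 * H] *= s * (1.0 - s)  # sigmoid derivative, all three gates
        dz[:, 3 * H :] = (dc * i) * (1.0 - g * g)
        dh_next = dz @ WhT
        dc_next = dc * f
    flatZt = dZt.reshape(-1, 4 * H)  # time-major flattening
    # recurrent-kernel gradient: sum over (t, b) of h_{t-1} x dz_t
    dWh = np.zeros((H, 4 * H), dtype)
    Hprev_flat = Ht[: N - 1].reshape(-1, H)
    if N > 1:
        dWh += Hprev_flat.T @ dZt[1:].reshape(-1, 4 * H)
    db = flatZt.sum(axis=0)
    # input-kernel gradient and input gradient need batch-major ordering
    flatZ = np.ascontiguousarray(dZt.transpose(1, 0, 2)).reshape(-1, 4 * H)
    dWx = X.reshape(-1, D).T @ flatZ
    dX = (flatZ @ Wx.T).reshape(B, N, D)
    return dX, dWx, dWh, db


class LSTMSurrogate:
    """Stacked-LSTM regressor with dropout and an Adam optimizer state.

    Weights live in ``self.params`` as a flat dict; ``dtype`` is float32 by
    default (float64 is used by the gradient-check tests).
    """

    def __init__(self, config: SurrogateConfig, n_features: int | None = None, dtype=np.float32):
        self.config = config
        self.n_features = n_features if n_features is not None else 5 + 2 + int(config.include_time)
        self.n_outputs = 2
        self.dtype = np.dtype(dtype)
        self.input_normalizer = Normalizer()
        self.output_normalizer = Normalizer()
        self.rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        self._init_weights()

    # -- initialization -----------------------------------------------------

    def _glorot(self, shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return self.rng.uniform(-lim, lim, size=shape).astype(self.dtype)

    def _orthogonal(self, n, m):
        a = self.rng.standard_normal((max(n, m), min(n, m)))
        q, r = np.linalg.qr(a)
        q = q * np.sign(np.diag(r))
        q = q if n >= m else q.T
        return q[:n, :m].astype(self.dtype)

    def _init_weights(self):
        H = self.config.cells_per_layer
        D = self.n_features
        for layer in range(self.config.lstm_layers):
            d_in = D if layer == 0 else H
            self.params[f"Wx{layer}"] = self._glorot((d_in, 4 * H))
            # recurrent kernel: orthogonal blocks per gate
            self.params[f"Wh{layer}"] = np.concatenate(
                [self._orthogonal(H, H) for _ in range(4)], axis=1
            )
            b = np.zeros(4 * H, self.dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b{layer}"] = b
        self.params["Wd"] = self._glorot((H, self.n_outputs))
        self.params["bd"] = np.zeros(self.n_outputs, self.dtype)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    @property
    def n_weights(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def set_dropout_rate(self, rate: float) -> None:
        self.config.dropout_rate = float(rate)

    # -- forward / backward -------------------------------------------------

    def _forward(self, Xn, dropout_rng=None, want_cache=False):
        """Forward pass on normalized inputs.  ``dropout_rng`` enables the
        stochastic (inverted) dropout masks between the layers."""
        Xn = np.ascontiguousarray(Xn, dtype=self.dtype)
        p = self.config.dropout_rate
        A = Xn
        caches, masks, inputs, houts = [], [], [], []
        for layer in range(self.config.lstm_layers):
            Ht, cache = _lstm_forward(
                A, self.params[f"Wx{layer}"], self.params[f"Wh{layer}"],
                self.params[f"b{layer}"], want_cache,
            )
            inputs.append(A)
            houts.append(Ht)  # time-major, pre-mask: the recurrence ran on these
            A = np.ascontiguousarray(Ht.transpose(1, 0, 2))  # back to (B, N, H)
            if dropout_rng is not None and p > 0.0:
                mask = (dropout_rng.random(A.shape, dtype=np.float32) >= p).astype(self.dtype)
                mask /= self.dtype.type(1.0 - p)
                A = A * mask
            else:
                mask = None
            caches.append(cache)
            masks.append(mask)
        B, N, H = A.shape
        Y = (A.reshape(-1, H) @ self.params["Wd"] + self.params["bd"]).reshape(B, N, self.n_outputs)
        if want_cache:
            return Y, (inputs, houts, caches, masks, A)
        return Y

    def _backward(self, ctx, dY):
        inputs, houts, caches, masks, A_last = ctx
        grads = {}
        B, N, H = A_last.shape
        flat_dY = dY.reshape(-1, self.n_outputs)
        grads["Wd"] = A_last.reshape(-1, H).T @ flat_dY
        grads["bd"] = flat_dY.sum(axis=0)
        dA = (flat_dY @ self.params["Wd"].T).reshape(B, N, H)
        for layer in range(self.config.lstm_layers - 1, -1, -1):
            if masks[layer] is not None:
                dA = dA * masks[layer]
            dHt = np.ascontiguousarray(dA.transpose(1, 0, 2))
            dA, dWx, dWh, db = _lstm_backward(
                inputs[layer], houts[layer], caches[layer],
                self.params[f"Wx{layer}"], self.params[f"Wh{layer}"], dHt,
            )
            grads[f"Wx{layer}"] = dWx
            grads[f"Wh{layer}"] = dWh
            grads[f"b{layer}"] = db
        return grads

    def _loss_and_grads(self, Xn, Tn, dropout_rng=None):
        Y, ctx = self._forward(Xn, dropout_rng=dropout_rng, want_cache=True)
        Tn = np.asarray(Tn, dtype=self.dtype)
        diff = Y - Tn
        loss = float(np.mean(np.abs(diff)))
        dY = np.sign(diff) / self.dtype.type(diff.size)
        grads = self._backward(ctx, dY)
        return loss, grads

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self._adam_t += 1
        t = self._adam_t
        bc1 = 1.0 - beta1**t
        bc2 = 1.0 - beta2**t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            self.params[k] -= (lr * (m / bc1) / (np.sqrt(v / bc2) + eps)).astype(self.dtype)

    # -- public API ---------------------------------------------------------

    def fit_normalizers(self, X_raw, Y_raw):
        """Fit input/output statistics; kept fixed across later trainings so
        that warm-started weights keep their meaning as the pool grows."""
        self.input_normalizer.fit(X_raw)
        self.output_normalizer.fit(Y_raw)
        return self

    def predict(self, X_raw, denormalize: bool = True):
        """Deterministic prediction (dropout off)."""
        Yn = self._forward(self.input_normalizer.transform(X_raw))
        return self.output_normalizer.inverse_transform(Yn) if denormalize else np.asarray(Yn, np.float64)

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.params)
        (d / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        sidecar = {
            "n_features": self.n_features,
            "input": self.input_normalizer.to_dict(),
            "output": self.output_normalizer.to_dict(),
        }
        (d / "normalizer.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory) -> "LSTMSurrogate":
        d = Path(directory)
        config = SurrogateConfig(**json.loads((d / "config.json").read_text()))
        sidecar = json.loads((d / "normalizer.json").read_text())
        model = cls(config, n_features=sidecar["n_features"])
        with np.load(d / "weights.npz") as z:
            model.params = {k: z[k].copy() for k in z.files}
        model._adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
        model._adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
        model.input_normalizer = Normalizer.from_dict(sidecar["input"])
        model.output_normalizer = Normalizer.from_dict(sidecar["output"])
        return model


def build_model(config: SurrogateConfig, n_features: int | None = None) -> LSTMSurrogate:
    """Construct a seeded surrogate network from its configuration."""
    return LSTMSurrogate(config, n_features=n_features)


def train(
    model: LSTMSurrogate,
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    epochs: int | None = None,
    shuffle: bool = True,
) -> list[float]:
    """Train on raw (unnormalized) sequences; returns per-epoch mean loss.

    Normalizer statistics are fitted on the first call and reused afterwards
    (warm starts).  Dropout is active whenever ``config.dropout_rate > 0``.
    Deterministic for a fixed model seed and call sequence.
    """
    epochs = model.config.epochs if epochs is None else epochs
    if len(X_raw) == 0:
        raise ValueError("training pool is empty")
    if not model.input_normalizer.fitted:
        model.fit_normalizers(X_raw, Y_raw)
    Xn = np.ascontiguousarray(model.input_normalizer.transform(X_raw), dtype=model.dtype)
    Tn = np.ascontiguousarray(model.output_normalizer.transform(Y_raw), dtype=model.dtype)
    n = Xn.shape[0]
    bs = model.config.batch_size
    history = []
    for _ in range(epochs):
        order = model.rng.permutation(n) if shuffle else np.arange(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            drop_rng = model.rng if model.config.dropout_rate > 0 else None
            loss, grads = model._loss_and_grads(Xn[idx], Tn[idx], dropout_rng=drop_rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss {loss}")
            model._adam_step(grads, model.config.learning_rate)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def mc_dropout_predict(
    model: LSTMSurrogate,
    X_raw: np.ndarray,
    n_calls: int = 16,
    rng: np.random.Generator | None = None,
):
    """Monte-Carlo dropout prediction.

    Runs ``n_calls`` stochastic forward passes and returns
    ``(mean_raw, variance_scalar, variance_t)``: the denormalized mean
    prediction, the per-sample scalar variance (across-call variance
    averaged over timesteps and both channels, in normalized output space),
    and the per-timestep variance field.
    """
    if n_calls < 2:
        raise ValueError("n_calls must be >= 2 for a variance estimate")
    if model.config.dropout_rate > 0 and rng is None:
        rng = model.rng
    Xn = model.input_normalizer.transform(X_raw)
    acc = None
    acc2 = None
    for _ in range(n_calls):
        Y = model._forward(Xn, dropout_rng=rng if model.config.dropout_rate > 0 else None)
        Y = np.asarray(Y, dtype=np.float64)
        acc = Y if acc is None else acc + Y
        acc2 = Y * Y if acc2 is None else acc2 + Y * Y
    mean_n = acc / n_calls
    var = np.clip(acc2 / n_calls - mean_n**2, 0.0, None)
    var_scalar = var.mean(axis=(1, 2))
    return model.output_normalizer.inverse_transform(mean_n), var_scalar, var


def r_squared(Y_true: np.ndarray, Y_pred: np.ndarray):
    """Per-sample coefficient of determination, pooled over timesteps and
    both output channels, plus its mean and standard deviation over samples.

    Samples with zero-variance truth are excluded with a warning.
    """
    Y_true = np.asarray(Y_true, dtype=np.float64)
    Y_pred = np.asarray(Y_pred, dtype=np.float64)
    if Y_true.shape != Y_pred.shape:
        raise ValueError("shape mismatch between truth and prediction")
    if Y_true.ndim == 2:
        Y_true, Y_pred = Y_true[None], Y_pred[None]
    n = Y_true.shape[0]
    flat_t = Y_true.reshape(n, -1)
    flat_p = Y_pred.reshape(n, -1)
    ss_res = np.sum((flat_t - flat_p) ** 2, axis=1)
    ss_tot = np.sum((flat_t - flat_t.mean(axis=1, keepdims=True)) ** 2, axis=1)
    valid = ss_tot > 0
    if not np.all(valid):
        warnings.warn(f"{int((~valid).sum())} zero-variance sample(s) excluded from R^2")
    r2 = np.full(n, np.nan)
    r2[valid] = 1.0 - ss_res[valid] / ss_tot[valid]
    vals = r2[valid]
    return r2, float(vals.mean()), float(vals.std())
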