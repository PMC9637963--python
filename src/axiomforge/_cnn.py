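"""Minimal 1D convolutional network regressor for genomic prediction,
implemented directly in NumPy (forward pass, backpropagation, Adam).

Architecture: convolution over the marker axis -> ReLU -> pooling
(min/mean/max) -> dropout -> dense -> ReLU -> batch normalization -> single
linear output. Training minimizes squared error with early stopping on a
held-out validation split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-5


@dataclass
class CNNSpec:
    """Hyper-parameters of the 1D-CNN regressor."""

    filters: int = 16
    kernel: int = 20
    stride: int = 5
    pool: str = "max"  # min | mean | max
    pool_size: int = 2
    dropout: float = 0.2
    dense: int = 64
    batch_norm: bool = True
    patience: int = 10
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-2
    validation_fraction: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.pool not in ("min", "mean", "max"):
            raise ValueError(f"unknown pooling {self.pool!r}")


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr, self.b1, self.b2, self.t = lr, 0.9, 0.999, 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + 1e-8)


class CNNRegressor:
    """Seeded 1D-CNN regressor over a marker matrix.

    Inputs are standardized per marker and the response is standardized
    internally; predictions are returned on the original scale. Training
    raises on a NaN loss with a diagnostic message.
    """

    def __init__(self, spec: CNNSpec | None = None, seed: int = 0):
        self.spec = spec or CNNSpec()
        self.seed = seed
        self.params: dict | None = None
        self.history: list[tuple[float, float]] = []  # (train, val) loss

    # -- layer plumbing -----------------------------------------------------

    def _init_params(self, m: int, rng):
        s = self.spec
        if s.kernel > m:
            raise ValueError(f"kernel {s.kernel} exceeds input length {m}")
        L = (m - s.kernel) // s.stride + 1
        Lp = max(L // s.pool_size, 1)
        flat = Lp * s.filters
        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        self._L, self._Lp, self._flat = L, Lp, flat
        self._cols = (
            np.arange(L)[:, None] * s.stride + np.arange(s.kernel)[None, :]
        )
        self.params = {
            "Wc": he((s.kernel, s.filters), s.kernel),
            "bc": np.zeros(s.filters),
            "Wd": he((flat, s.dense), flat),
            "bd": np.zeros(s.dense),
            "gamma": np.ones(s.dense),
            "beta": np.zeros(s.dense),
            "Wo": rng.normal(0.0, 0.01, size=s.dense),
            "bo": np.zeros(1),
        }
        self._run_mean = np.zeros(s.dense)
        self._run_var = np.ones(s.dense)

    def _forward(self, X, train: bool, rng=None):
        s, P = self.spec, self.params
        cache = {}
        Xc = X[:, self._cols]                       # (B, L, k)
        H1 = Xc @ P["Wc"] + P["bc"]                 # (B, L, F)
        A1 = np.maximum(H1, 0.0)
        B = X.shape[0]
        Ltrim = self._Lp * s.pool_size
        A1w = A1[:, :Ltrim].reshape(B, self._Lp, s.pool_size, s.filters)
        if s.pool == "mean":
            Pld = A1w.mean(axis=2)
        else:
            op = np.argmax if s.pool == "max" else np.argmin
            idx = op(A1w, axis=2)
            Pld = np.take_along_axis(A1w, idx[:, :, None, :], axis=2)[:, :, 0, :]
            cache["pool_idx"] = idx
        flat = Pld.reshape(B, self._flat)
        if train and s.dropout > 0:
            mask = (rng.random(flat.shape) >= s.dropout) / (1.0 - s.dropout)
            flat = flat * mask
            cache["drop_mask"] = mask
        H2 = flat @ P["Wd"] + P["bd"]
        A2 = np.maximum(H2, 0.0)
        if s.batch_norm:
            if train:
                mu = A2.mean(axis=0)
                var = A2.var(axis=0)
                self._run_mean = 0.9 * self._run_mean + 0.1 * mu
                self._run_var = 0.9 * self._run_var + 0.1 * var
            else:
                mu, var = self._run_mean, self._run_var
            xhat = (A2 - mu) / np.sqrt(var + _EPS)
            Z = P["gamma"] * xhat + P["beta"]
            cache.update(bn_xhat=xhat, bn_var=var)
        else:
            Z = A2
        yhat = Z @ P["Wo"] + P["bo"][0]
        cache.update(Xc=Xc, H1=H1, A1w=A1w, flat=flat, H2=H2, A2=A2, Z=Z)
        return yhat, cache

    def _backward(self, X, dy, cache):
        s, P = self.spec, self.params
        B = X.shape[0]
        g = {}
        Z = cache["Z"]
        g["Wo"] = Z.T @ dy
        g["bo"] = np.array([dy.sum()])
        dZ = np.outer(dy, P["Wo"])
        if s.batch_norm:
            xhat, var = cache["bn_xhat"], cache["bn_var"]
            g["gamma"] = (dZ * xhat).sum(axis=0)
            g["beta"] = dZ.sum(axis=0)
            inv = 1.0 / np.sqrt(var + _EPS)
            dA2 = (P["gamma"] * inv / B) * (
                B * dZ - dZ.sum(axis=0) - xhat * (dZ * xhat).sum(axis=0)
            )
        else:
            g["gamma"] = np.zeros_like(P["gamma"])
            g["beta"] = np.zeros_like(P["beta"])
            dA2 = dZ
        dH2 = dA2 * (cache["H2"] > 0)
        g["Wd"] = cache["flat"].T @ dH2
        g["bd"] = dH2.sum(axis=0)
        dflat = dH2 @ P["Wd"].T
        if "drop_mask" in cache:
            dflat = dflat * cache["drop_mask"]
        dP = dflat.reshape(B, self._Lp, s.filters)
        dA1w = np.zeros_like(cache["A1w"])
        if s.pool == "mean":
            dA1w += dP[:, :, None, :] / s.pool_size
        else:
            np.put_along_axis(
                dA1w, cache["pool_idx"][:, :, None, :], dP[:, :, None, :], axis=2
            )
        dA1 = np.zeros((B, self._L, s.filters))
        Ltrim = self._Lp * s.pool_size
        dA1[:, :Ltrim] = dA1w.reshape(B, Ltrim, s.filters)
        dH1 = dA1 * (cache["H1"] > 0)
        g["Wc"] = np.einsum("blk,blf->kf", cache["Xc"], dH1)
        g["bc"] = dH1.sum(axis=(0, 1))
        return g

    # -- public API ----------------------------------------------------------

    def fit(self, Z: np.ndarray, y: np.ndarray) -> "CNNRegressor":
        s = self.spec
        rng = np.random.default_rng(self.seed)
        Z = np.asarray(Z, float)
        y = np.asarray(y, float).ravel()
        self._x_mean = Z.mean(axis=0)
        self._x_sd = np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
        X = (Z - self._x_mean) / self._x_sd
        self._y_mean, self._y_sd = y.mean(), y.std() or 1.0
        t = (y - self._y_mean) / self._y_sd
        self._init_params(X.shape[1], rng)

        n = X.shape[0]
        n_val = max(int(round(s.validation_fraction * n)), 1)
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ttr, Xval, tval = X[tr_idx], t[tr_idx], X[val_idx], t[val_idx]

        opt = _Adam(self.params, s.learning_rate)
        best_val, best_params, wait = np.inf, None, 0
        for epoch in range(s.epochs):
            order = rng.permutation(len(Xtr))
            tr_loss = 0.0
            for start in range(0, len(Xtr), s.batch_size):
                b = order[start : start + s.batch_size]
                if len(b) < 2:
                    continue  # batch-norm needs >= 2 samples
                yhat, cache = self._forward(Xtr[b], train=True, rng=rng)
                err = yhat - ttr[b]
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"loss diverged at epoch {epoch} (lr={s.learning_rate})"
                    )
                tr_loss += loss * len(b)
                grads = self._backward(Xtr[b], 2.0 * err / len(b), cache)
                opt.step(self.params, grads)
            val_pred, _ = self._forward(Xval, train=False)
            val_loss = float(np.mean((val_pred - tval) ** 2))
            self.history.append((tr_loss / max(len(Xtr), 1), val_loss))
            if val_loss < best_val - 1e-6:
                best_val, wait = val_loss, 0
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_run = (self._run_mean.copy(), self._run_var.copy())
            else:
                wait += 1
                if wait >= s.patience:
                    break
        if best_params is not None:
            self.params = best_params
            self._run_mean, self._run_var = best_run
        return self

    def predict(self, Z: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        X = (np.asarray(Z, float) - self._x_mean) / self._x_sd
        yhat, _ = self._forward(X, train=False)
        return self._y_mean + self._y_sd * yhat
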