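"""A small 1-D convolutional network for spectral regression, in pure numpy.

Architecture (fixed): Conv(8 kernels, size 3, same padding) -> ReLU ->
MaxPool(2,2) -> Conv(8, 3, same) -> ReLU -> MaxPool(2,2) -> Dropout ->
Flatten -> Dense(fc_width) -> ReLU -> Dense(1).  Training minimizes
MSE + l2_lambda * sum(weights^2) with Adam, multiplies the learning rate by
``lr_decay_factor`` when the internal-validation loss plateaus, and stops
early when that loss fails to improve for ``early_stop_patience`` epochs
(best weights are restored).  Inputs and targets are standardized with
training statistics; predictions are returned on the original scale.

Everything is driven by one seeded Generator, so a (data, config, seed)
triple reproduces the fitted model bit-for-bit in a single-threaded run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["CNNConfig", "CNN1DRegressor", "cnn_parameter_count"]


@dataclass
class CNNConfig:
    n_kernels: int = 8
    kernel_size: int = 3
    conv_padding: str = "same"         # "same" (zero-padded) or "valid"
    pool_size: int = 2
    pool_stride: int = 1               # overlapping max-pool keeps short
                                       # spectral sequences informative
    fc_width: int = 32
    dropout: float = 0.5
    l2_lambda: float = 0.001
    batch_size: int = 32
    learning_rate: float = 0.001
    lr_decay_factor: float = 0.1
    lr_patience: int = 20
    min_lr: float = 1e-5
    val_smoothing: int = 9             # epochs in the validation moving average
    max_iterations: int = 500          # training epochs
    early_stop_patience: int = 150
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same padding)")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size >= 1 and learning_rate > 0 required")
        if not (0.0 < self.lr_decay_factor <= 1.0):
            raise ValueError("lr_decay_factor must lie in (0, 1]")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


def _pooled_len(L: int, size: int, stride: int) -> int:
    return (L - size) // stride + 1


def _layer_lengths(p: int, cfg: CNNConfig) -> tuple:
    """(conv1, pool1, conv2, pool2) sequence lengths for input length p."""
    pad = cfg.kernel_size // 2 if cfg.conv_padding == "same" else 0
    c1 = p + 2 * pad - cfg.kernel_size + 1
    p1 = _pooled_len(c1, cfg.pool_size, cfg.pool_stride) if c1 >= cfg.pool_size else 0
    c2 = p1 + 2 * pad - cfg.kernel_size + 1 if p1 else 0
    p2 = _pooled_len(c2, cfg.pool_size, cfg.pool_stride) if c2 >= cfg.pool_size else 0
    return c1, p1, c2, p2


def cnn_parameter_count(p: int, cfg: CNNConfig) -> int:
    """Closed-form trainable-parameter count for input length p."""
    f, k = cfg.n_kernels, cfg.kernel_size
    flat = f * _layer_lengths(p, cfg)[3]
    return (f * k + f) + (f * f * k + f) + (flat * cfg.fc_width + cfg.fc_width) \
        + (cfg.fc_width + 1)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, L) -> (B, L_out, C*k) patches; pad = k//2 gives 'same'."""
    B, C, L = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    return windows.transpose(0, 2, 1, 3).reshape(B, L + 2 * pad - k + 1, C * k)


class CNN1DRegressor:
    """Fit/predict wrapper around the fixed two-conv-layer architecture."""

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        self.params = None
        self.history = {"epoch": [], "train_rmse": [], "val_rmse": [], "lr": []}
        self._scaler = None

    # -- parameter plumbing -------------------------------------------------
    def _init_params(self, p: int, rng: np.random.Generator) -> dict:
        cfg = self.config
        L2 = _layer_lengths(p, cfg)[3]
        if L2 < 1:
            raise ValueError(
                f"input length {p} too short for two conv + max-pooling stages "
                f"(padding {cfg.conv_padding}, pool size {cfg.pool_size}, "
                f"stride {cfg.pool_stride})")
        f, k = cfg.n_kernels, cfg.kernel_size
        flat = f * L2

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        return {
            "W1": he((f, 1 * k), 1 * k), "b1": np.zeros(f),
            "W2": he((f, f * k), f * k), "b2": np.zeros(f),
            "W3": he((cfg.fc_width, flat), flat), "b3": np.zeros(cfg.fc_width),
            "W4": he((1, cfg.fc_width), cfg.fc_width), "b4": np.zeros(1),
        }

    # -- forward / backward -------------------------------------------------
    def _maxpool(self, a: np.ndarray):
        """Size/stride max-pool along axis 1 of (B, L, f)."""
        size, stride = self.config.pool_size, self.config.pool_stride
        L = a.shape[1]
        starts = np.arange(0, L - size + 1, stride)
        stack = np.stack([a[:, starts + o, :] for o in range(size)], axis=2)
        arg = stack.argmax(axis=2)                           # (B, L_out, f)
        return stack.max(axis=2), arg, starts

    def _unpool(self, d: np.ndarray, arg: np.ndarray, starts: np.ndarray,
                L: int) -> np.ndarray:
        B, L_out, f = d.shape
        out = np.zeros((B, L, f))
        bi, li, fi = np.meshgrid(np.arange(B), np.arange(L_out), np.arange(f),
                                 indexing="ij")
        np.add.at(out, (bi, starts[li] + arg, fi), d)
        return out

    def _forward(self, X: np.ndarray, dropout_mask=None):
        """X: (B, p) standardized.  Returns (prediction (B,), cache)."""
        P = self.params
        k = self.config.kernel_size
        pad = k // 2 if self.config.conv_padding == "same" else 0
        x0 = X[:, None, :]                                   # (B, 1, p)
        c1_in = _im2col(x0, k, pad)                          # (B, c1, k)
        z1 = c1_in @ P["W1"].T + P["b1"]                     # (B, c1, f)
        a1 = np.maximum(z1, 0.0)
        B = a1.shape[0]
        p1, arg1, starts1 = self._maxpool(a1)                # (B, L1, f)

        c2_in = _im2col(p1.transpose(0, 2, 1), k, pad)       # (B, c2, f*k)
        z2 = c2_in @ P["W2"].T + P["b2"]
        a2 = np.maximum(z2, 0.0)
        p2, arg2, starts2 = self._maxpool(a2)

        flat = p2.reshape(B, -1)
        if dropout_mask is not None:
            flat = flat * dropout_mask
        z3 = flat @ P["W3"].T + P["b3"]
        a3 = np.maximum(z3, 0.0)
        out = (a3 @ P["W4"].T + P["b4"]).ravel()
        cache = (x0, c1_in, z1, arg1, starts1, p1, c2_in, z2, arg2, starts2,
                 p2, flat, dropout_mask, z3, a3)
        return out, cache

    def _backward(self, dout: np.ndarray, cache) -> dict:
        P = self.params
        k = self.config.kernel_size
        (x0, c1_in, z1, arg1, starts1, p1, c2_in, z2, arg2, starts2,
         p2, flat, dropout_mask, z3, a3) = cache
        B = len(dout)
        f = self.config.n_kernels

        g = {}
        d = dout[:, None]                                    # (B, 1)
        g["W4"] = d.T @ a3
        g["b4"] = d.sum(axis=0)
        da3 = d @ P["W4"]
        dz3 = da3 * (z3 > 0)
        g["W3"] = dz3.T @ flat
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ P["W3"]
        if dropout_mask is not None:
            dflat = dflat * dropout_mask
        dp2 = dflat.reshape(p2.shape)                        # (B, L2out, f)

        da2 = self._unpool(dp2, arg2, starts2, z2.shape[1])
        dz2 = da2 * (z2 > 0)                                 # (B, L2, f)
        g["W2"] = np.einsum("blf,blk->fk", dz2, c2_in)
        g["b2"] = dz2.sum(axis=(0, 1))
        dc2_in = dz2 @ P["W2"]                               # (B, c2, f*k)
        pad = k // 2 if self.config.conv_padding == "same" else 0
        dp1 = self._col2im(dc2_in, B, f, p1.shape[1], k, pad).transpose(0, 2, 1)

        da1 = self._unpool(dp1, arg1, starts1, z1.shape[1])
        dz1 = da1 * (z1 > 0)
        g["W1"] = np.einsum("blf,blk->fk", dz1, c1_in)
        g["b1"] = dz1.sum(axis=(0, 1))
        return g

    @staticmethod
    def _col2im(dcols: np.ndarray, B: int, C: int, L_in: int, k: int,
                pad: int) -> np.ndarray:
        """Adjoint of _im2col: (B, L_out, C*k) -> (B, C, L_in)."""
        L_out = L_in + 2 * pad - k + 1
        dx = np.zeros((B, C, L_in + 2 * pad))
        d4 = dcols.reshape(B, L_out, C, k)
        for j in range(k):
            dx[:, :, j:j + L_out] += d4[:, :, :, j].transpose(0, 2, 1)
        return dx[:, :, pad:pad + L_in]

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray,
            validation: tuple | None = None) -> "CNN1DRegressor":
        """Train on (X, y).  ``validation`` overrides the internal seeded
        20 % validation split (pass (X_val, y_val))."""
        cfg = self.config
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        rng = np.random.default_rng(cfg.seed)

        xm, xs = X.mean(axis=0), X.std(axis=0)
        xs[xs == 0] = 1.0
        ym, ys = y.mean(), y.std() or 1.0
        self._scaler = (xm, xs, ym, ys)
        Xs = (X - xm) / xs
        ysc = (y - ym) / ys

        if validation is not None:
            Xtr, ytr = Xs, ysc
            Xval = (np.asarray(validation[0], float) - xm) / xs
            yval = (np.asarray(validation[1], float) - ym) / ys
        elif cfg.validation_fraction > 0 and len(y) >= 10:
            n_val = max(1, int(round(cfg.validation_fraction * len(y))))
            perm = rng.permutation(len(y))
            vi, ti = perm[:n_val], perm[n_val:]
            Xtr, ytr, Xval, yval = Xs[ti], ysc[ti], Xs[vi], ysc[vi]
        else:
            Xtr, ytr, Xval, yval = Xs, ysc, None, None

        self.params = self._init_params(X.shape[1], rng)
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        t_step = 0
        lr = cfg.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        best_loss, best_params, since_best, since_decay = np.inf, None, 0, 0
        val_window: list = []
        n = len(ytr)
        bs = min(cfg.batch_size, n)
        for epoch in range(cfg.max_iterations):
            perm = rng.permutation(n)
            sq_sum, cnt = 0.0, 0
            for s in range(0, n, bs):
                idx = perm[s:s + bs]
                mask = None
                if cfg.dropout > 0:
                    keep = 1.0 - cfg.dropout
                    flat_dim = self.params["W3"].shape[1]
                    mask = (rng.random((len(idx), flat_dim)) < keep) / keep
                pred, cache = self._forward(Xtr[idx], dropout_mask=mask)
                err = pred - ytr[idx]
                sq_sum += float(err @ err)
                cnt += len(idx)
                dout = 2.0 * err / len(idx)
                grads = self._backward(dout, cache)
                t_step += 1
                for key in self.params:
                    gk = grads[key]
                    adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * gk
                    adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * gk ** 2
                    mhat = adam_m[key] / (1 - beta1 ** t_step)
                    vhat = adam_v[key] / (1 - beta2 ** t_step)
                    step = mhat / (np.sqrt(vhat) + eps)
                    if key.startswith("W") and cfg.l2_lambda > 0:
                        # decoupled weight decay: the L2 term is applied
                        # outside Adam's adaptive scaling
                        step = step + 2.0 * cfg.l2_lambda * self.params[key]
                    self.params[key] -= lr * step
            train_rmse = float(np.sqrt(sq_sum / cnt))
            if not np.isfinite(train_rmse):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={lr}, l2={cfg.l2_lambda}, batch={bs}")
            if Xval is not None and len(yval):
                vp, _ = self._forward(Xval)
                val_rmse = float(np.sqrt(np.mean((vp - yval) ** 2)))
            else:
                val_rmse = train_rmse
            self.history["epoch"].append(epoch)
            self.history["train_rmse"].append(train_rmse)
            self.history["val_rmse"].append(val_rmse)
            self.history["lr"].append(lr)

            # early-stop decisions track a short moving average of the
            # validation loss; a tiny validation fold is too noisy raw
            val_window.append(val_rmse)
            if len(val_window) > max(1, cfg.val_smoothing):
                val_window.pop(0)
            val_smooth = float(np.mean(val_window))
            if val_smooth < best_loss - 1e-6:
                best_loss = val_smooth
                best_params = {k: v.copy() for k, v in self.params.items()}
                since_best = since_decay = 0
            else:
                since_best += 1
                since_decay += 1
                if (cfg.lr_decay_factor < 1.0 and since_decay >= cfg.lr_patience
                        and lr > cfg.min_lr):
                    lr = max(lr * cfg.lr_decay_factor, cfg.min_lr)
                    since_decay = 0
                if cfg.early_stop_patience and since_best >= cfg.early_stop_patience:
                    break
        if best_params is not None:
            self.params = best_params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        xm, xs, ym, ys = self._scaler
        Xs = (np.asarray(X, float) - xm) / xs
        if Xs.shape[1] != len(xm):
            raise ValueError("feature dimension mismatch")
        out = np.empty(len(Xs))
        for s in range(0, len(Xs), 4096):
            out[s:s + 4096], _ = self._forward(Xs[s:s + 4096])
        return out * ys + ym

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))
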