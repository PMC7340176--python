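"""Dual-channel 1-D convolutional severity regressor.

The network follows the classic five-convolution / three-fully-connected
AlexNet outline, adapted to one-dimensional pulse waveforms: the brachial
and ankle pressure waveforms are stacked as two rows of a (2, L) input and
convolved *independently* by shared height-1 kernels (the rows are folded
into the batch axis for the convolutional stack, which realises exactly
the shared-kernel, row-independent convolution).  Each conv block is
convolution -> batch normalisation -> LeakyReLU, with stride-2 max pooling
after blocks 1, 2 and 5 and a global average pool after block 5.  The
flattened latent vector has 32 channels x 2 rows = 64 features, matching
the 64-wide fully connected layers; the output head is linear and predicts
the scalar PAD severity.

Everything here — forward, backward, Adam, batch norm — is implemented in
NumPy so training is deterministic bit-for-bit given a seed, and gradients
with respect to intermediate activations (needed for Grad-CAM) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "SeverityRegressor",
    "build_model",
    "train",
    "predict_severity",
    "classify",
    "hyperparameter_sensitivity",
]

SEVERITY_MAX = 0.8


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description; the default realises the 5+3 layer plan."""

    input_len: int = 256
    kernel_counts: tuple[int, ...] = (16, 32, 32, 64, 32)
    kernel_sizes: tuple[int, ...] = (11, 7, 5, 3, 3)
    pool_after: tuple[int, ...] = (1, 2, 5)  # 1-based conv indices
    leaky_slope: float = 0.01
    batch_norm: bool = True
    fc_width: int = 64
    n_rows: int = 2  # brachial + ankle

    @property
    def n_conv_layers(self) -> int:
        return len(self.kernel_counts)

    @property
    def n_fc_layers(self) -> int:
        return 3

    @property
    def latent_dim(self) -> int:
        return self.kernel_counts[-1] * self.n_rows

    def validate(self) -> None:
        if len(self.kernel_counts) != 5 or len(self.kernel_sizes) != 5:
            raise ValueError("the architecture uses exactly five convolution layers")
        if self.leaky_slope <= 0:
            raise ValueError("LeakyReLU slope must be positive")
        if self.latent_dim != self.fc_width:
            raise ValueError(
                f"latent feature count {self.latent_dim} must equal the fully "
                f"connected width {self.fc_width}"
            )
        if any(k < 1 for k in self.kernel_sizes) or any(c < 1 for c in self.kernel_counts):
            raise ValueError("kernel sizes and counts must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 300
    patience: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


# ---------------------------------------------------------------------------
# layers


class _Conv1d:
    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k))
        self.b = np.zeros(out_ch)
        self.k = k
        self.pad_l = (k - 1) // 2
        self.pad_r = k - 1 - self.pad_l

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        self._cols = cols  # (B, C, L, k)
        return np.einsum("bclk,fck->bfl", cols, self.w, optimize=True) + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = np.einsum("bfl,bclk->fck", dy, self._cols, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        dcols = np.einsum("bfl,fck->bclk", dy, self.w, optimize=True)
        B, C, L, k = dcols.shape
        dxp = np.zeros((B, C, L + k - 1))
        for j in range(k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j]
        return dxp[:, :, self.pad_l : self.pad_l + L]

    def params(self):
        return [("w", self), ("b", self)]


class _BatchNorm1d:
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.w = np.ones(ch)
        self.b = np.zeros(ch)
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None]) * self._inv_std[:, None]
        self._train_batch = x.shape[0] * x.shape[2] if train else None
        return self.w[:, None] * self._xhat + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = (dy * self._xhat).sum(axis=(0, 2))
        self.db = dy.sum(axis=(0, 2))
        dxhat = dy * self.w[:, None]
        if self._train_batch is None:  # eval mode: affine only
            return dxhat * self._inv_std[:, None]
        n = self._train_batch
        return (
            self._inv_std[:, None]
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 2), keepdims=True)
                - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
            )
        )

    def params(self):
        return [("w", self), ("b", self)]


class _LeakyReLU:
    def __init__(self, slope: float):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)

    def params(self):
        return []


class _MaxPool1d:
    """Kernel-2, stride-2 max pooling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        x2 = x[:, :, : (L // 2) * 2].reshape(B, C, L // 2, 2)
        self._arg = x2.argmax(axis=3)
        self._in_shape = x.shape
        return x2.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, Lh = dy.shape
        dx = np.zeros(self._in_shape)
        dx2 = dx[:, :, : Lh * 2].reshape(B, C, Lh, 2)
        np.put_along_axis(dx2, self._arg[..., None], dy[..., None], axis=3)
        return dx

    def params(self):
        return []


class _GlobalAvgPool:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._len, axis=2) / self._len

    def params(self):
        return []


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.w

    def params(self):
        return [("w", self), ("b", self)]


# ---------------------------------------------------------------------------
# model


class SeverityRegressor:
    """The configured network plus its normalisation constants and history."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.conv_stack: list = []
        in_ch = 1
        for i, (count, size) in enumerate(
            zip(config.kernel_counts, config.kernel_sizes), start=1
        ):
            self.conv_stack.append(_Conv1d(in_ch, count, size, rng))
            if config.batch_norm:
                self.conv_stack.append(_BatchNorm1d(count))
            self.conv_stack.append(_LeakyReLU(config.leaky_slope))
            if i in config.pool_after:
                self.conv_stack.append(_MaxPool1d())
            in_ch = count
        self.gap = _GlobalAvgPool()
        self.fc_stack = [
            _Linear(config.latent_dim, config.fc_width, rng),
            _LeakyReLU(config.leaky_slope),
            _Linear(config.fc_width, config.fc_width, rng),
            _LeakyReLU(config.leaky_slope),
            _Linear(config.fc_width, 1, rng),
        ]
        # per-channel standardisation constants, set from the training set
        self.norm_mean = np.zeros(config.n_rows)
        self.norm_std = np.ones(config.n_rows)
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.provenance: dict = {}

    # -- introspection ------------------------------------------------------

    def describe(self) -> dict:
        return {
            "n_conv_layers": sum(isinstance(l, _Conv1d) for l in self.conv_stack),
            "n_fc_layers": sum(isinstance(l, _Linear) for l in self.fc_stack),
            "latent_dim": self.config.latent_dim,
            "n_parameters": sum(
                getattr(layer, name).size
                for layer in self.conv_stack + self.fc_stack
                for name, _ in layer.params()
            ),
        }

    def _all_params(self):
        for layer in self.conv_stack + self.fc_stack:
            for name, owner in layer.params():
                yield owner, name

    # -- forward / backward -------------------------------------------------

    def standardize(self, x: np.ndarray) -> np.ndarray:
        """(B, rows, L) -> z-scored with the stored training statistics."""
        return (x - self.norm_mean[:, None]) / self.norm_std[:, None]

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, R, L = x.shape
        h = x.reshape(B * R, 1, L)  # rows share kernels via the batch axis
        for layer in self.conv_stack:
            h = layer.forward(h, train)
        self._conv_maps = h  # (B*R, C, L'), last-conv activations for Grad-CAM
        z = self.gap.forward(h, train)
        z = z.reshape(B, R * z.shape[1])
        self._latents = z
        for layer in self.fc_stack:
            z = layer.forward(z, train)
        return z[:, 0]

    def _backward(self, dout: np.ndarray, to_conv_maps_only: bool = False):
        """Backprop d(scalar outputs)/d(everything); dout shape (B,)."""
        g = dout[:, None]
        for layer in reversed(self.fc_stack):
            g = layer.backward(g)
        B = g.shape[0]
        R = self.config.n_rows
        g = g.reshape(B * R, -1)
        g = self.gap.backward(g)
        if to_conv_maps_only:
            return g
        for layer in reversed(self.conv_stack):
            g = layer.backward(g)
        return g

    def predict(
        self, x: np.ndarray, standardized: bool = False, chunk: int = 256
    ) -> np.ndarray:
        """Severity estimates for a (B, rows, L) batch, clipped to [0, 0.8].

        Inference runs in fixed-size chunks to bound memory; batch
        composition does not affect per-sample outputs (batch norm uses its
        running statistics in evaluation mode).
        """
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.config.n_rows or x.shape[2] != self.config.input_len:
            raise ValueError(
                f"expected input shape (B, {self.config.n_rows}, "
                f"{self.config.input_len}), got {x.shape}"
            )
        if not standardized:
            x = self.standardize(x)
        out = [
            self._forward(x[i : i + chunk], train=False)
            for i in range(0, x.shape[0], chunk)
        ]
        return np.clip(np.concatenate(out), 0.0, SEVERITY_MAX)

    def latent_features(
        self, x: np.ndarray, standardized: bool = False, chunk: int = 256
    ) -> np.ndarray:
        """Flattened last-conv-layer features (B, latent_dim) after pooling."""
        x = np.asarray(x, dtype=float)
        if not standardized:
            x = self.standardize(x)
        out = []
        for i in range(0, x.shape[0], chunk):
            self._forward(x[i : i + chunk], train=False)
            out.append(self._latents.copy())
        return np.concatenate(out)


def preprocess_waveform(x: np.ndarray, target_len: int) -> np.ndarray:
    """Resample one period to the network input length (linear, periodic)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n == target_len:
        return x
    old_t = np.arange(n) / n
    new_t = np.arange(target_len) / target_len
    return np.interp(new_t, old_t, x, period=1.0)


def build_model(config: NetworkConfig | None = None, seed: int = 0) -> SeverityRegressor:
    """Construct the severity regressor; raises on invalid layer plans."""
    return SeverityRegressor(config or NetworkConfig(), seed=seed)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(o, n)) for o, n in self.params]
        self.v = [np.zeros_like(getattr(o, n)) for o, n in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (owner, name) in enumerate(self.params):
            g = getattr(owner, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            setattr(
                owner,
                name,
                getattr(owner, name) - self.lr * mhat / (np.sqrt(vhat) + self.eps),
            )


def _snapshot(model: SeverityRegressor) -> list[np.ndarray]:
    return [getattr(o, n).copy() for o, n in model._all_params()] + [
        l.running_mean.copy() if isinstance(l, _BatchNorm1d) else None
        for l in model.conv_stack
    ] + [
        l.running_var.copy() if isinstance(l, _BatchNorm1d) else None
        for l in model.conv_stack
    ]


def _restore(model: SeverityRegressor, snap: list) -> None:
    params = list(model._all_params())
    for (owner, name), value in zip(params, snap[: len(params)]):
        setattr(owner, name, value.copy())
    n = len(params)
    bn_layers = model.conv_stack
    means = snap[n : n + len(bn_layers)]
    variances = snap[n + len(bn_layers) :]
    for layer, m, v in zip(bn_layers, means, variances):
        if isinstance(layer, _BatchNorm1d):
            layer.running_mean = m.copy()
            layer.running_var = v.copy()


def train(
    model: SeverityRegressor,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    tcfg: TrainingConfig | None = None,
) -> SeverityRegressor:
    """Fit the regressor with Adam on mean-squared error.

    ``train_data``/``val_data`` are (X, y) with X of shape (n, rows, L) in
    physical units; per-channel standardisation constants are computed from
    the training X and stored on the model.  Training is deterministic for
    a fixed seed.  The best-validation-loss parameters are restored at the
    end; raises on NaN loss with diagnostics.
    """
    tcfg = tcfg or TrainingConfig()
    tcfg.validate()
    x_train, y_train = train_data
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if np.any(y_train < 0) or np.any(y_train > SEVERITY_MAX + 1e-9):
        raise ValueError(f"severity labels must lie in [0, {SEVERITY_MAX}]")

    model.norm_mean = x_train.mean(axis=(0, 2))
    model.norm_std = x_train.std(axis=(0, 2))
    model.norm_std[model.norm_std == 0] = 1.0
    xs = model.standardize(x_train)
    if val_data is not None:
        xv = model.standardize(np.asarray(val_data[0], dtype=float))
        yv = np.asarray(val_data[1], dtype=float)

    opt = _Adam(model._all_params(), tcfg.learning_rate, tcfg.beta1, tcfg.beta2)
    rng = np.random.default_rng(tcfg.seed)
    n = xs.shape[0]
    best_val = np.inf
    best_snap = None
    stale = 0

    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = xs[idx], y_train[idx]
            pred = model._forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}, batch start {start}; "
                    f"lr={tcfg.learning_rate}, pred range "
                    f"[{np.nanmin(pred)}, {np.nanmax(pred)}]"
                )
            epoch_loss += loss * idx.size
            model._backward(2.0 * err / idx.size)
            opt.step()
        model.history["train_loss"].append(epoch_loss / n)

        if val_data is not None:
            val_pred = model._forward(xv, train=False)
            val_loss = float(np.mean((val_pred - yv) ** 2))
            model.history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_snap = _snapshot(model)
                stale = 0
            else:
                stale += 1
                if stale >= tcfg.patience:
                    break

    if best_snap is not None:
        _restore(model, best_snap)
    model.provenance["training_config"] = tcfg.__dict__.copy()
    model.provenance["n_train"] = int(n)
    return model


# ---------------------------------------------------------------------------
# prediction / classification helpers


def predict_severity(
    model: SeverityRegressor, brachial_bp: np.ndarray, ankle_bp: np.ndarray
) -> float:
    """Severity estimate for one sample from its two pressure waveforms."""
    L = model.config.input_len
    x = np.stack(
        [preprocess_waveform(brachial_bp, L), preprocess_waveform(ankle_bp, L)]
    )[None, ...]
    return float(model.predict(x)[0])


def classify(predictions, threshold: float) -> np.ndarray:
    """Boolean PAD labels: predicted severity >= threshold counts as PAD."""
    if not (0.0 < threshold < SEVERITY_MAX):
        raise ValueError(f"threshold must lie in (0, {SEVERITY_MAX})")
    return np.asarray(predictions, dtype=float) >= threshold


def dataset_to_arrays(dataset, input_len: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """(brachial BP, ankle BP) rows from a Dataset, plus severity labels."""
    b = dataset.brachial_bp()
    a = dataset.ankle_bp()
    if b.shape[1] != input_len:
        b = np.stack([preprocess_waveform(w, input_len) for w in b])
        a = np.stack([preprocess_waveform(w, input_len) for w in a])
    return np.stack([b, a], axis=1), dataset.labels.copy()


# ---------------------------------------------------------------------------
# hyper-parameter sensitivity


def hyperparameter_sensitivity(
    base_config: NetworkConfig,
    train_data,
    val_data,
    tcfg: TrainingConfig | None = None,
    perturbations: list[tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Retrain under local architecture perturbations and compare final cost.

    The default perturbation set scales the kernel counts by 1.5 and 2 and
    grows every kernel size by 1 and 2 samples; a zero-perturbation row is
    included as the reference.
    """
    if perturbations is None:
        perturbations = [
            ("none", 0),
            ("kernel_count_x", 1.5),
            ("kernel_count_x", 2.0),
            ("kernel_size_+", 1),
            ("kernel_size_+", 2),
        ]
    tcfg = tcfg or TrainingConfig()
    rows = []
    base_loss = None
    for kind, amount in perturbations:
        cfg = base_config
        if kind == "kernel_count_x":
            counts = tuple(int(round(c * amount)) for c in base_config.kernel_counts)
            cfg = replace(
                base_config,
                kernel_counts=counts,
                fc_width=counts[-1] * base_config.n_rows,
            )
        elif kind == "kernel_size_+":
            cfg = replace(
                base_config,
                kernel_sizes=tuple(k + int(amount) for k in base_config.kernel_sizes),
            )
        elif kind != "none":
            raise ValueError(f"unknown perturbation kind {kind!r}")
        model = build_model(cfg, seed=tcfg.seed)
        train(model, train_data, val_data, tcfg)
        final = model.history["val_loss"][-1] if model.history["val_loss"] else model.history["train_loss"][-1]
        if kind == "none":
            base_loss = final
        rows.append(dict(perturbation=kind, amount=amount, final_val_loss=final))
    df = pd.DataFrame(rows)
    if base_loss is None:
        base_loss = df.final_val_loss.iloc[0]
    df["relative_change"] = (df.final_val_loss - base_loss) / base_loss
    return df
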