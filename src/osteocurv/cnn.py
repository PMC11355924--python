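"""CNN regression from curvature-projection images to bone parameters.

A small convolutional network maps the 4-channel 2D curvature projection
of a trabecular cube to a vector of continuous targets (histomorphometric
parameters, plate/rod geometric parameters, or the nine orthotropic
stiffness constants). The architecture is the classic stack

    [conv(k x k, f_i) + ReLU + max-pool(p x p)] x 3
    -> flatten -> dense(+ReLU, dropout) ... -> linear outputs

trained with Adam on mean-squared error; targets are min-max normalized
to [0, 1] using statistics of the training split only.

The implementation is pure numpy (forward and backward passes written
out), which keeps training fully seeded and deterministic: two runs with
the same config produce identical loss histories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

__all__ = [
    "CNNConfig",
    "TABLE_CONFIGS",
    "TargetNormalizer",
    "minmax_normalize",
    "split_dataset",
    "build_model",
    "CNNRegressor",
    "train",
    "evaluate",
    "RegressionReport",
]


class ArchitectureError(ValueError):
    """Input resolution incompatible with the conv/pool stack."""


class TrainingError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of one regression model.

    ``hidden_widths`` are the fully connected widths before the linear
    output layer of ``n_outputs`` units; dropout applies to dense layers
    only.
    """

    kernel_size: int = 3
    pool_size: int = 2
    conv_filters: tuple[int, ...] = (8, 16, 32)
    hidden_widths: tuple[int, ...] = (128, 64)
    learning_rate: float = 1e-4
    n_epochs: int = 200
    dropout_rate: float = 0.3
    n_outputs: int = 6
    batch_size: int = 16
    seed: int = 0
    #: random dihedral (flip/rot90) augmentation of the input images during
    #: training; an exact symmetry of projection images for scalar targets
    augment: bool = True

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.conv_filters) or any(
                w <= 0 for w in self.hidden_widths):
            raise ValueError("filter counts and hidden widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_outputs <= 0:
            raise ValueError("n_outputs must be positive")


#: The three tuned model variants: histomorphometric (6 outputs),
#: geometric (8 outputs) and stiffness (9 outputs) target sets.
TABLE_CONFIGS = {
    "histomorphometric": CNNConfig(kernel_size=3, conv_filters=(8, 16, 32),
                                   n_epochs=200, dropout_rate=0.3, n_outputs=6),
    "geometric": CNNConfig(kernel_size=5, conv_filters=(16, 16, 64),
                           n_epochs=300, dropout_rate=0.4, n_outputs=8),
    "stiffness": CNNConfig(kernel_size=3, conv_filters=(16, 32, 64),
                           n_epochs=250, dropout_rate=0.5, n_outputs=9),
}


# ---------------------------------------------------------------------------
# normalization and splitting


@dataclass
class TargetNormalizer:
    """Per-target min-max normalization x' = (x - min) / (max - min).

    Fit on the training split only; the same (min, max) are reused for
    test data so no test statistics leak into training.
    """

    minima: np.ndarray | None = None
    maxima: np.ndarray | None = None
    names: tuple[str, ...] | None = None

    def fit(self, values: np.ndarray, names=None) -> "TargetNormalizer":
        values = np.asarray(values, dtype=float)
        self.minima = values.min(axis=0)
        self.maxima = values.max(axis=0)
        self.names = tuple(names) if names is not None else None
        flat = np.nonzero(self.maxima <= self.minima)[0]
        if len(flat):
            label = (self.names[flat[0]] if self.names
                     else f"target {flat[0]}")
            raise ValueError(f"target {label!r} is constant; cannot normalize")
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, float) - self.minima) / (self.maxima - self.minima)

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, float) * (self.maxima - self.minima) + self.minima


def minmax_normalize(values: np.ndarray, names=None):
    """One-shot fit+transform; returns (normalized, normalizer)."""
    norm = TargetNormalizer().fit(values, names)
    return norm.transform(values), norm


def split_dataset(n_samples: int, train_fraction: float = 0.8, seed: int = 0):
    """Random disjoint exhaustive train/test index split, reproducible for
    a fixed seed."""
    if n_samples < 5:
        raise ValueError("need at least 5 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_train = int(round(train_fraction * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# layers (NCHW)


class _Conv2D:
    def __init__(self, in_ch, out_ch, k, rng):
        fan_in, fan_out = in_ch * k * k, out_ch * k * k
        limit = np.sqrt(6.0 / (fan_in + fan_out))     # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.k = k
        self.params = [self.W, self.b]

    def forward(self, x, train):
        k = self.k
        if x.shape[2] < k or x.shape[3] < k:
            raise ArchitectureError("feature map smaller than kernel")
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,H',W',k,k
        n, c, h, w = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.W.reshape(len(self.W), -1).T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, f, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dW = (dflat.T @ self._cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        dcols = dflat @ self.W.reshape(f, -1)          # N*H'*W', C*k*k
        k = self.k
        _, c, H, W_ = self._xshape
        dx = np.zeros(self._xshape)
        dcols = dcols.reshape(n, h, w, c, k, k)
        for di in range(k):                            # scatter-add, k*k small
            for dj in range(k):
                dx[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self.grads = [self.dW, self.db]
        return dx


class _MaxPool:
    def __init__(self, p):
        self.p = p
        self.params = []

    def forward(self, x, train):
        p = self.p
        n, c, h, w = x.shape
        if h < p or w < p:
            raise ArchitectureError("feature map smaller than pooling window")
        hp, wp = h // p, w // p
        xc = x[:, :, :hp * p, :wp * p]
        blocks = xc.reshape(n, c, hp, p, wp, p)
        out = blocks.max(axis=(3, 5))
        self._mask = blocks == out[:, :, :, None, :, None]
        self._xshape, self._crop = x.shape, (hp * p, wp * p)
        return out

    def backward(self, dout):
        n, c, hp, wp = dout.shape
        p = self.p
        d = self._mask * dout[:, :, :, None, :, None]
        dx = np.zeros(self._xshape)
        dx[:, :, :self._crop[0], :self._crop[1]] = d.reshape(
            n, c, hp * p, wp * p)
        self.grads = []
        return dx


class _ReLU:
    params = []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        self.grads = []
        return dout * self._mask


class _Flatten:
    params = []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dout):
        self.grads = []
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in, n_out, rng):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self.grads = [self.dW, self.db]
        return dout @ self.W.T


class _Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng
        self.params = []

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        self.grads = []
        return dout if self._mask is None else dout * self._mask


class CNNRegressor:
    """Feed-forward conv net with a linear multi-output head."""

    def __init__(self, config: CNNConfig, input_resolution, n_channels: int = 4):
        self.config = config
        self.input_resolution = tuple(input_resolution)
        self.n_channels = n_channels
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

        h, w = self.input_resolution
        layers = []
        ch = n_channels
        for f in config.conv_filters:
            layers += [_Conv2D(ch, f, config.kernel_size, rng), _ReLU(),
                       _MaxPool(config.pool_size)]
            h = (h - config.kernel_size + 1) // config.pool_size
            w = (w - config.kernel_size + 1) // config.pool_size
            if h < 1 or w < 1:
                raise ArchitectureError(
                    "conv/pool stack reduces the input below 1x1; use a "
                    "larger input or fewer stages")
            ch = f
        layers.append(_Flatten())
        n_feat = ch * h * w
        for width in config.hidden_widths:
            layers += [_Dense(n_feat, width, rng), _ReLU(),
                       _Dropout(config.dropout_rate, self._dropout_rng)]
            n_feat = width
        layers.append(_Dense(n_feat, config.n_outputs, rng))
        self.layers = layers

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    predict = forward

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self):
        return [g for layer in self.layers if layer.params for g in layer.grads]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_model(config: CNNConfig, input_resolution, n_channels: int = 4) -> CNNRegressor:
    """Construct the (seeded) regressor for a given input size."""
    return CNNRegressor(config, input_resolution, n_channels)


def train(
    model: CNNRegressor,
    images: np.ndarray,
    targets: np.ndarray,
    config: CNNConfig | None = None,
) -> list[float]:
    """Minimize MSE with Adam for ``config.n_epochs``; returns the per-epoch
    mean training loss. Fully deterministic for a fixed config seed.

    ``targets`` must already be normalized (see :class:`TargetNormalizer`).
    """
    config = config or model.config
    x = np.asarray(images, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim != 4:
        raise ValueError("images must be (n, channels, height, width)")
    if len(x) != len(y):
        raise ValueError("images and targets disagree in length")
    opt = _Adam(model.parameters, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 2)
    history: list[float] = []
    n = len(x)
    square = x.shape[2] == x.shape[3]
    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            if config.augment:
                # random dihedral transform per sample: exact symmetry of a
                # projection image with respect to scalar targets
                xb = xb.copy()
                ks = rng.integers(0, 4 if square else 1, size=len(xb))
                flips = rng.integers(0, 2, size=len(xb))
                for b in range(len(xb)):
                    im = xb[b]
                    if ks[b]:
                        im = np.rot90(im, ks[b], axes=(1, 2))
                    if flips[b]:
                        im = im[:, ::-1, :]
                    xb[b] = im
            pred = model.forward(xb, train=True)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model.backward(2.0 * err / err.size)
            opt.step(model.gradients)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


@dataclass
class RegressionReport:
    """Per-target prediction quality on a held-out set. ``r2`` is the
    squared Pearson correlation of predicted vs true values; ``p_value``
    the two-sided significance of that correlation. Predictions and truth
    are in native units."""

    names: tuple[str, ...]
    r2: np.ndarray
    p_value: np.ndarray
    predicted: np.ndarray
    true: np.ndarray

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {name: {"r2": float(self.r2[i]), "p": float(self.p_value[i])}
                for i, name in enumerate(self.names)}


def evaluate(
    model: CNNRegressor,
    images: np.ndarray,
    targets_native: np.ndarray,
    normalizer: TargetNormalizer,
    names=None,
) -> RegressionReport:
    """Predict on a test set and score per-target squared Pearson
    correlation (with its two-sided p-value) in native units."""
    x = np.asarray(images, dtype=float)
    y = np.asarray(targets_native, dtype=float)
    if len(y) < 2:
        raise ValueError("correlation is undefined for fewer than 2 samples")
    pred = normalizer.inverse(model.forward(x, train=False))
    nt = y.shape[1]
    r2 = np.empty(nt)
    pv = np.empty(nt)
    for j in range(nt):
        if np.ptp(pred[:, j]) == 0 or np.ptp(y[:, j]) == 0:
            r2[j], pv[j] = 0.0, 1.0
            continue
        r, p = stats.pearsonr(pred[:, j], y[:, j])
        r2[j], pv[j] = r * r, p
    if names is None:
        names = (normalizer.names if normalizer.names
                 else tuple(f"target_{j}" for j in range(nt)))
    return RegressionReport(names=tuple(names), r2=r2, p_value=pv,
                            predicted=pred, true=y)
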