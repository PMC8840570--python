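"""A compact NumPy convolutional classifier over stacked GLCM channels.

Each sample is the stack of its normalized 32x32 co-occurrence matrices, one
channel per direction; a whole scale group contributes 3, 6 or 4 channels and
the all-13-direction stack is the single-scale comparator.  The network is
small and fixed:

    conv 3x3, 64 maps, stride 1 -> batch norm -> ReLU -> max-pool 2x2 stride 2
    conv 3x3, 64 maps, stride 1 -> batch norm -> ReLU -> max-pool 2x2 stride 2
    dense 1000 -> ReLU -> dense 1000 -> ReLU -> dense 2 -> softmax

trained with cross-entropy and Adam (initial learning rate 1e-3, multiplied
by 0.01 every 10 epochs, 40 epochs).  Group-level forward-stepwise
integration picks the best single group as baseline and adds remaining
groups, in descending order of their individual AUC, only when the mean
cross-validated AUC strictly improves.

The implementation is pure NumPy (im2col convolutions, explicit backprop);
all randomness flows from a single seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evalstats import SplitScheme, roc_auc

__all__ = [
    "CNNConfig",
    "SmallGLCMNet",
    "build_model",
    "train_cnn",
    "cnn_group_fsfs",
    "GroupFSFSResult",
]


@dataclass
class CNNConfig:
    """Architecture and training hyper-parameters."""

    input_size: int = 32
    conv_channels: int = 64
    dense_units: tuple[int, int] = (1000, 1000)
    n_classes: int = 2
    epochs: int = 40
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.01
    lr_decay_every: int = 10
    batch_size: int | None = None  # None = full training set
    weight_decay: float = 0.0

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index (stepwise multiplicative decay)."""
        return self.learning_rate * self.lr_decay_factor ** (epoch // self.lr_decay_every)


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, C*9, H*W) patches for a 3x3 same-padded convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((b, c, 9, h, w), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di : di + h, dj : dj + w]
            k += 1
    return cols.reshape(b, c * 9, h * w)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    b, c, h, w = shape
    dcols = dcols.reshape(b, c, 9, h, w)
    dxp = np.zeros((b, c, h + 2, w + 2), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, k]
            k += 1
    return dxp[:, :, 1:-1, 1:-1]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        self.cols = _im2col(x)  # (B, C*9, HW)
        b, _, hw = self.cols.shape
        h = w = int(np.sqrt(hw))
        out = np.einsum("of,bfp->bop", self.w, self.cols) + self.b[None, :, None]
        return out.reshape(b, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, co, h, w = dout.shape
        d = dout.reshape(b, co, h * w)
        self.grads[0][...] = np.einsum("bop,bfp->of", d, self.cols)
        self.grads[1][...] = d.sum(axis=(0, 2))
        dcols = np.einsum("of,bop->bfp", self.w, d)
        return _col2im(dcols, self.x_shape)


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self.std = np.sqrt(var + self.eps)[None, :, None, None]
        self.xhat = (x - mean[None, :, None, None]) / self.std
        return self.gamma[None, :, None, None] * self.xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads[0][...] = (dout * self.xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma[None, :, None, None]
        return (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self.xhat * (dxhat * self.xhat).mean(axis=axes, keepdims=True)
        ) / self.std


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class _MaxPool2:
    """2x2 max-pool, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        # ties share the gradient equally (counts divisor in backward)
        self.mask = xr == out[:, :, :, None, :, None]
        self.xr_shape = xr.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h2, _, w2, _ = self.xr_shape
        counts = self.mask.sum(axis=(3, 5), keepdims=True)
        dxr = self.mask * (dout[:, :, :, None, :, None] / counts)
        return dxr.reshape(b, c, h2 * 2, w2 * 2)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self.x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallGLCMNet:
    """The two-conv-block network over (B, C, S, S) GLCM stacks."""

    def __init__(self, c_in: int, config: CNNConfig | None = None, seed: int = 0):
        if c_in < 1:
            raise ValueError(f"channel count must be positive, got {c_in}")
        self.config = config or CNNConfig()
        self.c_in = c_in
        rng = np.random.default_rng(seed)
        cc = self.config.conv_channels
        s = self.config.input_size
        self.conv1 = _Conv3x3(c_in, cc, rng)
        self.bn1 = _BatchNorm(cc)
        self.relu1 = _ReLU()
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv3x3(cc, cc, rng)
        self.bn2 = _BatchNorm(cc)
        self.relu2 = _ReLU()
        self.pool2 = _MaxPool2()
        flat = cc * (s // 4) * (s // 4)
        d1, d2 = self.config.dense_units
        self.fc1 = _Dense(flat, d1, rng)
        self.relu3 = _ReLU()
        self.fc2 = _Dense(d1, d2, rng)
        self.relu4 = _ReLU()
        self.fc3 = _Dense(d2, self.config.n_classes, rng)
        self._param_layers = [
            self.conv1, self.bn1, self.conv2, self.bn2, self.fc1, self.fc2, self.fc3,
        ]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self._param_layers for p in layer.params)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for input of shape (B, C, S, S)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[1] != self.c_in:
            raise ValueError(
                f"expected (B, {self.c_in}, {self.config.input_size}, "
                f"{self.config.input_size}) input, got {x.shape}"
            )
        h = self.conv1.forward(x)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h)
        h = self.pool1.forward(h)
        h = self.conv2.forward(h)
        h = self.bn2.forward(h, train)
        h = self.relu2.forward(h)
        h = self.pool2.forward(h)
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.relu3.forward(self.fc1.forward(h))
        h = self.relu4.forward(self.fc2.forward(h))
        return self.fc3.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc3.backward(dlogits)
        d = self.fc2.backward(self.relu4.backward(d))
        d = self.fc1.backward(self.relu3.backward(d))
        d = d.reshape(self._flat_shape)
        d = self.pool2.backward(d)
        d = self.bn2.backward(self.relu2.backward(d))
        d = self.conv2.backward(d)
        d = self.pool1.backward(d)
        d = self.bn1.backward(self.relu1.backward(d))
        self.conv1.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x, train=False))


def build_model(c: int, config: CNNConfig | None = None, seed: int = 0) -> SmallGLCMNet:
    """Construct the network for ``c`` input GLCM channels."""
    return SmallGLCMNet(c_in=c, config=config, seed=seed)


class _Adam:
    def __init__(self, layers, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for l in layers for p in l.params]
        self.v = [np.zeros_like(p) for l in layers for p in l.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        k = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
                self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
                mhat = self.m[k] / (1 - self.beta1 ** self.t)
                vhat = self.v[k] / (1 - self.beta2 ** self.t)
                p -= lr * mhat / (np.sqrt(vhat) + self.eps)
                k += 1


def train_cnn(
    model: SmallGLCMNet,
    tensors: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig | None = None,
    seed: int = 0,
) -> list[float]:
    """Train with cross-entropy and Adam; returns the per-epoch loss trace.

    ``tensors`` has shape (N, C, S, S) and ``labels`` binary classes.  The
    seed controls batch shuffling only (weights were seeded at construction).
    Raises on a non-finite loss.
    """
    config = config or model.config
    x = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    n = x.shape[0]
    bs = config.batch_size or n
    rng = np.random.default_rng(seed)
    opt = _Adam(model._param_layers)
    trace: list[float] = []
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits = model.forward(x[idx], train=True)
            probs = _softmax(logits)
            eps = 1e-12
            loss = -np.log(probs[np.arange(idx.size), y[idx]] + eps).mean()
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            dlogits = probs.copy()
            dlogits[np.arange(idx.size), y[idx]] -= 1.0
            dlogits /= idx.size
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


@dataclass
class GroupFSFSResult:
    """Outcome of group-level forward-stepwise integration."""

    selected_groups: list[int]
    auc_trace: list[float]
    group_aucs: dict[int, float] = field(default_factory=dict)
    final_auc: float = float("nan")
    final_std: float = float("nan")


def _evaluate_stack(
    stack: np.ndarray,
    labels: np.ndarray,
    scheme: SplitScheme,
    config: CNNConfig,
    seed: int,
) -> tuple[float, float]:
    """Mean/STD test AUC of a channel stack over the scheme's splits."""
    y = np.asarray(labels)
    aucs = []
    for k, (train, test) in enumerate(scheme.splits):
        if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
            continue
        model = build_model(stack.shape[1], config, seed=seed + k)
        train_cnn(model, stack[train], y[train], config, seed=seed + k)
        probs = model.predict_proba(stack[test])[:, 1]
        aucs.append(roc_auc(probs, y[test]))
    if not aucs:
        raise ValueError("no usable splits in scheme")
    return float(np.mean(aucs)), float(np.std(aucs))


def cnn_group_fsfs(
    group_stacks: dict[int, np.ndarray],
    labels: np.ndarray,
    scheme: SplitScheme,
    config: CNNConfig | None = None,
    seed: int = 0,
) -> GroupFSFSResult:
    """Group-level forward-stepwise integration of GLCM channel stacks.

    Each group's stack (N, c_g, S, S) is first evaluated alone; the best one
    becomes the baseline, and the remaining groups are tried in descending
    order of their individual AUC, each kept only on strict improvement of
    the mean AUC.  Ties break toward the smaller group id.
    """
    config = config or CNNConfig()
    if not group_stacks:
        raise ValueError("need at least one group")
    gids = sorted(group_stacks)
    group_aucs = {
        g: _evaluate_stack(group_stacks[g], labels, scheme, config, seed)[0]
        for g in gids
    }
    order = sorted(gids, key=lambda g: (-group_aucs[g], g))
    baseline = [order[0]]
    best_auc = group_aucs[order[0]]
    best_std = _evaluate_stack(group_stacks[order[0]], labels, scheme, config, seed)[1]
    trace = [best_auc]
    for g in order[1:]:
        stack = np.concatenate([group_stacks[h] for h in baseline + [g]], axis=1)
        auc, std = _evaluate_stack(stack, labels, scheme, config, seed)
        if auc > best_auc:
            baseline.append(g)
            best_auc, best_std = auc, std
            trace.append(auc)
    return GroupFSFSResult(
        selected_groups=baseline,
        auc_trace=trace,
        group_aucs=group_aucs,
        final_auc=best_auc,
        final_std=best_std,
    )
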