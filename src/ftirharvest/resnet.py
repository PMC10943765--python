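"""A small residual convolutional network, implemented directly in NumPy.

The classifier consumes rendered correlation-spectroscopy images and
assigns them to harvest periods.  The architecture is a 14-weighted-layer
residual network: a stem convolution, three stages each holding one Conv
block (projection shortcut, used where the shape changes) and one Identity
block (plain shortcut), global average pooling, and a final linear
classification layer — 1 + 6 x 2 + 1 = 14 layers, channel widths
16/32/64 by default (projection shortcuts and batch-norm layers are not
counted in the depth, the usual convention).

Training is plain stochastic gradient descent with momentum, weight decay
on convolution/linear weights, and a softmax cross-entropy loss.  All
randomness (weight init, data split, batch order) flows from a single seed,
so a run is exactly reproducible.

Forward and backward passes are written against im2col matrix products;
on the image sizes used here (64-224 px) this trains a small dataset in
minutes on one CPU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

import pandas as pd

__all__ = ["ResNetConfig", "ResNetClassifier", "ResNetResults", "build_resnet14"]

DTYPE = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d:
    """3x3 (or 1x1) convolution, no bias (batch norm follows)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)).astype(DTYPE)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.dw = np.zeros_like(self.w)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.w.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, wd = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        out = col @ self.w.reshape(self.w.shape[0], -1).T
        if train:
            self._cache = (x.shape, col, ho, wo)
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, c, h, wd), col, ho, wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        c_out = self.w.shape[0]
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, c_out)
        self.dw = (dflat.T @ col).reshape(self.w.shape)
        dcol = (dflat @ self.w.reshape(c_out, -1)).reshape(n, ho, wo, c, k, k)
        dcol = dcol.transpose(0, 3, 1, 2, 4, 5)  # n, c, ho, wo, k, k
        dxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcol[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + wd]


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.run_mean = np.zeros(c, dtype=DTYPE)
        self.run_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_sd[None, :, None, None]
        if train:
            self._cache = (xhat, inv_sd)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_sd = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * inv_sd[None, :, None, None]
        return dx.astype(DTYPE)


class ReLU:
    n_params = 0

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T


# ---------------------------------------------------------------------------
# residual blocks
# ---------------------------------------------------------------------------

class _ResidualBlock:
    """Two 3x3 convolutions with a shortcut.

    projection=True gives the Conv block (1x1 projection shortcut, used when
    the output shape differs from the input); projection=False the Identity
    block (plain additive shortcut).
    """

    def __init__(self, c_in: int, c_out: int, stride: int, projection: bool,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.projection = projection
        if projection:
            self.proj = Conv2d(c_in, c_out, 1, stride, rng)
            self.proj_bn = BatchNorm2d(c_out)
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        sc = self.proj_bn.forward(self.proj.forward(x, train), train) if self.projection else x
        return self.relu_out.forward(out + sc, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dmain = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))
        ))
        if self.projection:
            dsc = self.proj.backward(self.proj_bn.backward(d))
        else:
            dsc = d
        return dmain + dsc

    def layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.projection:
            out += [self.proj, self.proj_bn]
        return out

    # weighted depth excludes BN and the projection shortcut
    weighted_layers = 2


class ResNet14:
    """The network graph; see module docstring for the layer budget."""

    def __init__(self, n_classes: int, in_channels: int = 3, width: int = 16,
                 seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(seed)
        self.stem = Conv2d(in_channels, width, 3, 1, rng)
        self.stem_bn = BatchNorm2d(width)
        self.stem_relu = ReLU()
        self.blocks = [
            _ResidualBlock(width, width, 1, True, rng),
            _ResidualBlock(width, width, 1, False, rng),
            _ResidualBlock(width, 2 * width, 2, True, rng),
            _ResidualBlock(2 * width, 2 * width, 1, False, rng),
            _ResidualBlock(2 * width, 4 * width, 2, True, rng),
            _ResidualBlock(4 * width, 4 * width, 1, False, rng),
        ]
        self.fc = Linear(4 * width, n_classes, rng)
        self.n_classes = n_classes
        self._pool_hw = None

    @property
    def weighted_depth(self) -> int:
        return 1 + sum(b.weighted_layers for b in self.blocks) + 1

    @property
    def n_params(self) -> int:
        total = self.stem.n_params + self.stem_bn.n_params + self.fc.n_params
        for b in self.blocks:
            total += sum(layer.n_params for layer in b.layers())
        return total

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train)
        for b in self.blocks:
            out = b.forward(out, train)
        self._pool_hw = out.shape[2] * out.shape[3]
        pooled = out.mean(axis=(2, 3))
        self._pool_shape = out.shape
        return self.fc.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.fc.backward(dlogits)
        n, c, h, w = self._pool_shape
        d = np.broadcast_to(
            dpooled[:, :, None, None] / self._pool_hw, (n, c, h, w)
        ).astype(DTYPE)
        for b in reversed(self.blocks):
            d = b.backward(d)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(d)))

    # -- parameter plumbing for the optimiser ---------------------------
    def param_groups(self):
        """Yield (layer, attr, decay) triples for every trainable tensor;
        weight decay applies to convolution/linear weights only."""
        yield self.stem, "w", True
        yield self.stem_bn, "gamma", False
        yield self.stem_bn, "beta", False
        for b in self.blocks:
            for layer in b.layers():
                if isinstance(layer, Conv2d):
                    yield layer, "w", True
                else:
                    yield layer, "gamma", False
                    yield layer, "beta", False
        yield self.fc, "w", True
        yield self.fc, "b", False


def build_resnet14(n_classes: int, in_channels: int = 3, width: int = 16,
                   seed: int = 0) -> ResNet14:
    """Construct the 14-weighted-layer residual network."""
    return ResNet14(n_classes, in_channels=in_channels, width=width, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class ResNetConfig:
    """Training settings: SGD with lr 0.01 and weight decay 1e-4, a
    stratified 60/30/10 train/test/external split, and a single seed
    controlling init, split and batch order."""

    lr: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    epochs: int = 60
    batch_size: int = 16
    split: tuple[float, float, float] = (0.60, 0.30, 0.10)
    width: int = 16
    seed: int = 0
    early_stop: bool = False  # stop once train and test accuracy reach 100%

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class ResNetResults:
    """Training curve and the held-out accuracies of the best model."""

    curve: pd.DataFrame = field(repr=False)
    best_epoch: int
    accuracy_train: float
    accuracy_test: float
    accuracy_external: float
    n_params: int
    model: ResNet14 = field(repr=False)

    def summary(self) -> str:
        return (
            f"ResNet-14 ({self.n_params} parameters), best epoch {self.best_epoch}\n"
            f"  accuracy: training {self.accuracy_train:.2f}%  "
            f"test {self.accuracy_test:.2f}%  "
            f"external {self.accuracy_external:.2f}%"
        )


def stratified_three_way_split(labels: np.ndarray, fractions, rng) -> tuple:
    """Seeded stratified split into train/test/external index arrays."""
    labels = np.asarray(labels)
    tr, te, ev = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_te = int(round(fractions[1] * n))
        n_tr = max(1, min(n_tr, n - 2))
        n_te = max(1, min(n_te, n - n_tr - 1))
        tr.extend(idx[:n_tr])
        te.extend(idx[n_tr:n_tr + n_te])
        ev.extend(idx[n_tr + n_te:])
    if not ev:
        raise ValueError("external split is empty; provide more samples per class")
    return np.sort(tr), np.sort(te), np.sort(ev)


def _softmax_ce(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(DTYPE)


class ResNetClassifier:
    """Model object: correlation-map images + labels in, trained residual
    CNN results out.

    ``images`` is (N, H, W, C) uint8/float (as returned by the image
    renderer) or (N, C, H, W) float; pixel values are scaled to [0, 1].
    """

    def __init__(self, images: np.ndarray, labels: np.ndarray,
                 config: ResNetConfig | None = None):
        x = np.asarray(images)
        if x.ndim != 4:
            raise ValueError("images must be a 4-D array")
        if x.shape[-1] in (1, 3) and x.shape[1] not in (1, 3):
            x = x.transpose(0, 3, 1, 2)
        x = x.astype(DTYPE)
        if x.max() > 1.5:
            x = x / 255.0
        self.x = x
        self.labels = np.asarray(labels)
        self.classes = np.unique(self.labels)
        if len(self.classes) < 2:
            raise ValueError("need at least two classes")
        self.y = np.searchsorted(self.classes, self.labels)
        self.config = config or ResNetConfig()

    def _accuracy(self, net: ResNet14, idx: np.ndarray, batch: int = 32) -> float:
        correct = 0
        for start in range(0, len(idx), batch):
            sel = idx[start:start + batch]
            logits = net.forward(self.x[sel], train=False)
            correct += int(np.sum(np.argmax(logits, axis=1) == self.y[sel]))
        return 100.0 * correct / len(idx)

    def fit(self) -> ResNetResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        tr, te, ev = stratified_three_way_split(self.y, cfg.split, rng)
        net = ResNet14(len(self.classes), in_channels=self.x.shape[1],
                       width=cfg.width, seed=cfg.seed)
        vel: dict[int, np.ndarray] = {}

        rows = []
        best = (-1.0, np.inf, -1, None)  # (test acc, loss, epoch, params)
        for epoch in range(1, cfg.epochs + 1):
            order = tr[rng.permutation(len(tr))]
            losses, n_correct = [], 0
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                logits = net.forward(self.x[sel], train=True)
                loss, dlogits = _softmax_ce(logits, self.y[sel])
                net.backward(dlogits)
                losses.append(loss)
                n_correct += int(np.sum(np.argmax(logits, axis=1) == self.y[sel]))
                for i, (layer, attr, decay) in enumerate(net.param_groups()):
                    g = getattr(layer, "d" + attr if attr in ("w", "b") else
                                {"gamma": "dgamma", "beta": "dbeta"}[attr])
                    w = getattr(layer, attr)
                    if decay and cfg.weight_decay:
                        g = g + cfg.weight_decay * w
                    v = vel.get(i)
                    v = g if v is None else cfg.momentum * v + g
                    vel[i] = v
                    setattr(layer, attr, (w - cfg.lr * v).astype(DTYPE))
            acc_train_batch = 100.0 * n_correct / len(order)
            acc_test = self._accuracy(net, te)
            mean_loss = float(np.mean(losses))
            rows.append({"epoch": epoch, "loss": mean_loss,
                         "accuracy_train": acc_train_batch, "accuracy_test": acc_test})
            if acc_test > best[0] or (acc_test == best[0] and mean_loss < best[1]):
                snapshot = copy.deepcopy(
                    [(getattr(l, a).copy()) for l, a, _ in net.param_groups()]
                )
                bn_state = copy.deepcopy(
                    [(l.run_mean.copy(), l.run_var.copy())
                     for l, a, _ in net.param_groups() if a == "gamma"]
                )
                best = (acc_test, mean_loss, epoch, (snapshot, bn_state))
            if cfg.early_stop and acc_train_batch >= 100.0 and acc_test >= 100.0:
                break

        # restore the best weights before the one-shot external validation
        snapshot, bn_state = best[3]
        for (layer, attr, _), w in zip(net.param_groups(), snapshot):
            setattr(layer, attr, w)
        bns = [l for l, a, _ in net.param_groups() if a == "gamma"]
        for layer, (rm, rv) in zip(bns, bn_state):
            layer.run_mean, layer.run_var = rm, rv

        return ResNetResults(
            curve=pd.DataFrame(rows),
            best_epoch=best[2],
            accuracy_train=self._accuracy(net, tr),
            accuracy_test=self._accuracy(net, te),
            accuracy_external=self._accuracy(net, ev),
            n_params=net.n_params,
            model=net,
        )
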