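"""Shallow residual CNN for 2DCOS image classification, in pure numpy.

The network is a compact ResNet: a 3x3 stem convolution, four stages of
three identity-shortcut residual blocks each (12 blocks total; every block
is conv3x3-BN-ReLU-conv3x3-BN plus the skip connection, then ReLU), stride-2
downsampling convolutions between stages, global average pooling and a
linear softmax head.  Default channel widths are (16, 32, 64, 128) at
128x128x3 input; both are configurable so the model can be trained
scaled-down on a single CPU.

Training is plain SGD with momentum 0.9, cross-entropy loss and L2 weight
decay on convolution/linear weights.  Convolutions are implemented as
im2col matrix products with hand-written backward passes; everything is
deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .chemometrics import ClassMetrics, class_metrics


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------

def _out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)


def col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d:
    def __init__(self, cin, cout, k=3, stride=1, pad=1, rng=None):
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.W = rng.normal(0, scale, (cout, cin, k, k))
        self.k, self.stride, self.pad = k, stride, pad
        self.dW = np.zeros_like(self.W)
        self.decay = True

    def forward(self, x, train=True):
        self._x_shape = x.shape
        self._cols = im2col(x, self.k, self.stride, self.pad)
        n = x.shape[0]
        oh = _out_size(x.shape[2], self.k, self.stride, self.pad)
        ow = _out_size(x.shape[3], self.k, self.stride, self.pad)
        out = self.W.reshape(self.W.shape[0], -1) @ self._cols
        return out.reshape(n, self.W.shape[0], oh, ow)

    def backward(self, dout):
        n, f, oh, ow = dout.shape
        dflat = dout.reshape(n, f, oh * ow)
        self.dW = np.einsum("nfo,nco->fc", dflat, self._cols).reshape(self.W.shape)
        dcols = np.einsum("fc,nfo->nco", self.W.reshape(f, -1), dflat)
        self._cols = None
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)

    def params(self):
        return [("W", self)]


class BatchNorm2d:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps
        self.decay = False

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        ) / self._std[None, :, None, None]
        self._xhat = None
        return dx


class ReLU:
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Linear:
    def __init__(self, fin, fout, rng=None):
        self.W = rng.normal(0, np.sqrt(2.0 / fin), (fin, fout))
        self.b = np.zeros(fout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.decay = True

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class ResidualBlock:
    """conv-BN-ReLU-conv-BN with identity shortcut, spatial-shape preserving."""

    def __init__(self, channels, rng):
        self.conv1 = Conv2d(channels, channels, rng=rng)
        self.bn1 = BatchNorm2d(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng)
        self.bn2 = BatchNorm2d(channels)
        self.relu_out = ReLU()

    def forward(self, x, train=True):
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        assert out.shape == x.shape, "residual branch must preserve shape"
        return self.relu_out.forward(out + x, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        db = self.bn2.backward(d)
        db = self.conv2.backward(db)
        db = self.relu1.backward(db)
        db = self.bn1.backward(db)
        db = self.conv1.backward(db)
        return db + d  # branch + skip

    def layers(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class ResNetConfig:
    n_residual_blocks: int = 12
    input_size: int = 128
    in_channels: int = 3
    channels: tuple[int, ...] = (16, 32, 64, 128)
    n_classes: int = 3
    initial_lr: float = 0.01
    momentum: float = 0.9
    l2_weight_decay: float = 1e-4
    max_epochs: int = 30
    batch_size: int = 16
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residual_blocks % len(self.channels) != 0:
            raise ValueError("blocks must spread evenly over the stages")
        if self.initial_lr <= 0 or self.l2_weight_decay < 0:
            raise ValueError("lr must be > 0 and weight decay >= 0")


class ResNet:
    """Shallow residual classifier over (N, C, H, W) image tensors."""

    def __init__(self, cfg: ResNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        blocks_per_stage = cfg.n_residual_blocks // len(cfg.channels)
        self.stem = [Conv2d(cfg.in_channels, cfg.channels[0], rng=rng),
                     BatchNorm2d(cfg.channels[0]), ReLU()]
        self.stages = []
        for s, width in enumerate(cfg.channels):
            stage = []
            if s > 0:  # stride-2 downsampling between stages
                stage += [
                    Conv2d(cfg.channels[s - 1], width, stride=2, rng=rng),
                    BatchNorm2d(width),
                    ReLU(),
                ]
            stage += [ResidualBlock(width, rng) for _ in range(blocks_per_stage)]
            self.stages.append(stage)
        self.head = Linear(cfg.channels[-1], cfg.n_classes, rng=rng)
        self._velocity = {}

    # -- forward / backward ------------------------------------------------
    def _iter_layers(self):
        for lay in self.stem:
            yield lay
        for stage in self.stages:
            yield from stage
        yield self.head

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Class probabilities (softmax) for a (N, C, H, W) batch."""
        for lay in self.stem:
            x = lay.forward(x, train)
        for stage in self.stages:
            for lay in stage:
                x = lay.forward(x, train)
        self._gap_shape = x.shape
        x = x.mean(axis=(2, 3))  # global average pooling
        logits = self.head.forward(x, train)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, y_idx: np.ndarray) -> None:
        n = y_idx.size
        dlogits = self._probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        d = self.head.backward(dlogits)
        _, c, h, w = self._gap_shape
        d = np.repeat(np.repeat(d[:, :, None, None], h, axis=2), w, axis=3) / (h * w)
        for stage in reversed(self.stages):
            for lay in reversed(stage):
                d = lay.backward(d)
        for lay in reversed(self.stem):
            d = lay.backward(d)

    # -- parameters --------------------------------------------------------
    def _param_grads(self):
        for lay in self._iter_layers():
            if isinstance(lay, ResidualBlock):
                subs = lay.layers()
            else:
                subs = [lay]
            for sub in subs:
                if isinstance(sub, Conv2d):
                    yield sub, "W", "dW", True
                elif isinstance(sub, Linear):
                    yield sub, "W", "dW", True
                    yield sub, "b", "db", False
                elif isinstance(sub, BatchNorm2d):
                    yield sub, "gamma", "dgamma", False
                    yield sub, "beta", "dbeta", False

    def num_params(self) -> int:
        return sum(getattr(o, p).size for o, p, _, _ in self._param_grads())

    def sgd_step(self, lr: float) -> None:
        wd = self.cfg.l2_weight_decay
        for i, (obj, pname, gname, decay) in enumerate(self._param_grads()):
            p = getattr(obj, pname)
            g = getattr(obj, gname) + (wd * p if decay else 0.0)
            v = self._velocity.get(i, np.zeros_like(p))
            v = self.cfg.momentum * v - lr * g
            self._velocity[i] = v
            setattr(obj, pname, p + v)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        preds = []
        for i in range(0, x.shape[0], batch_size):
            preds.append(np.argmax(self.forward(x[i : i + batch_size], train=False), axis=1))
        return np.concatenate(preds)


def build_model(cfg: ResNetConfig) -> ResNet:
    return ResNet(cfg)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainReport:
    """Per-epoch accuracies/losses plus optional external-validation metrics."""

    history: pd.DataFrame
    classes: np.ndarray
    external: ClassMetrics | None = None
    meta: dict = field(default_factory=dict)


def images_to_tensor(images) -> np.ndarray:
    """PIL images (or HxWx3 arrays) -> float tensor (N, 3, H, W) in [0, 1]."""
    arrs = [np.asarray(im, dtype=float) / 255.0 for im in images]
    x = np.stack(arrs)
    if x.ndim == 3:  # grayscale -> replicate channels
        x = np.repeat(x[:, None], 3, axis=1)
    else:
        x = x.transpose(0, 3, 1, 2)
    return x


def train(
    model: ResNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
) -> TrainReport:
    """SGD training with per-epoch logging and test-plateau early stopping."""
    cfg = model.cfg
    if x_train.shape[0] == 0 or x_test.shape[0] == 0:
        raise ValueError("empty split")
    classes = np.unique(np.concatenate([y_train, y_test]))
    idx_of = {c: i for i, c in enumerate(classes)}
    yt = np.array([idx_of[c] for c in y_train])
    ye = np.array([idx_of[c] for c in y_test])

    rng = np.random.default_rng(cfg.seed)
    rows = []
    best_acc, since_best = -1.0, 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(x_train.shape[0])
        losses = []
        for i in range(0, order.size, cfg.batch_size):
            b = order[i : i + cfg.batch_size]
            probs = model.forward(x_train[b], train=True)
            losses.append(-np.log(probs[np.arange(b.size), yt[b]] + 1e-12).mean())
            model.backward(yt[b])
            model.sgd_step(cfg.initial_lr)
        train_acc = float((model.predict(x_train) == yt).mean())
        test_acc = float((model.predict(x_test) == ye).mean())
        rows.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.mean(losses)),
                "train_acc": train_acc,
                "test_acc": test_acc,
            }
        )
        if test_acc > best_acc + 1e-12:
            best_acc, since_best = test_acc, 0
        else:
            since_best += 1
        if best_acc == 1.0 or since_best >= cfg.early_stop_patience:
            break

    return TrainReport(
        history=pd.DataFrame(rows),
        classes=classes,
        meta={"n_params": model.num_params()},
    )


def evaluate_external(model: ResNet, x_val: np.ndarray, y_val: np.ndarray, classes) -> ClassMetrics:
    """Classification metrics on a held-out set never used in training."""
    pred = np.asarray(classes)[model.predict(x_val)]
    return class_metrics(y_val, pred)
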