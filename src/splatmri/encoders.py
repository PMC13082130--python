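"""Dual-path motion encoder: nine per-score MLPs and a projection CNN.

The MLP path maps the z-scored k-space-center navigator of one stack to the
nine basis scores, one small fully connected network per score (three
linear layers, ReLU after the first two).  The CNN path maps the stack's
low-frequency projection image to all nine scores through six stride-2
convolution blocks (kernels 7,7,5,5,3,3; output channels 2,4,8,16,32,32;
each conv -> batch norm -> ReLU), global average pooling, and one linear
head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, custom_op
from .acquisition import NormalizationStats, fit_normalization  # re-export

__all__ = [
    "MLPEncoder",
    "CNNEncoder",
    "NormalizationStats",
    "fit_normalization",
    "mlp_forward",
    "cnn_forward",
]

CNN_KERNELS = (7, 7, 5, 5, 3, 3)
CNN_CHANNELS = (2, 4, 8, 16, 32, 32)
N_SCORES = 9


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / max(fan_in, 1))


class Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        self.w = Tensor(_he_init(rng, n_in, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2) -> Tensor:
    """'same'-style strided convolution: output H = ceil(H/stride)."""
    n, cin, h, wd = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError("channel mismatch")
    oh = -(-h // stride)
    ow = -(-wd // stride)
    ph = max((oh - 1) * stride + kh - h, 0)
    pw = max((ow - 1) * stride + kw - wd, 0)
    pt, pl = ph // 2, pw // 2
    xpad = np.pad(x.data, ((0, 0), (0, 0), (pt, ph - pt), (pl, pw - pl)))
    from numpy.lib.stride_tricks import sliding_window_view
    win = sliding_window_view(xpad, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win[:, :, :oh, :ow]
    out = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True) \
        + b.data[None, :, None, None]

    def backward(g):
        gw = np.einsum("nohw,nchwij->ocij", g, win, optimize=True)
        gb = g.sum(axis=(0, 2, 3))
        gxpad = np.zeros_like(xpad)
        for di in range(kh):
            for dj in range(kw):
                patch = np.einsum("nohw,oc->nchw", g, w.data[:, :, di, dj],
                                  optimize=True)
                gxpad[:, :, di:di + stride * oh:stride,
                      dj:dj + stride * ow:stride] += patch
        gx = gxpad[:, :, pt:pt + h, pl:pl + wd]
        return gx, gw, gb

    return custom_op([x, w, b], out, backward)


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels), requires_grad=True)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            norm = centered * ((var + self.eps) ** -0.5)
        else:
            rm = self.running_mean[None, :, None, None]
            rv = self.running_var[None, :, None, None]
            norm = (x - rm) * Tensor(1.0 / np.sqrt(rv + self.eps))
        return norm * self.gamma.reshape(1, -1, 1, 1) \
            + self.beta.reshape(1, -1, 1, 1)

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"gamma": self.gamma.data.copy(), "beta": self.beta.data.copy(),
                "running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def load_state(self, st):
        self.gamma.data[...] = st["gamma"]
        self.beta.data[...] = st["beta"]
        self.running_mean[...] = st["running_mean"]
        self.running_var[...] = st["running_var"]


class MLPEncoder:
    """Nine independent 3-layer MLPs, one scalar score each.

    Scores are assembled in (level, direction) order to match the basis
    fields.
    """

    def __init__(self, n_features: int, hidden: tuple[int, int] = (64, 64),
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_features = n_features
        self.nets = []
        for _ in range(N_SCORES):
            self.nets.append([Linear(rng, n_features, hidden[0]),
                              Linear(rng, hidden[0], hidden[1]),
                              Linear(rng, hidden[1], 1)])

    def forward(self, navigators: Tensor) -> Tensor:
        """(N, n_features) -> (N, 9) scores."""
        if navigators.shape[-1] != self.n_features:
            raise ValueError(
                f"navigator width {navigators.shape[-1]} != {self.n_features}")
        outs = []
        for net in self.nets:
            h = net[0](navigators).relu()
            h = net[1](h).relu()
            outs.append(net[2](h))
        return concat(outs, axis=1)

    def parameters(self):
        return [p for net in self.nets for layer in net for p in layer.parameters()]

    def state_dict(self):
        return {f"net{i}_l{j}_{n}": getattr(layer, n).data.copy()
                for i, net in enumerate(self.nets)
                for j, layer in enumerate(net) for n in ("w", "b")}

    def load_state_dict(self, st):
        for i, net in enumerate(self.nets):
            for j, layer in enumerate(net):
                layer.w.data[...] = st[f"net{i}_l{j}_w"]
                layer.b.data[...] = st[f"net{i}_l{j}_b"]


def mlp_forward(encoder: MLPEncoder, navigator: np.ndarray) -> np.ndarray:
    """Numpy convenience wrapper: one navigator -> 9 scores."""
    nav = np.atleast_2d(np.asarray(navigator, dtype=np.float64))
    return encoder.forward(Tensor(nav)).data[0]


class CNNEncoder:
    """Six stride-2 conv blocks + global average pooling + linear head."""

    MIN_INPUT = 8

    def __init__(self, seed: int = 0, kernels=CNN_KERNELS, channels=CNN_CHANNELS):
        rng = np.random.default_rng(seed)
        self.convs = []
        self.bns = []
        cin = 1
        for k, cout in zip(kernels, channels):
            w = Tensor(_he_init(rng, cin * k * k, (cout, cin, k, k)),
                       requires_grad=True)
            b = Tensor(np.zeros(cout), requires_grad=True)
            self.convs.append((w, b))
            self.bns.append(BatchNorm2d(cout))
            cin = cout
        self.head = Linear(rng, cin, N_SCORES)
        self.training = True

    def train(self, flag: bool = True):
        self.training = flag
        for bn in self.bns:
            bn.training = flag
        return self

    def eval(self):
        return self.train(False)

    def forward(self, images: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N, 9) scores."""
        if images.ndim != 4 or images.shape[1] != 1:
            raise ValueError("expected single-channel (N,1,H,W) input")
        if min(images.shape[2], images.shape[3]) < self.MIN_INPUT:
            raise ValueError("projection image below the receptive minimum")
        h = images
        for (w, b), bn in zip(self.convs, self.bns):
            h = conv2d(h, w, b, stride=2)
            h = bn(h)
            h = h.relu()
        pooled = h.mean(axis=(2, 3))
        return self.head(pooled)

    def parameters(self):
        ps = []
        for w, b in self.convs:
            ps += [w, b]
        for bn in self.bns:
            ps += bn.parameters()
        ps += self.head.parameters()
        return ps

    def state_dict(self):
        st = {}
        for i, (w, b) in enumerate(self.convs):
            st[f"conv{i}_w"] = w.data.copy()
            st[f"conv{i}_b"] = b.data.copy()
        for i, bn in enumerate(self.bns):
            for k, v in bn.state().items():
                st[f"bn{i}_{k}"] = v
        st["head_w"] = self.head.w.data.copy()
        st["head_b"] = self.head.b.data.copy()
        return st

    def load_state_dict(self, st):
        for i, (w, b) in enumerate(self.convs):
            w.data[...] = st[f"conv{i}_w"]
            b.data[...] = st[f"conv{i}_b"]
        for i, bn in enumerate(self.bns):
            bn.load_state({k: st[f"bn{i}_{k}"] for k in
                           ("gamma", "beta", "running_mean", "running_var")})
        self.head.w.data[...] = st["head_w"]
        self.head.b.data[...] = st["head_b"]


def cnn_forward(encoder: CNNEncoder, projection: np.ndarray) -> np.ndarray:
    """Numpy convenience wrapper in evaluation mode: one image -> 9 scores."""
    was_training = encoder.training
    encoder.eval()
    img = np.asarray(projection, dtype=np.float64)
    out = encoder.forward(Tensor(img[None, None])).data[0]
    encoder.train(was_training)
    return out
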