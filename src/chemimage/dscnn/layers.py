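"""Numpy forward/backward implementations of every network layer.

No autodiff backend is assumed: each layer owns its parameters and gradient
buffers and implements an explicit backward pass. Data streams through layers
in one of three forms:

* 3-D stream ``(N, M, H, W, D)`` — M feature-map volumes per sample with a
  retained spectral axis D (the input cube enters as M=1, D=channels);
* 2-D stream ``(N, C, H, W)`` — flat feature maps after the spectral axis is
  collapsed (by a collapsing 2-D convolution or spectral average pooling);
* flat stream ``(N, K)`` — after flattening, for the dense head.

Convolutions use stride 1 with "same" zero padding in every convolved
dimension (even kernels pad asymmetrically: floor((k-1)/2) before, floor(k/2)
after); pooling is "valid" with stride equal to the window by default
(stride-1 pooling is available via the ``stride`` argument).

The two depthwise-separable 3-D convolutions factor a full 3-D convolution
into a spatial (x-y) stage and a 1-D spectral (z) stage:

* Type 1: one shared spatial kernel (with per-input-map weights, summed over
  maps) produces a single intermediate volume; F learnable 1-D spectral
  kernels then produce F output volumes.
* Type 2: S spatial kernels produce S sublayer volumes; each sublayer gets its
  own T spectral kernels, producing S·T output volumes.

ReLU is applied once per composite layer, after the spectral stage and bias.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2dCollapse",
    "DscType1",
    "DscType2",
    "MaxPool3d",
    "AvgPool3d",
    "MaxPool2d",
    "AvgPool1dSpectral",
    "GlobalAvgPool3d",
    "Flatten",
    "Dense",
    "BatchNorm",
    "he_uniform",
    "same_pad",
]


def same_pad(k: int) -> tuple[int, int]:
    """Zero padding (before, after) giving 'same' output size at stride 1."""
    return (k - 1) // 2, k // 2


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Uniform He initialisation: U(-sqrt(6/fan_in), +sqrt(6/fan_in))."""
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter registry plus forward/backward contract."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init_params(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _as_2d_stream(x: np.ndarray) -> np.ndarray:
    """Accept (N,C,H,W) or (N,M,H,W,D) (folding M·D into channels)."""
    if x.ndim == 4:
        return x
    if x.ndim == 5:
        n, m, h, w, d = x.shape
        # (N,M,H,W,D) -> (N, M*D, H, W)
        return np.moveaxis(x, 4, 2).reshape(n, m * d, h, w)
    raise ValueError(f"expected 4-D or 5-D input, got shape {x.shape}")


class Conv2dCollapse(Layer):
    """Standard multi-channel 2-D convolution, collapsing depth by summation.

    Every filter spans all input channels (for a 3-D stream: all maps × all
    spectral slices) and sums over them — "collapses to a single value per
    pixel by vector addition" — producing one 2-D map per filter.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int = 5,
                 apply_relu: bool = True) -> None:
        super().__init__()
        self.c_in = int(in_channels)
        self.f = int(filters)
        self.k = int(kernel)
        self.apply_relu = apply_relu
        self.params = {
            "w": np.zeros((self.f, self.c_in, self.k, self.k)),
            "b": np.zeros(self.f),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_params(self, rng: np.random.Generator) -> None:
        self.params["w"] = he_uniform(rng, self.params["w"].shape,
                                      fan_in=self.c_in * self.k * self.k)
        self.params["b"][:] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._orig_shape = x.shape
        x = _as_2d_stream(x)
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv2dCollapse: expected {self.c_in} channels, got {c}")
        pb, pa = same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa)))
        self._xp = xp
        W = self.params["w"]
        out = np.zeros((n, self.f, h, w), dtype=x.dtype)
        for a in range(self.k):
            for b in range(self.k):
                patch = xp[:, :, a : a + h, b : b + w]
                out += np.einsum("ncij,fc->nfij", patch, W[:, :, a, b])
        out += self.params["b"][None, :, None, None]
        self._pre = out
        return np.maximum(out, 0.0) if self.apply_relu else out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.apply_relu:
            dout = dout * (self._pre > 0)
        xp = self._xp
        n, c, hp, wp = xp.shape
        h, w = dout.shape[2], dout.shape[3]
        W = self.params["w"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for a in range(self.k):
            for b in range(self.k):
                patch = xp[:, :, a : a + h, b : b + w]
                dW[:, :, a, b] = np.einsum("nfij,ncij->fc", dout, patch)
                dxp[:, :, a : a + h, b : b + w] += np.einsum(
                    "nfij,fc->ncij", dout, W[:, :, a, b]
                )
        self.grads["w"] = dW
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        pb, pa = same_pad(self.k)
        dx = dxp[:, :, pb : hp - pa, pb : wp - pa]
        if len(self._orig_shape) == 5:  # unfold channels back to (N,M,H,W,D)
            n_, m_, h_, w_, d_ = self._orig_shape
            dx = np.moveaxis(dx.reshape(n_, m_, d_, h_, w_), 2, 4)
        return dx


def _pad_spatial_3d(x: np.ndarray, k: int) -> np.ndarray:
    pb, pa = same_pad(k)
    return np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa), (0, 0)))


class DscType1(Layer):
    """Type 1 depthwise-separable 3-D convolution.

    Stage 1: a single spatial kernel (per-input-map weights, summed over maps,
    one shared bias) convolves every spectral slice → one intermediate volume.
    Stage 2: F 1-D spectral kernels (bias each) convolve the intermediate
    volume along z → F output volumes. ReLU after stage 2.
    """

    def __init__(self, in_maps: int, filters: int, k_spatial: int = 5,
                 k_spectral: int = 5, apply_relu: bool = True) -> None:
        super().__init__()
        self.m_in = int(in_maps)
        self.f = int(filters)
        self.ks = int(k_spatial)
        self.kz = int(k_spectral)
        self.apply_relu = apply_relu
        self.params = {
            "ws": np.zeros((self.m_in, self.ks, self.ks)),
            "bs": np.zeros(1),
            "wz": np.zeros((self.f, self.kz)),
            "bz": np.zeros(self.f),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_params(self, rng: np.random.Generator) -> None:
        self.params["ws"] = he_uniform(rng, self.params["ws"].shape,
                                       fan_in=self.m_in * self.ks**2)
        self.params["wz"] = he_uniform(rng, self.params["wz"].shape, fan_in=self.kz)
        self.params["bs"][:] = 0.0
        self.params["bz"][:] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, m, h, w, d = x.shape
        if m != self.m_in:
            raise ValueError(f"DscType1: expected {self.m_in} input maps, got {m}")
        xp = _pad_spatial_3d(x, self.ks)
        self._xp = xp
        ws = self.params["ws"]
        inter = np.zeros((n, h, w, d), dtype=x.dtype)
        for a in range(self.ks):
            for b in range(self.ks):
                inter += np.einsum(
                    "nmijd,m->nijd", xp[:, :, a : a + h, b : b + w, :], ws[:, a, b]
                )
        inter += self.params["bs"][0]
        pb, pa = same_pad(self.kz)
        zp = np.pad(inter, ((0, 0), (0, 0), (0, 0), (pb, pa)))
        self._zp = zp
        win = sliding_window_view(zp, self.kz, axis=3)  # (n,h,w,d,kz)
        pre = np.einsum("nijde,fe->nfijd", win, self.params["wz"])
        pre += self.params["bz"][None, :, None, None, None]
        self._pre = pre
        return np.maximum(pre, 0.0) if self.apply_relu else pre

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.apply_relu:
            dout = dout * (self._pre > 0)
        zp, xp = self._zp, self._xp
        n, f, h, w, d = dout.shape
        wz = self.params["wz"]
        self.grads["bz"] = dout.sum(axis=(0, 2, 3, 4))
        dwz = np.zeros_like(wz)
        dzp = np.zeros_like(zp)
        for e in range(self.kz):
            dwz[:, e] = np.einsum("nfijd,nijd->f", dout, zp[:, :, :, e : e + d])
            dzp[:, :, :, e : e + d] += np.einsum("nfijd,f->nijd", dout, wz[:, e])
        self.grads["wz"] = dwz
        pb, pa = same_pad(self.kz)
        dinter = dzp[:, :, :, pb : zp.shape[3] - pa]
        self.grads["bs"] = np.array([dinter.sum()])
        ws = self.params["ws"]
        dws = np.zeros_like(ws)
        dxp = np.zeros_like(xp)
        for a in range(self.ks):
            for b in range(self.ks):
                patch = xp[:, :, a : a + h, b : b + w, :]
                dws[:, a, b] = np.einsum("nijd,nmijd->m", dinter, patch)
                dxp[:, :, a : a + h, b : b + w, :] += np.einsum(
                    "nijd,m->nmijd", dinter, ws[:, a, b]
                )
        self.grads["ws"] = dws
        pbs, pas = same_pad(self.ks)
        return dxp[:, :, pbs : xp.shape[2] - pas, pbs : xp.shape[3] - pas, :]


class DscType2(Layer):
    """Type 2 depthwise-separable 3-D convolution.

    Stage 1: S spatial kernels (per-input-map weights, bias each) → S sublayer
    volumes. Stage 2: each sublayer gets its own T spectral kernels (bias per
    output map) → S·T output volumes, ordered sublayer-major. ReLU after
    stage 2.
    """

    def __init__(self, in_maps: int, s_filters: int, t_filters: int,
                 k_spatial: int = 5, k_spectral: int = 5,
                 apply_relu: bool = True) -> None:
        super().__init__()
        self.m_in = int(in_maps)
        self.s = int(s_filters)
        self.t = int(t_filters)
        self.ks = int(k_spatial)
        self.kz = int(k_spectral)
        self.apply_relu = apply_relu
        self.params = {
            "ws": np.zeros((self.s, self.m_in, self.ks, self.ks)),
            "bs": np.zeros(self.s),
            "wz": np.zeros((self.s, self.t, self.kz)),
            "bz": np.zeros((self.s, self.t)),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_params(self, rng: np.random.Generator) -> None:
        self.params["ws"] = he_uniform(rng, self.params["ws"].shape,
                                       fan_in=self.m_in * self.ks**2)
        self.params["wz"] = he_uniform(rng, self.params["wz"].shape, fan_in=self.kz)
        self.params["bs"][:] = 0.0
        self.params["bz"][:] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, m, h, w, d = x.shape
        if m != self.m_in:
            raise ValueError(f"DscType2: expected {self.m_in} input maps, got {m}")
        xp = _pad_spatial_3d(x, self.ks)
        self._xp = xp
        ws = self.params["ws"]
        sub = np.zeros((n, self.s, h, w, d), dtype=x.dtype)
        for a in range(self.ks):
            for b in range(self.ks):
                sub += np.einsum(
                    "nmijd,sm->nsijd", xp[:, :, a : a + h, b : b + w, :], ws[:, :, a, b]
                )
        sub += self.params["bs"][None, :, None, None, None]
        pb, pa = same_pad(self.kz)
        zp = np.pad(sub, ((0, 0), (0, 0), (0, 0), (0, 0), (pb, pa)))
        self._zp = zp
        win = sliding_window_view(zp, self.kz, axis=4)  # (n,s,h,w,d,kz)
        pre = np.einsum("nsijde,ste->nstijd", win, self.params["wz"])
        pre += self.params["bz"][None, :, :, None, None, None]
        self._pre = pre
        out = pre.reshape(n, self.s * self.t, h, w, d)
        return np.maximum(out, 0.0) if self.apply_relu else out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        h, w, d = dout.shape[2], dout.shape[3], dout.shape[4]
        dpre = dout.reshape(n, self.s, self.t, h, w, d)
        if self.apply_relu:
            dpre = dpre * (self._pre > 0)
        zp, xp = self._zp, self._xp
        wz = self.params["wz"]
        self.grads["bz"] = dpre.sum(axis=(0, 3, 4, 5))
        dwz = np.zeros_like(wz)
        dzp = np.zeros_like(zp)
        for e in range(self.kz):
            dwz[:, :, e] = np.einsum("nstijd,nsijd->st", dpre, zp[:, :, :, :, e : e + d])
            dzp[:, :, :, :, e : e + d] += np.einsum("nstijd,st->nsijd", dpre, wz[:, :, e])
        self.grads["wz"] = dwz
        pb, pa = same_pad(self.kz)
        dsub = dzp[:, :, :, :, pb : zp.shape[4] - pa]
        self.grads["bs"] = dsub.sum(axis=(0, 2, 3, 4))
        ws = self.params["ws"]
        dws = np.zeros_like(ws)
        dxp = np.zeros_like(xp)
        for a in range(self.ks):
            for b in range(self.ks):
                patch = xp[:, :, a : a + h, b : b + w, :]
                dws[:, :, a, b] = np.einsum("nsijd,nmijd->sm", dsub, patch)
                dxp[:, :, a : a + h, b : b + w, :] += np.einsum(
                    "nsijd,sm->nmijd", dsub, ws[:, :, a, b]
                )
        self.grads["ws"] = dws
        pbs, pas = same_pad(self.ks)
        return dxp[:, :, pbs : xp.shape[2] - pas, pbs : xp.shape[3] - pas, :]


class _PoolNd(Layer):
    """Valid pooling over the trailing ``nd`` axes; stride defaults to window."""

    reduce: str = "max"

    def __init__(self, window: tuple[int, ...], stride: tuple[int, ...] | None = None) -> None:
        super().__init__()
        self.window = tuple(int(w) for w in window)
        self.stride = tuple(int(s) for s in (stride or self.window))
        if any(w < 1 for w in self.window) or any(s < 1 for s in self.stride):
            raise ValueError("pool window and stride must be >= 1")

    def _out_sizes(self, sizes: tuple[int, ...]) -> tuple[int, ...]:
        out = tuple((sz - w) // s + 1 for sz, w, s in zip(sizes, self.window, self.stride))
        if any(o < 1 for o in out):
            raise ValueError(f"pool window {self.window} larger than input {sizes}")
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        nd = len(self.window)
        lead = x.ndim - nd
        axes = tuple(range(lead, x.ndim))
        self._x_shape = x.shape
        self._out_sizes(x.shape[lead:])
        win = sliding_window_view(x, self.window, axis=axes)
        # stride subsampling on the window-position axes
        sl = tuple([slice(None)] * lead
                   + [slice(None, None, s) for s in self.stride]
                   + [slice(None)] * nd)
        win = win[sl]
        pos_shape = win.shape[: lead + nd]
        blocks = win.reshape(pos_shape + (-1,))
        if self.reduce == "max":
            self._argmax = np.argmax(blocks, axis=-1)
            out = np.take_along_axis(blocks, self._argmax[..., None], axis=-1)[..., 0]
        else:
            out = blocks.mean(axis=-1)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        nd = len(self.window)
        lead = len(self._x_shape) - nd
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        pos_sizes = dout.shape[lead:]
        if self.reduce == "max":
            # scatter gradient to the first-maximum voxel of each window
            idx = np.indices(dout.shape)
            offs = np.unravel_index(self._argmax, self.window)
            full = tuple(idx[i] for i in range(lead)) + tuple(
                idx[lead + i] * self.stride[i] + offs[i] for i in range(nd)
            )
            np.add.at(dx, full, dout)
        else:
            scale = 1.0 / float(np.prod(self.window))
            lead_sl = (slice(None),) * lead
            for offs in np.ndindex(*self.window):
                sl = tuple(
                    slice(o, o + p * s, s)
                    for o, p, s in zip(offs, pos_sizes, self.stride)
                )
                dx[lead_sl + sl] += dout * scale
        return dx


class MaxPool3d(_PoolNd):
    """3-D max pooling over (H, W, D) of a 3-D stream."""

    reduce = "max"

    def __init__(self, window=(2, 2, 2), stride=None) -> None:
        super().__init__(window, stride)


class AvgPool3d(_PoolNd):
    reduce = "avg"

    def __init__(self, window=(4, 4, 4), stride=None) -> None:
        super().__init__(window, stride)


class MaxPool2d(_PoolNd):
    """2-D max pooling over (H, W) of a 2-D stream."""

    reduce = "max"

    def __init__(self, window=(2, 2), stride=None) -> None:
        super().__init__(window, stride)


class AvgPool1dSpectral(Layer):
    """Average over the entire spectral axis: (N,M,H,W,D) → (N,M,H,W)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._d = x.shape[4]
        return x.mean(axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[..., None], self._d, axis=4) / self._d


class GlobalAvgPool3d(Layer):
    """Average each feature volume to one value: (N,M,H,W,D) → (N,M)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, m, h, w, d = self._shape
        return np.broadcast_to(dout[:, :, None, None, None], self._shape) / (h * w * d)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; hidden layers use ReLU, the output layer none
    (the sigmoid lives in the loss/prediction for numerical stability)."""

    def __init__(self, n_in: int, n_out: int, apply_relu: bool = True) -> None:
        super().__init__()
        self.n_in, self.n_out = int(n_in), int(n_out)
        self.apply_relu = apply_relu
        self.params = {"w": np.zeros((self.n_in, self.n_out)), "b": np.zeros(self.n_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def init_params(self, rng: np.random.Generator) -> None:
        self.params["w"] = he_uniform(rng, self.params["w"].shape, fan_in=self.n_in)
        self.params["b"][:] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        pre = x @ self.params["w"] + self.params["b"]
        self._pre = pre
        return np.maximum(pre, 0.0) if self.apply_relu else pre

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.apply_relu:
            dout = dout * (self._pre > 0)
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class BatchNorm(Layer):
    """Per-feature-map batch normalisation (2 learnable parameters per map).

    Normalises over every axis except the map axis (axis 1); keeps running
    statistics for evaluation mode.
    """

    def __init__(self, n_maps: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.m = int(n_maps)
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(self.m), "beta": np.zeros(self.m)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(self.m)
        self.running_var = np.ones(self.m)

    def _bshape(self, ndim: int):
        return (1, self.m) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._nred = int(np.prod([x.shape[a] for a in axes]))
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shp)) / self._std.reshape(shp)
        self._train = train
        return self.params["gamma"].reshape(shp) * self._xhat + self.params["beta"].reshape(shp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shp = self._bshape(dout.ndim)
        axes = self._axes
        xhat = self._xhat
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"].reshape(shp)
        if not self._train:
            return dout * g / self._std.reshape(shp)
        n = self._nred
        dxhat = dout * g
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shp)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp)
        )
        return term / self._std.reshape(shp)
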