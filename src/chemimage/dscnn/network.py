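"""Realize a declarative architecture as a trainable numpy network."""

from __future__ import annotations

import numpy as np

from . import layers as L
from .specs import ArchitectureSpec, LayerSpec, ShapeError, infer_shapes

__all__ = [
    "Network",
    "realize",
    "conv2d_collapse_forward",
    "dsc_type1_forward",
    "dsc_type2_forward",
]


class Network:
    """Ordered layer stack with explicit forward/backward and logit output."""

    def __init__(self, arch: ArchitectureSpec, layer_objs: list[L.Layer]) -> None:
        self.arch = arch
        self.layers = layer_objs

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (N,). Input: (N, rows, cols, channels) cubes."""
        out = np.ascontiguousarray(x)[:, None, :, :, :]  # -> (N, 1, H, W, D)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        grad = np.asarray(dlogits)[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = np.empty(x.shape[0])
        for i in range(0, x.shape[0], batch_size):
            z = self.forward(x[i : i + batch_size], train=False)
            out[i : i + batch_size] = 1.0 / (1.0 + np.exp(-z))
        return out

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        """Yield (layer_index, name, array) for every learnable parameter."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield i, name, layer.params[name]

    @property
    def n_params(self) -> int:
        """Trainable total as reported by the realized arrays themselves."""
        return sum(p.size for _, _, p in self.parameters())

    def get_state(self) -> dict:
        return {f"{i}/{n}": p.copy() for i, n, p in self.parameters()}

    def set_state(self, state: dict) -> None:
        for i, n, p in self.parameters():
            p[...] = state[f"{i}/{n}"]


def _make_layer(spec: LayerSpec, stream_in) -> L.Layer:
    k = spec.kind
    if k == "conv2d_collapse":
        c_in = stream_in[1] * stream_in[4] if stream_in[0] == "3d" else stream_in[1]
        return L.Conv2dCollapse(c_in, spec.filters, kernel=spec.k_spatial)
    if k == "dsc_type1":
        return L.DscType1(stream_in[1], spec.filters,
                          k_spatial=spec.k_spatial, k_spectral=spec.k_spectral)
    if k == "dsc_type2":
        return L.DscType2(stream_in[1], spec.s_filters, spec.t_filters,
                          k_spatial=spec.k_spatial, k_spectral=spec.k_spectral)
    if k == "maxpool3d":
        return L.MaxPool3d(spec.pool, spec.stride or None)
    if k == "avgpool3d":
        return L.AvgPool3d(spec.pool, spec.stride or None)
    if k == "maxpool2d":
        return L.MaxPool2d(spec.pool, spec.stride or None)
    if k == "avgpool1d_spectral":
        return L.AvgPool1dSpectral()
    if k == "global_avgpool3d":
        return L.GlobalAvgPool3d()
    if k == "flatten":
        return L.Flatten()
    if k == "dense":
        return L.Dense(stream_in[1], spec.units, apply_relu=True)
    if k == "output_sigmoid":
        return L.Dense(stream_in[1], spec.units, apply_relu=False)
    if k == "batch_norm":
        return L.BatchNorm(stream_in[1])
    raise AssertionError(k)


def realize(arch: ArchitectureSpec, seed: int = 0) -> Network:
    """Instantiate a network with uniform-He-initialized parameters.

    Realized output shapes are guaranteed to match the symbolic shape algebra;
    the instantiated parameter total equals ``arch.n_params()``.
    """
    shapes = infer_shapes(arch)
    stream = ("3d", 1, *arch.input_shape[:2], arch.input_shape[2])
    rng = np.random.default_rng(seed)
    objs: list[L.Layer] = []
    for spec, out_stream in zip(arch.layers, shapes):
        layer = _make_layer(spec, stream)
        layer.init_params(rng)
        objs.append(layer)
        stream = out_stream
    net = Network(arch, objs)
    if net.n_params != arch.n_params():
        raise ShapeError(
            f"realized parameter total {net.n_params} != symbolic count {arch.n_params()}"
        )
    return net


# ---------------------------------------------------------------------------
# functional single-layer forwards (operator surface for oracle checks)
# ---------------------------------------------------------------------------

def conv2d_collapse_forward(x: np.ndarray, weights: np.ndarray, bias: np.ndarray,
                            apply_relu: bool = False) -> np.ndarray:
    """Collapsing multi-channel 2-D convolution (same padding, stride 1).

    ``x``: (N, C, H, W) or (N, M, H, W, D); ``weights``: (F, C, k, k).
    """
    f, c_in, k, _ = weights.shape
    layer = L.Conv2dCollapse(c_in, f, kernel=k, apply_relu=apply_relu)
    layer.params["w"] = np.asarray(weights, dtype=np.float64)
    layer.params["b"] = np.asarray(bias, dtype=np.float64)
    return layer.forward(np.asarray(x, dtype=np.float64))


def dsc_type1_forward(x: np.ndarray, spatial_kernel: np.ndarray,
                      spectral_kernels: np.ndarray, spatial_bias: float = 0.0,
                      spectral_bias: np.ndarray | None = None,
                      apply_relu: bool = False) -> np.ndarray:
    """Type 1 depthwise-separable 3-D convolution forward.

    ``x``: (N, M, H, W, D); ``spatial_kernel``: (M, ks, ks);
    ``spectral_kernels``: (F, kz). Output: (N, F, H, W, D).
    """
    spatial_kernel = np.asarray(spatial_kernel, dtype=np.float64)
    spectral_kernels = np.asarray(spectral_kernels, dtype=np.float64)
    m, ks, _ = spatial_kernel.shape
    f, kz = spectral_kernels.shape
    layer = L.DscType1(m, f, k_spatial=ks, k_spectral=kz, apply_relu=apply_relu)
    layer.params["ws"] = spatial_kernel
    layer.params["bs"] = np.array([float(spatial_bias)])
    layer.params["wz"] = spectral_kernels
    layer.params["bz"] = (np.zeros(f) if spectral_bias is None
                          else np.asarray(spectral_bias, dtype=np.float64))
    return layer.forward(np.asarray(x, dtype=np.float64))


def dsc_type2_forward(x: np.ndarray, spatial_kernels: np.ndarray,
                      spectral_kernels: np.ndarray,
                      spatial_bias: np.ndarray | None = None,
                      spectral_bias: np.ndarray | None = None,
                      apply_relu: bool = False) -> np.ndarray:
    """Type 2 depthwise-separable 3-D convolution forward.

    ``x``: (N, M, H, W, D); ``spatial_kernels``: (S, M, ks, ks);
    ``spectral_kernels``: (S, T, kz). Output: (N, S·T, H, W, D),
    sublayer-major.
    """
    spatial_kernels = np.asarray(spatial_kernels, dtype=np.float64)
    spectral_kernels = np.asarray(spectral_kernels, dtype=np.float64)
    s, m, ks, _ = spatial_kernels.shape
    s2, t, kz = spectral_kernels.shape
    if s2 != s:
        raise ValueError("spatial and spectral kernel counts disagree on S")
    layer = L.DscType2(m, s, t, k_spatial=ks, k_spectral=kz, apply_relu=apply_relu)
    layer.params["ws"] = spatial_kernels
    layer.params["bs"] = (np.zeros(s) if spatial_bias is None
                          else np.asarray(spatial_bias, dtype=np.float64))
    layer.params["wz"] = spectral_kernels
    layer.params["bz"] = (np.zeros((s, t)) if spectral_bias is None
                          else np.asarray(spectral_bias, dtype=np.float64))
    return layer.forward(np.asarray(x, dtype=np.float64))
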