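"""Declarative network architectures: shape algebra and exact parameter counts.

An :class:`ArchitectureSpec` is an ordered list of :class:`LayerSpec` entries
plus an input shape. It is purely symbolic: output shapes of every layer and
the exact learnable-parameter total derive from the spec alone, before any
parameter array exists, and a spec serialises to/from JSON so a training run
is reproducible from its config.

Seven named architectures are provided:

* ``lenet5_mod`` — LeNet5 adapted to hyperspectral input: two collapsing 2-D
  convolutions (the full spectral depth is summed into each filter response),
  each followed by 2×2 max pooling, then dense 180 → 100 → 1.
* ``model1`` — lenet5_mod with the first convolution replaced by a Type 1
  depthwise-separable 3-D convolution (spectral axis retained through one
  3-D pooling stage, then collapsed by the second, 2-D, convolution).
* ``model2`` — four Type 1 DSC layers (12/25/25/50 filters of 5×5×5), each
  followed by 2×2×2 max pooling; dense head.
* ``model3`` — three Type 1 DSC layers; the spectral dimension is collapsed
  entirely by 1-D average pooling after the third DSC, then 2×2 max pooling.
* ``model4`` — three Type 1 DSC layers (12/25/50) with 3-D global average
  pooling instead of flatten, giving the smallest parameter budget.
* ``model5`` — four Type 2 DSC layers (5×3, 5×5, 5×5, 5×10 spatial×spectral
  filters); final 2×2×5 max pooling.
* ``model6`` — 4×4×4 average pooling of the input, then two Type 1 DSC layers
  with larger kernels (8×8×8 and 3×3×5), a collapsing 2-D convolution and
  2×2 max pooling — the aggressively downsampled "small RAM" design.

Dense widths are fixed at 180 → 100 → 1 with ReLU hidden activations and a
sigmoid output; optional batch normalisation sits between each convolution
and its pooling layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ShapeError",
    "build_architecture",
    "count_params",
    "infer_shapes",
    "ARCHITECTURE_NAMES",
]

ARCHITECTURE_NAMES = (
    "lenet5_mod", "model1", "model2", "model3", "model4", "model5", "model6",
)

KINDS = {
    "conv2d_collapse", "dsc_type1", "dsc_type2",
    "maxpool3d", "avgpool3d", "maxpool2d",
    "avgpool1d_spectral", "global_avgpool3d",
    "flatten", "dense", "batch_norm", "output_sigmoid",
}


class ShapeError(ValueError):
    """Layer geometry inconsistent with its input shape."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer: kind plus the geometry that determines shapes and counts."""

    kind: str
    filters: int = 0        # F (conv2d_collapse, dsc_type1)
    s_filters: int = 0      # S (dsc_type2)
    t_filters: int = 0      # T (dsc_type2)
    k_spatial: int = 0      # spatial kernel edge
    k_spectral: int = 0     # spectral kernel length
    pool: tuple[int, ...] = ()
    stride: tuple[int, ...] = ()
    units: int = 0          # dense width

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


# ---------------------------------------------------------------------------
# shape algebra over symbolic streams
# ---------------------------------------------------------------------------
# stream forms: ("3d", M, H, W, D) | ("2d", C, H, W) | ("flat", K)

def _pool_out(sizes, window, stride):
    stride = stride or window
    out = tuple((sz - w) // s + 1 for sz, w, s in zip(sizes, window, stride))
    if any(o < 1 for o in out):
        raise ShapeError(f"pool window {window} does not fit input {sizes}")
    return out


def _step(stream, spec: LayerSpec):
    kind = spec.kind
    if kind == "conv2d_collapse":
        if stream[0] == "3d":
            _, m, h, w, d = stream
            c_in = m * d
        elif stream[0] == "2d":
            _, c_in, h, w = stream
        else:
            raise ShapeError("conv2d_collapse needs a spatial stream")
        return ("2d", spec.filters, h, w)
    if kind in ("dsc_type1", "dsc_type2"):
        if stream[0] != "3d":
            raise ShapeError(f"{kind} needs a 3-D stream, got {stream[0]}")
        _, m, h, w, d = stream
        out_maps = spec.filters if kind == "dsc_type1" else spec.s_filters * spec.t_filters
        return ("3d", out_maps, h, w, d)
    if kind in ("maxpool3d", "avgpool3d"):
        if stream[0] != "3d":
            raise ShapeError(f"{kind} needs a 3-D stream")
        _, m, h, w, d = stream
        ho, wo, do = _pool_out((h, w, d), spec.pool, spec.stride)
        return ("3d", m, ho, wo, do)
    if kind == "maxpool2d":
        if stream[0] != "2d":
            raise ShapeError("maxpool2d needs a 2-D stream")
        _, c, h, w = stream
        ho, wo = _pool_out((h, w), spec.pool, spec.stride)
        return ("2d", c, ho, wo)
    if kind == "avgpool1d_spectral":
        if stream[0] != "3d":
            raise ShapeError("avgpool1d_spectral needs a 3-D stream")
        _, m, h, w, d = stream
        return ("2d", m, h, w)
    if kind == "global_avgpool3d":
        if stream[0] != "3d":
            raise ShapeError("global_avgpool3d needs a 3-D stream")
        return ("flat", stream[1])
    if kind == "flatten":
        if stream[0] == "3d":
            return ("flat", stream[1] * stream[2] * stream[3] * stream[4])
        if stream[0] == "2d":
            return ("flat", stream[1] * stream[2] * stream[3])
        return stream
    if kind in ("dense", "output_sigmoid"):
        if stream[0] != "flat":
            raise ShapeError(f"{kind} needs a flat stream (insert flatten)")
        return ("flat", spec.units)
    if kind == "batch_norm":
        if stream[0] == "flat":
            raise ShapeError("batch_norm sits between convolution and pooling")
        return stream
    raise AssertionError(kind)


def infer_shapes(arch: "ArchitectureSpec") -> list[tuple]:
    """Symbolic output stream of every layer; raises ShapeError with the
    offending layer index on inconsistency."""
    stream = ("3d", 1, *arch.input_shape[:2], arch.input_shape[2])
    out = []
    for i, spec in enumerate(arch.layers):
        try:
            stream = _step(stream, spec)
        except ShapeError as e:
            raise ShapeError(f"layer {i} ({spec.kind}): {e}") from e
        out.append(stream)
    if arch.layers and arch.layers[-1].kind != "output_sigmoid":
        raise ShapeError("final layer must be output_sigmoid")
    if out and out[-1] != ("flat", 1):
        raise ShapeError(f"output layer must have width 1, got {out[-1]}")
    return out


def _layer_params(stream_in, spec: LayerSpec) -> int:
    kind = spec.kind
    if kind == "conv2d_collapse":
        c_in = stream_in[1] * stream_in[4] if stream_in[0] == "3d" else stream_in[1]
        return spec.filters * (spec.k_spatial**2 * c_in + 1)
    if kind == "dsc_type1":
        m = stream_in[1]
        return (spec.k_spatial**2 * m + 1) + spec.filters * (spec.k_spectral + 1)
    if kind == "dsc_type2":
        m = stream_in[1]
        s, t = spec.s_filters, spec.t_filters
        return s * (spec.k_spatial**2 * m + 1) + s * t * (spec.k_spectral + 1)
    if kind in ("dense", "output_sigmoid"):
        return (stream_in[1] + 1) * spec.units
    if kind == "batch_norm":
        return 2 * stream_in[1]
    return 0


def count_params(arch: "ArchitectureSpec") -> int:
    """Exact learnable-parameter total, derived from the spec alone."""
    stream = ("3d", 1, *arch.input_shape[:2], arch.input_shape[2])
    total = 0
    for spec in arch.layers:
        total += _layer_params(stream, spec)
        stream = _step(stream, spec)
    return total


@dataclass(frozen=True)
class ArchitectureSpec:
    """Named, fully declarative network description."""

    name: str
    input_shape: tuple[int, int, int]  # rows, cols, channels
    layers: tuple[LayerSpec, ...]

    def shapes(self) -> list[tuple]:
        return infer_shapes(self)

    def n_params(self) -> int:
        return count_params(self)

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "input_shape": list(self.input_shape),
            "layers": [asdict(l) for l in self.layers],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        layers = tuple(
            LayerSpec(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in ld.items()})
            for ld in d["layers"]
        )
        return cls(name=d["name"], input_shape=tuple(d["input_shape"]), layers=layers)

    def describe(self) -> str:
        """Human-readable layer table with shapes and parameter counts."""
        lines = [f"{self.name}  input {self.input_shape}"]
        stream = ("3d", 1, *self.input_shape[:2], self.input_shape[2])
        shapes = self.shapes()
        for i, (spec, shp) in enumerate(zip(self.layers, shapes)):
            n = _layer_params(stream, spec)
            geom = ""
            if spec.kind == "conv2d_collapse":
                geom = f"F={spec.filters} k={spec.k_spatial}"
            elif spec.kind == "dsc_type1":
                geom = f"F={spec.filters} k={spec.k_spatial}x{spec.k_spatial}x{spec.k_spectral}"
            elif spec.kind == "dsc_type2":
                geom = (f"S={spec.s_filters} T={spec.t_filters} "
                        f"k={spec.k_spatial}x{spec.k_spatial}x{spec.k_spectral}")
            elif spec.pool:
                geom = "x".join(map(str, spec.pool))
            elif spec.units:
                geom = f"units={spec.units}"
            lines.append(f"  {i:2d} {spec.kind:<20s} {geom:<24s} -> {shp}  params={n}")
            stream = shp
        lines.append(f"  total params: {self.n_params()}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# named builders
# ---------------------------------------------------------------------------

def _dense_head(with_flatten: bool = True) -> list[LayerSpec]:
    head = [LayerSpec("flatten")] if with_flatten else []
    head += [
        LayerSpec("dense", units=180),
        LayerSpec("dense", units=100),
        LayerSpec("output_sigmoid", units=1),
    ]
    return head


def _with_bn(layers: list[LayerSpec], enabled: bool) -> list[LayerSpec]:
    """Insert batch_norm between each convolution and the following pooling."""
    if not enabled:
        return layers
    conv_kinds = {"conv2d_collapse", "dsc_type1", "dsc_type2"}
    pool_kinds = {"maxpool3d", "avgpool3d", "maxpool2d", "avgpool1d_spectral",
                  "global_avgpool3d"}
    out: list[LayerSpec] = []
    for i, spec in enumerate(layers):
        out.append(spec)
        nxt = layers[i + 1] if i + 1 < len(layers) else None
        if spec.kind in conv_kinds and nxt is not None and nxt.kind in pool_kinds:
            out.append(LayerSpec("batch_norm"))
    return out


def build_architecture(
    name: str,
    input_shape: tuple[int, int, int],
    use_batch_norm: bool = False,
    lenet_filters: tuple[int, int] = (6, 16),
    model6_filters: tuple[int, int, int] = (12, 25, 25),
    model6_kz: int = 8,
    model5_mid: tuple[int, int] = (5, 5),
) -> ArchitectureSpec:
    """Build one of the seven named architectures for a given input shape.

    The spec is validated symbolically (shape algebra) before being returned;
    an unbuildable geometry raises :class:`ShapeError` naming the layer.
    """
    if input_shape[2] < 8:
        raise ShapeError("input must have at least 8 spectral channels")
    f1, f2 = lenet_filters
    mp3 = LayerSpec("maxpool3d", pool=(2, 2, 2))
    mp2 = LayerSpec("maxpool2d", pool=(2, 2))

    if name == "lenet5_mod":
        layers = [
            LayerSpec("conv2d_collapse", filters=f1, k_spatial=5), mp2,
            LayerSpec("conv2d_collapse", filters=f2, k_spatial=5), mp2,
            *_dense_head(),
        ]
    elif name == "model1":
        layers = [
            LayerSpec("dsc_type1", filters=f1, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("conv2d_collapse", filters=f2, k_spatial=5), mp2,
            *_dense_head(),
        ]
    elif name == "model2":
        layers = [
            LayerSpec("dsc_type1", filters=12, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type1", filters=25, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type1", filters=25, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type1", filters=50, k_spatial=5, k_spectral=5), mp3,
            *_dense_head(),
        ]
    elif name == "model3":
        layers = [
            LayerSpec("dsc_type1", filters=12, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type1", filters=25, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type1", filters=25, k_spatial=5, k_spectral=5),
            LayerSpec("avgpool1d_spectral"), mp2,
            *_dense_head(),
        ]
    elif name == "model4":
        layers = [
            LayerSpec("dsc_type1", filters=12, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type1", filters=25, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type1", filters=50, k_spatial=5, k_spectral=5),
            LayerSpec("global_avgpool3d"),
            *_dense_head(with_flatten=False),
        ]
    elif name == "model5":
        s_mid, t_mid = model5_mid
        layers = [
            LayerSpec("dsc_type2", s_filters=5, t_filters=3, k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type2", s_filters=s_mid, t_filters=t_mid,
                      k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type2", s_filters=s_mid, t_filters=t_mid,
                      k_spatial=5, k_spectral=5), mp3,
            LayerSpec("dsc_type2", s_filters=5, t_filters=10, k_spatial=5, k_spectral=5),
            LayerSpec("maxpool3d", pool=(2, 2, 5)),
            *_dense_head(),
        ]
    elif name == "model6":
        g1, g2, g3 = model6_filters
        layers = [
            LayerSpec("avgpool3d", pool=(4, 4, 4)),
            LayerSpec("dsc_type1", filters=g1, k_spatial=8, k_spectral=model6_kz), mp3,
            LayerSpec("dsc_type1", filters=g2, k_spatial=3, k_spectral=5), mp3,
            LayerSpec("conv2d_collapse", filters=g3, k_spatial=5), mp2,
            *_dense_head(),
        ]
    else:
        raise ValueError(f"unknown architecture {name!r}; choose from {ARCHITECTURE_NAMES}")

    arch = ArchitectureSpec(
        name=name, input_shape=tuple(input_shape),
        layers=tuple(_with_bn(layers, use_batch_norm)),
    )
    arch.shapes()  # symbolic validation before any training
    return arch
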