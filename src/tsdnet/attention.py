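"""Tri-directional attention weights.

A shallow feature map of shape ``(H, W, C)`` (optionally with a leading
batch axis) is scored by three small learned projections, one per
direction. Each score array is softmax-normalized along the axis its
direction designates — horizontal across width, vertical across height,
depth across channels — and then rescaled so the per-map maximum equals
one, which makes the downstream gate thresholds scale-free.

The raw softmax values scale as ``1/n`` along the normalized axis, so
without max-rescaling no fixed threshold in (0, 1) would be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DIRECTIONS = ("H", "V", "D")

#: direction tag -> normalization axis, counted from the trailing
#: (height, width, channel) triple of the array.
_AXIS_FROM_END = {"H": -2, "V": -3, "D": -1}


class DirectionError(ValueError):
    pass


def direction_axis(direction: str, ndim: int) -> int:
    """Resolve a direction tag to a concrete numpy axis for `ndim` dims."""
    if direction not in DIRECTIONS:
        raise DirectionError(f"unknown direction {direction!r}; expected one of {DIRECTIONS}")
    if ndim == 1:
        return -1
    if ndim == 2:
        axis = {"H": -1, "V": -2}.get(direction)
        if axis is None:
            raise DirectionError("depth direction undefined for a 2-D array")
        return axis
    return _AXIS_FROM_END[direction]


@dataclass
class DirectionalWeights:
    """The (a_H, a_V, a_D) triple, each shaped like its feature map."""

    a_h: np.ndarray
    a_v: np.ndarray
    a_d: np.ndarray

    def __post_init__(self):
        shapes = {self.a_h.shape, self.a_v.shape, self.a_d.shape}
        if len(shapes) != 1:
            raise ValueError(f"weight arrays must share a shape, got {shapes}")
        for name, arr in self.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in a_{name}")
            if arr.min() < 0 or arr.max() > 1 + 1e-12:
                raise ValueError(f"a_{name} outside [0, 1]")

    def items(self):
        return (("h", self.a_h), ("v", self.a_v), ("d", self.a_d))

    @property
    def shape(self):
        return self.a_h.shape


class DirectionalAttentionParams:
    """Learned projections producing the three directional score arrays.

    The hidden representation is the feature map after a 1x1 channel
    mixing; each direction then applies its own 1x1 linear scoring (the
    three scorings share parameters when ``shared`` is set).
    """

    def __init__(self, n_channels: int, seed: int = 0, shared: bool = False):
        rng = np.random.default_rng(seed)
        self.n_channels = n_channels
        scale = 1.0 / np.sqrt(n_channels)
        self.w_mix = rng.normal(0.0, scale, size=(n_channels, n_channels))
        self.b_mix = np.zeros(n_channels)
        self.w_dir: dict[str, np.ndarray] = {}
        self.b_dir: dict[str, np.ndarray] = {}
        first = None
        for d in DIRECTIONS:
            if shared and first is not None:
                self.w_dir[d] = self.w_dir[first]
                self.b_dir[d] = self.b_dir[first]
            else:
                self.w_dir[d] = rng.normal(0.0, scale, size=(n_channels, n_channels))
                self.b_dir[d] = np.zeros(n_channels)
                first = first or d

    def state(self) -> dict[str, np.ndarray]:
        out = {"w_mix": self.w_mix, "b_mix": self.b_mix}
        for d in DIRECTIONS:
            out[f"w_{d}"] = self.w_dir[d]
            out[f"b_{d}"] = self.b_dir[d]
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.w_mix = state["w_mix"]
        self.b_mix = state["b_mix"]
        for d in DIRECTIONS:
            self.w_dir[d] = state[f"w_{d}"]
            self.b_dir[d] = state[f"b_{d}"]


def compute_directional_logits(
    f: np.ndarray, params: DirectionalAttentionParams
) -> dict[str, np.ndarray]:
    """Score a feature map, returning one logit array per direction.

    The hidden representation ``h`` is a 1x1 learned mixing of the input;
    each direction's logits are a further 1x1 linear scoring of ``h``.
    Deterministic given (f, params); output shapes equal ``f.shape``.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.shape[-1] != params.n_channels:
        raise ValueError(
            f"feature map has {f.shape[-1]} channels but params expect {params.n_channels}"
        )
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map contains non-finite entries")
    h = f @ params.w_mix + params.b_mix
    return {d: h @ params.w_dir[d] + params.b_dir[d] for d in DIRECTIONS}


def _map_axes(ndim: int) -> tuple[int, ...]:
    """Axes spanning one map (everything except a leading batch axis)."""
    if ndim == 4:
        return (1, 2, 3)
    return tuple(range(ndim))


def normalize_direction(e: np.ndarray, direction: str) -> np.ndarray:
    """Softmax the logits along the direction's axis, then rescale to [0, 1].

    The rescaling divides each map by its maximum so thresholds in (0, 1)
    are meaningful regardless of the softmax axis length.
    """
    e = np.asarray(e, dtype=np.float64)
    axis = direction_axis(direction, e.ndim)
    shifted = e - e.max(axis=axis, keepdims=True)
    ex = np.exp(shifted)
    sm = ex / ex.sum(axis=axis, keepdims=True)
    peak = sm.max(axis=_map_axes(e.ndim), keepdims=True)
    return sm / peak


def softmax_direction(e: np.ndarray, direction: str) -> np.ndarray:
    """The pre-rescale softmax along the direction's axis (sums to 1)."""
    e = np.asarray(e, dtype=np.float64)
    axis = direction_axis(direction, e.ndim)
    shifted = e - e.max(axis=axis, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=axis, keepdims=True)


def attention_weights(f: np.ndarray, params: DirectionalAttentionParams) -> DirectionalWeights:
    """Full pipeline: logits -> per-direction softmax -> max-rescale."""
    logits = compute_directional_logits(f, params)
    return DirectionalWeights(
        a_h=normalize_direction(logits["H"], "H"),
        a_v=normalize_direction(logits["V"], "V"),
        a_d=normalize_direction(logits["D"], "D"),
    )
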