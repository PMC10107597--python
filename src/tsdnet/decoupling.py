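"""Semantic-guided decoupling: combined-magnitude screening.

The three directional weight maps are collapsed into a single combined
magnitude — the elementwise Euclidean norm, bounded by sqrt(3) — which
is thresholded twice: at ``t1`` to screen the shallow feature map and at
``t3`` to screen the deep one. Because sqrt(a^2 + ...) >= a, a point
whose weight in any single direction clears the threshold always
survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import DirectionalWeights

SQRT3 = float(np.sqrt(3.0))


@dataclass
class CombinedWeights:
    """Shallow (s_hvd) and deep (d_hvd) combined magnitudes; identical by
    construction, kept as two fields because they are thresholded
    independently."""

    s_hvd: np.ndarray
    d_hvd: np.ndarray


def combined_magnitude(w: DirectionalWeights) -> CombinedWeights:
    """Elementwise Euclidean norm of (a_H, a_V, a_D); range [0, sqrt(3)]."""
    c = np.sqrt(w.a_h ** 2 + w.a_v ** 2 + w.a_d ** 2)
    return CombinedWeights(s_hvd=c, d_hvd=c.copy())


def threshold_mask(c: np.ndarray, t: float) -> np.ndarray:
    """Binary mask: 1 where c >= t (equality retains, mirroring the dual gate)."""
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    return (np.asarray(c) >= t).astype(np.int8)


def screen_features(mask: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Hard elementwise gating of a feature map by a binary mask.

    The mask may match ``f`` exactly or omit the channel axis, in which
    case it broadcasts across channels.
    """
    f = np.asarray(f, dtype=np.float64)
    mask = np.asarray(mask)
    if mask.shape == f.shape:
        return f * mask
    if mask.ndim == f.ndim - 1 and mask.shape == f.shape[:-1]:
        return f * mask[..., None]
    if mask.ndim == f.ndim and mask.shape[:-1] == f.shape[:-1] and mask.shape[-1] == 1:
        return f * mask
    raise ValueError(f"mask shape {mask.shape} incompatible with feature shape {f.shape}")
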