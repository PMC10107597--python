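"""Cross feature screening: dual-gate masks and level features.

The three directional weight maps are combined in pairs (arithmetic
mean), cross-averaged per branch, and compared to two gate thresholds.
Every feature point is classified as important (mean >= t1), secondary
(t2 <= mean < t1) or redundant (mean < t2); the three resulting 0-1
masks partition the map exactly. Gated copies of the input feature map
are concatenated along the channel axis into the three level features,
so each level has triple the input channel count.

Tie rule: a mean exactly at t1 is important; exactly at t2, secondary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import DirectionalWeights

BRANCHES = ("HV", "HD", "VD")


class ScreeningError(ValueError):
    pass


@dataclass
class PairedWeights:
    """Pairwise means a_HV, a_HD, a_VD of the directional weights."""

    a_hv: np.ndarray
    a_hd: np.ndarray
    a_vd: np.ndarray

    def __post_init__(self):
        shapes = {self.a_hv.shape, self.a_hd.shape, self.a_vd.shape}
        if len(shapes) != 1:
            raise ScreeningError(f"paired weights must share a shape, got {shapes}")

    def get(self, branch: str) -> np.ndarray:
        try:
            return {"HV": self.a_hv, "HD": self.a_hd, "VD": self.a_vd}[branch]
        except KeyError:
            raise ScreeningError(f"unknown branch {branch!r}") from None


@dataclass
class GateMaskTriple:
    """Binary masks (important, secondary, redundant) partitioning a map."""

    m_imp: np.ndarray
    m_sec: np.ndarray
    m_red: np.ndarray

    def __post_init__(self):
        for m in (self.m_imp, self.m_sec, self.m_red):
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0, 1))):
                raise ScreeningError("masks must be binary")
        total = self.m_imp + self.m_sec + self.m_red
        if not np.all(total == 1):
            raise ScreeningError("masks must partition: m_imp + m_sec + m_red == 1")

    def as_tuple(self):
        return (self.m_imp, self.m_sec, self.m_red)


@dataclass
class LevelFeatures:
    """Channel-concatenated gated features, one map per screening level."""

    f1: np.ndarray  # important
    f2: np.ndarray  # secondary
    f3: np.ndarray  # redundant


def pair_weights(w: DirectionalWeights) -> PairedWeights:
    """Elementwise mean of each unordered pair of directional weights."""
    return PairedWeights(
        a_hv=(w.a_h + w.a_v) / 2.0,
        a_hd=(w.a_h + w.a_d) / 2.0,
        a_vd=(w.a_v + w.a_d) / 2.0,
    )


#: branch -> the two paired maps its cross-mean averages, as printed.
_CROSS = {"HV": ("HV", "HD"), "HD": ("HD", "VD"), "VD": ("VD", "HV")}


def cross_mean(p: PairedWeights, branch: str, mode: str = "printed") -> np.ndarray:
    """The mean matrix a given branch is gated on.

    mode="printed": HV -> (a_HV + a_HD)/2, HD -> (a_HD + a_VD)/2,
    VD -> (a_VD + a_HV)/2. mode="branch": each branch gates on its own
    paired map directly (the alternative reading).
    """
    if branch not in BRANCHES:
        raise ScreeningError(f"unknown branch {branch!r}; expected one of {BRANCHES}")
    if mode == "printed":
        x, y = _CROSS[branch]
        return (p.get(x) + p.get(y)) / 2.0
    if mode == "branch":
        return p.get(branch)
    raise ScreeningError(f"unknown cross-mean mode {mode!r}")


def dual_gate_masks(mean: np.ndarray, t1: float, t2: float) -> GateMaskTriple:
    """Partition every position by the two gates.

    mean >= t1 -> important; t2 <= mean < t1 -> secondary;
    mean < t2 -> redundant.
    """
    if t2 >= t1:
        raise ScreeningError(f"thresholds must satisfy t2 < t1, got t1={t1}, t2={t2}")
    mean = np.asarray(mean)
    m_imp = (mean >= t1).astype(np.int8)
    m_red = (mean < t2).astype(np.int8)
    m_sec = ((mean >= t2) & (mean < t1)).astype(np.int8)
    return GateMaskTriple(m_imp=m_imp, m_sec=m_sec, m_red=m_red)


def _align_mask(mask: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Broadcast a per-pixel mask across the channel axis if needed."""
    if mask.ndim == f.ndim:
        if mask.shape != f.shape:
            raise ScreeningError(f"mask shape {mask.shape} != feature shape {f.shape}")
        return mask
    if mask.ndim == f.ndim - 1 and mask.shape == f.shape[:-1]:
        return mask[..., None]
    raise ScreeningError(f"mask shape {mask.shape} incompatible with feature shape {f.shape}")


def apply_masks(f: np.ndarray, g: GateMaskTriple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gate a feature map by each of the three masks (hard zeroing)."""
    f = np.asarray(f, dtype=np.float64)
    return tuple(f * _align_mask(m, f) for m in g.as_tuple())


def assemble_levels(branch_outputs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]) -> LevelFeatures:
    """Concatenate the nine gated maps into f1/f2/f3 (channel axis, HV|HD|VD order)."""
    for b in BRANCHES:
        if b not in branch_outputs:
            raise ScreeningError(f"missing branch {b!r}")
    spatial = {branch_outputs[b][k].shape[:-1] for b in BRANCHES for k in range(3)}
    if len(spatial) != 1:
        raise ScreeningError(f"inconsistent spatial shapes: {spatial}")
    levels = [
        np.concatenate([branch_outputs[b][k] for b in BRANCHES], axis=-1) for k in range(3)
    ]
    return LevelFeatures(f1=levels[0], f2=levels[1], f3=levels[2])


def branch_masks(
    w: DirectionalWeights,
    t1: float,
    t2: float,
    mode: str = "printed",
    per_pixel: bool = True,
) -> dict[str, GateMaskTriple]:
    """Gate masks per branch: pair -> cross-mean -> dual gates.

    With ``per_pixel`` the cross-mean is averaged over channels before
    gating, so each branch mask is spatial and broadcasts across the
    channel axis (weights act as spatial weight matrices).
    """
    p = pair_weights(w)
    masks: dict[str, GateMaskTriple] = {}
    for b in BRANCHES:
        mean = cross_mean(p, b, mode=mode)
        if per_pixel and mean.ndim >= 3:
            mean = mean.mean(axis=-1)
        masks[b] = dual_gate_masks(mean, t1, t2)
    return masks


def screen_levels(
    w: DirectionalWeights,
    f: np.ndarray,
    t1: float,
    t2: float,
    mode: str = "printed",
    per_pixel: bool = True,
) -> tuple[LevelFeatures, dict[str, GateMaskTriple]]:
    """Full chain: pair -> cross-mean -> dual gates -> gated levels."""
    masks = branch_masks(w, t1, t2, mode=mode, per_pixel=per_pixel)
    outputs = {b: apply_masks(f, masks[b]) for b in BRANCHES}
    return assemble_levels(outputs), masks
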