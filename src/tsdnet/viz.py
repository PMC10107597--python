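"""Nine-tile attention heatmap panel for a single image.

Tiles: original image, deep feature (channel mean of the shallow map),
the three directional weight grids, the three branch cross-mean grids,
and the combined-magnitude grid. Every numeric grid is also dumped as
CSV; the combined grid is computed from the dumped directional grids, so
the CSVs alone reproduce it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .attention import DirectionalWeights
from .decoupling import combined_magnitude
from .fusion import TSDNet
from .screening import cross_mean, pair_weights

TILE_ORDER = (
    "original",
    "deep_feature",
    "a_V",
    "a_H",
    "a_D",
    "cross_HV",
    "cross_HD",
    "cross_VD",
    "combined_HVD",
)


def panel_grids(model: TSDNet, image: np.ndarray) -> dict[str, np.ndarray]:
    """All nine 2-D grids keyed by tile name."""
    probs, details = model.forward(image[None])
    fx = details["f_x"].data[0]
    w = details["weights"]
    reduced = DirectionalWeights(
        a_h=w.a_h[0].mean(axis=-1),
        a_v=w.a_v[0].mean(axis=-1),
        a_d=w.a_d[0].mean(axis=-1),
    )
    paired = pair_weights(reduced)
    grids = {
        "original": image.mean(axis=-1),
        "deep_feature": fx.mean(axis=-1),
        "a_V": reduced.a_v,
        "a_H": reduced.a_h,
        "a_D": reduced.a_d,
        "cross_HV": cross_mean(paired, "HV"),
        "cross_HD": cross_mean(paired, "HD"),
        "cross_VD": cross_mean(paired, "VD"),
        "combined_HVD": combined_magnitude(reduced).s_hvd,
    }
    return grids


def render_panel(model: TSDNet, image: np.ndarray, out_png: str | Path,
                 csv_dir: str | Path | None = None) -> dict[str, np.ndarray]:
    """Render the 3x3 panel and dump each grid as CSV; returns the grids."""
    grids = panel_grids(model, image)
    fig, axes = plt.subplots(3, 3, figsize=(9, 9))
    for ax, name in zip(axes.ravel(), TILE_ORDER):
        cmap = "gray" if name == "original" else "jet"
        ax.imshow(grids[name], cmap=cmap)
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    out_png = Path(out_png)
    out_png.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    if csv_dir is not None:
        csv_dir = Path(csv_dir)
        csv_dir.mkdir(parents=True, exist_ok=True)
        for name, grid in grids.items():
            np.savetxt(csv_dir / f"{name}.csv", grid, delimiter=",")
    return grids
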