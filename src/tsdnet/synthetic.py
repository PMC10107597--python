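"""Deterministic synthetic image datasets and the 7:1:2 split.

Three structure families give class-dependent content:

* ``blob-count`` — class ``k`` has ``k + 1`` bright Gaussian blobs at
  well-separated seeded positions (so a peak detector recovers the count
  on noiseless images);
* ``texture-frequency`` — a 2-D sinusoidal grating whose frequency grows
  with the class index;
* ``ring-lesion`` — a centred annulus whose radius grows with the class.

Images are grayscale replicated to three channels, quantized to uint8
before any use, and byte-identical across runs with the same spec.
Per-class counts can be skewed with imbalance weights to emulate small
clinical collections (e.g. 336/326 two-class, or a 7-class long tail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

FAMILIES = ("blob-count", "texture-frequency", "ring-lesion")

#: class-count skews loosely mirroring the three reference collections
PRESET_WEIGHTS = {
    "two-class": (336 / 331.0, 326 / 331.0),
    "three-class": (1345 / 1295.3, 1341 / 1295.3, 1200 / 1295.3),
    "seven-class": (1113 / 1430.7, 6705 / 1430.7, 514 / 1430.7, 327 / 1430.7,
                    1099 / 1430.7, 115 / 1430.7, 142 / 1430.7),
}


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_classes: int = 3
    images_per_class: int = 50
    image_size: int = 256
    family: str = "blob-count"
    noise_std: float = 0.05
    imbalance: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.n_classes <= 7):
            raise ValueError("n_classes must be in [2, 7]")
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.imbalance is not None:
            if len(self.imbalance) != self.n_classes:
                raise ValueError("imbalance weights must have one entry per class")
            if any(w <= 0 for w in self.imbalance):
                raise ValueError("imbalance weights must be positive")

    def class_counts(self) -> list[int]:
        if self.imbalance is None:
            return [self.images_per_class] * self.n_classes
        return [max(1, round(self.images_per_class * w)) for w in self.imbalance]


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _blob_image(rng: np.random.Generator, size: int, n_blobs: int) -> np.ndarray:
    sigma = size / 16.0
    margin = int(2 * sigma) + 1
    min_sep = 4.2 * sigma
    centers: list[tuple[float, float]] = []
    while len(centers) < n_blobs:
        cy, cx = rng.uniform(margin, size - margin, size=2)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep ** 2 for y, x in centers):
            centers.append((cy, cx))
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.full((size, size), 0.05)
    for cy, cx in centers:
        img += 0.7 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2)))
    return img


def _texture_image(rng: np.random.Generator, size: int, class_id: int) -> np.ndarray:
    freq = 2.0 + 2.0 * class_id
    phase_y, phase_x = rng.uniform(0, 2 * np.pi, size=2)
    yy, xx = np.mgrid[0:size, 0:size] / size
    img = 0.5 + 0.4 * np.sin(2 * np.pi * freq * yy + phase_y) * np.sin(
        2 * np.pi * freq * xx + phase_x
    )
    return img


def _ring_image(rng: np.random.Generator, size: int, class_id: int) -> np.ndarray:
    radius = size * (0.12 + 0.05 * class_id)
    thickness = size * 0.03
    jitter = size * 0.04
    cy, cx = size / 2 + rng.uniform(-jitter, jitter, size=2)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    img = 0.08 + 0.75 * np.exp(-(((r - radius) / thickness) ** 2) / 2)
    return img


def _render(spec: SyntheticDatasetSpec, rng: np.random.Generator, class_id: int) -> np.ndarray:
    if spec.family == "blob-count":
        img = _blob_image(rng, spec.image_size, class_id + 1)
    elif spec.family == "texture-frequency":
        img = _texture_image(rng, spec.image_size, class_id)
    else:
        img = _ring_image(rng, spec.image_size, class_id)
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_arrays(spec: SyntheticDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """All images as a float tensor in [0, 1] plus integer labels.

    Shape ``(N, size, size, 3)``; grayscale replicated to 3 channels and
    quantized through uint8 so in-memory use matches what PNGs round-trip.
    """
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for class_id, count in enumerate(spec.class_counts()):
        for _ in range(count):
            img = _render(spec, rng, class_id)
            q = np.round(img * 255.0).astype(np.uint8)
            images.append(np.repeat(q[..., None], 3, axis=-1))
            labels.append(class_id)
    x = np.stack(images).astype(np.float64) / 255.0
    return x, np.asarray(labels, dtype=np.int64)


def generate_dataset(spec: SyntheticDatasetSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write PNGs and a labels table; byte-identical across runs per seed."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for class_id, count in enumerate(spec.class_counts()):
        for i in range(count):
            img = _render(spec, rng, class_id)
            q = np.round(img * 255.0).astype(np.uint8)
            name = f"class{class_id}_{i:05d}.png"
            Image.fromarray(q, mode="L").save(out_dir / "images" / name)
            rows.append({"filename": name, "class_id": class_id,
                         "class_name": f"class{class_id}"})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "labels.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_counts(n: int, ratios=(7, 1, 2)) -> tuple[int, int, int]:
    """Floor-then-remainder split of `n` items: floor for train and val,
    remainder to test."""
    total = sum(ratios)
    n_train = int(np.floor(n * ratios[0] / total))
    n_val = int(np.floor(n * ratios[1] / total))
    return n_train, n_val, n - n_train - n_val


def split_dataset(labels, ratios=(7, 1, 2), seed: int = 0) -> np.ndarray:
    """Stratified assignment of each item to train/val/test.

    ``labels`` is the per-item class vector; returns an object array of
    split names aligned to it. Classes with fewer items than split
    buckets go entirely to train, with a warning.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("split ratios must be positive")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=object)
    for class_id in np.unique(labels):
        idx = np.flatnonzero(labels == class_id)
        if len(idx) < len(ratios):
            warnings.warn(
                f"class {class_id} has {len(idx)} item(s), fewer than {len(ratios)} "
                "splits; assigning all to train",
                stacklevel=2,
            )
            assignment[idx] = "train"
            continue
        perm = rng.permutation(idx)
        n_train, n_val, _ = split_counts(len(idx), ratios)
        assignment[perm[:n_train]] = "train"
        assignment[perm[n_train : n_train + n_val]] = "val"
        assignment[perm[n_train + n_val :]] = "test"
    return assignment


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def resize_bilinear(img: np.ndarray, out_size: int) -> np.ndarray:
    """Align-corners bilinear resample of a 2-D array."""
    h, w = img.shape
    if (h, w) == (out_size, out_size):
        return img.astype(np.float64)
    rows = np.linspace(0, h - 1, out_size)
    cols = np.linspace(0, w - 1, out_size)
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(img.astype(np.float64), grid, order=1, mode="nearest")


def load_image_folder(path: str | Path, image_size: int) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load a generated (or compatible) folder into tensors.

    Returns ``(images, labels, table)`` with images resized to
    ``image_size`` squared, intensities in [0, 1], ordered by filename.
    """
    path = Path(path)
    labels_file = path / "labels.csv"
    if not labels_file.exists():
        raise FileNotFoundError(f"missing labels table: {labels_file}")
    df = pd.read_csv(labels_file).sort_values("filename").reset_index(drop=True)
    images = []
    for name in df["filename"]:
        fp = path / "images" / name
        try:
            with Image.open(fp) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read image {fp}: {exc}") from exc
        resized = np.stack(
            [resize_bilinear(arr[..., c], image_size) for c in range(3)], axis=-1
        )
        images.append(resized)
    x = np.stack(images) if images else np.zeros((0, image_size, image_size, 3))
    return x, df["class_id"].to_numpy(dtype=np.int64), df
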