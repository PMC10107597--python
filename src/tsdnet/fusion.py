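"""Fusion head and the end-to-end classifier graph.

The model wires a small strided-conv backbone to the directional
attention, screening and decoupling stages, then fuses the screened
features into class logits:

* ``fuse_mid`` maps the important, redundant and shallow-screened maps
  to ``d_fuse``-length vectors and adds them.
* ``fuse_deep`` re-expands the shallow-screened map, 1-D-convolves the
  fused vector, and concatenates both with the deep-screened map along a
  sequence axis.
* ``classify`` applies a 1-D convolution plus an affine map and softmax.

Gate masks are computed outside the autodiff graph and enter it as
constants, so positions a mask eliminates contribute exactly zero to
every downstream sum and pass no gradient — screening is hard discard,
not soft attenuation. A consequence is that the attention projections
themselves receive no gradient and stay at their seeded initialization.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .attention import DirectionalAttentionParams, attention_weights
from .autograd import Tensor
from .config import ConfigurationError, ModelConfig
from .decoupling import combined_magnitude, threshold_mask
from .layers import Conv1D, Conv2D, Dense, Layer
from .screening import BRANCHES, branch_masks

KNOCKOUTS = ("f_cg", "f_1", "f_2", "f_3")


def _zeros_like(t: Tensor) -> Tensor:
    return ag.constant(np.zeros(t.shape))


class FusionHead(Layer):
    """The three fusion stages; all widths derived from the config."""

    def __init__(self, rng: np.random.Generator, cfg: ModelConfig, m: int, c: int, c_cg: int):
        super().__init__()
        self.cfg = cfg
        self.m = m
        self.c = c
        n_spatial = m * m
        self.conv_f1 = Conv2D(rng, 3 * c, c, k=3, stride=1)
        self.dense_f1 = Dense(rng, n_spatial * c, cfg.d_fuse)
        self.dense_f3 = Dense(rng, n_spatial * 3 * c, cfg.d_fuse)
        self.dense_cg_mid = Dense(rng, n_spatial * c_cg, cfg.d_fuse)
        self.dense_cg_deep = Dense(rng, n_spatial * c_cg, cfg.d_fuse)
        self.conv_fm = Conv1D(rng, 1, 1, k=cfg.conv1d_kernel)
        self.seq_len = 2 * cfg.d_fuse + n_spatial * c
        self.conv_out = Conv1D(rng, 1, cfg.fusion_conv_channels, k=cfg.conv1d_kernel)
        self.dense_out = Dense(rng, self.seq_len * cfg.fusion_conv_channels, cfg.n_classes)
        for sub in (self.conv_f1, self.dense_f1, self.dense_f3, self.dense_cg_mid,
                    self.dense_cg_deep, self.conv_fm, self.conv_out, self.dense_out):
            self.params.extend(sub.params)

    def _flat(self, t: Tensor) -> Tensor:
        return ag.reshape(t, (t.shape[0], -1))

    def fuse_mid(self, f1: Tensor, f3: Tensor, f_cg: Tensor) -> Tensor:
        """f_m = affine(flat(f3)) + affine(flat(conv(f1))) + affine(flat(f_cg))."""
        f3p = self.dense_f3(self._flat(f3))
        f1p = self.dense_f1(self._flat(ag.relu(self.conv_f1(f1))))
        cg = self.dense_cg_mid(self._flat(f_cg))
        return ag.add(ag.add(f3p, f1p), cg)

    def fuse_deep(self, f_cg: Tensor, f_m: Tensor, f_cg_deep: Tensor) -> Tensor:
        """Concatenate the three re-shaped streams along a sequence axis."""
        b = f_m.shape[0]
        cg2 = ag.reshape(self.dense_cg_deep(self._flat(f_cg)), (b, self.cfg.d_fuse, 1))
        fm1 = self.conv_fm(ag.reshape(f_m, (b, self.cfg.d_fuse, 1)))
        cg_hat = ag.reshape(f_cg_deep, (b, -1, 1))
        return ag.concat([cg2, fm1, cg_hat], axis=1)

    def classify(self, f_i: Tensor) -> Tensor:
        """Logits O = affine(flat(conv1d(f_i)))."""
        return self.dense_out(self._flat(self.conv_out(f_i)))


class TSDNet:
    """End-to-end stereo-screening classifier.

    Forward pass on ``(B, size, size, in_channels)`` inputs yields a
    ``(B, n_classes)`` probability matrix; `forward` also returns the
    intermediate features for inspection and visualization.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone: list[Conv2D] = []
        c_in = cfg.in_channels
        m = cfg.image_size
        for width in cfg.backbone_widths:
            self.backbone.append(Conv2D(rng, c_in, width, k=3, stride=2))
            c_in = width
            m = -(-m // 2)
        self.m = m
        self.c = c_in
        self.attention = DirectionalAttentionParams(
            self.c, seed=cfg.seed + 1, shared=cfg.shared_direction_params
        )
        self.deep_block = Conv2D(rng, 3 * self.c, self.c, k=3, stride=1)
        c_cg = 3 * self.c if cfg.deep_gate_source == "f1" else self.c
        self.head = FusionHead(rng, cfg, self.m, self.c, c_cg)
        self.params: list[Tensor] = []
        for conv in self.backbone:
            self.params.extend(conv.params)
        self.params.extend(self.deep_block.params)
        self.params.extend(self.head.params)

    # -- introspection ----------------------------------------------
    def n_parameters(self) -> int:
        trainable = sum(p.data.size for p in self.params)
        frozen = sum(v.size for v in self.attention.state().values())
        return trainable + frozen

    def summary_rows(self) -> list[tuple[str, str, int]]:
        rows = []
        for i, conv in enumerate(self.backbone):
            rows.append((f"backbone{i}", str(conv.w.shape), sum(p.data.size for p in conv.params)))
        rows.append(("attention", "frozen", sum(v.size for v in self.attention.state().values())))
        rows.append(("deep_block", str(self.deep_block.w.shape),
                     sum(p.data.size for p in self.deep_block.params)))
        rows.append(("fusion_head", "-", sum(p.data.size for p in self.head.params)))
        return rows

    # -- forward -----------------------------------------------------
    def forward(self, x: np.ndarray, knockout: frozenset[str] | set[str] = frozenset()):
        """Run the full graph; returns (probabilities, details dict).

        ``knockout`` names branches in {"f_cg", "f_1", "f_2", "f_3"} whose
        feature maps are replaced by zeros of matching shape.
        """
        knockout = frozenset(knockout)
        bad = knockout - set(KNOCKOUTS)
        if bad:
            raise ConfigurationError(f"unknown knockout(s): {sorted(bad)}")
        if knockout >= set(KNOCKOUTS):
            raise ConfigurationError("cannot knock out every feature branch")
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (self.cfg.image_size, self.cfg.image_size, self.cfg.in_channels):
            raise ConfigurationError(
                f"input shape {x.shape[1:]} does not match config "
                f"({self.cfg.image_size}, {self.cfg.image_size}, {self.cfg.in_channels})"
            )
        th = self.cfg.thresholds

        t = ag.constant(x)
        for conv in self.backbone:
            t = ag.relu(conv(t))
        fx = t  # (B, m, m, C)

        # Attention weights and all gate masks live outside the autodiff
        # graph: hard gates pass no gradient.
        weights = attention_weights(fx.data, self.attention)
        masks = branch_masks(weights, th.t1, th.t2,
                             mode=self.cfg.branch_mean_mode,
                             per_pixel=self.cfg.per_pixel_masks)

        def gated(mask_arr: np.ndarray) -> Tensor:
            m = mask_arr.astype(np.float64)
            if m.ndim == fx.ndim - 1:
                m = m[..., None]
            return ag.mul(fx, ag.constant(m))

        level_parts = {k: [] for k in range(3)}
        for b in BRANCHES:
            triple = masks[b].as_tuple()
            for k in range(3):
                level_parts[k].append(gated(triple[k]))
        f1 = ag.concat(level_parts[0], axis=-1)
        f2 = ag.concat(level_parts[1], axis=-1)
        f3 = ag.concat(level_parts[2], axis=-1)
        if "f_1" in knockout:
            f1 = _zeros_like(f1)
        if "f_2" in knockout:
            f2 = _zeros_like(f2)
        if "f_3" in knockout:
            f3 = _zeros_like(f3)

        combined = combined_magnitude(weights)
        s_mask = threshold_mask(combined.s_hvd, th.t1).astype(np.float64)
        d_mask = threshold_mask(combined.d_hvd, th.t3).astype(np.float64)

        if self.cfg.deep_gate_source == "f1":
            f_cg = ag.mul(f1, ag.constant(np.concatenate([s_mask] * 3, axis=-1)))
        else:
            f_cg = ag.mul(fx, ag.constant(s_mask))
        if "f_cg" in knockout:
            f_cg = _zeros_like(f_cg)

        fy = ag.relu(self.deep_block(f2))
        f_cg_deep = ag.mul(fy, ag.constant(d_mask))

        f_m = self.head.fuse_mid(f1, f3, f_cg)
        f_i = self.head.fuse_deep(f_cg, f_m, f_cg_deep)
        logits = self.head.classify(f_i)
        probs = ag.softmax(logits, axis=1)

        details = {
            "f_x": fx,
            "weights": weights,
            "masks": masks,
            "combined": combined,
            "f_1": f1,
            "f_2": f2,
            "f_3": f3,
            "f_cg": f_cg,
            "f_y": fy,
            "f_cg_deep": f_cg_deep,
            "f_m": f_m,
            "f_i": f_i,
            "logits": logits,
        }
        return probs, details

    def predict(self, x: np.ndarray, batch_size: int = 32,
                knockout: frozenset[str] | set[str] = frozenset()) -> np.ndarray:
        """Class labels for a batch of images, computed in chunks."""
        x = np.asarray(x, dtype=np.float64)
        out = []
        for i in range(0, len(x), batch_size):
            probs, _ = self.forward(x[i : i + batch_size], knockout=knockout)
            out.append(probs.data.argmax(axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)

    # -- serialization -----------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        out = {f"param_{i}": p.data for i, p in enumerate(self.params)}
        for k, v in self.attention.state().items():
            out[f"attention_{k}"] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            arr = np.asarray(state[f"param_{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ConfigurationError(
                    f"checkpoint shape mismatch at param_{i}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr
        att = {k[len("attention_"):]: np.asarray(v) for k, v in state.items()
               if k.startswith("attention_")}
        self.attention.load_state(att)

    def save(self, path) -> None:
        np.savez(path, **self.state())

    @classmethod
    def load(cls, path, cfg: ModelConfig) -> "TSDNet":
        model = cls(cfg)
        with np.load(path) as data:
            model.load_state({k: data[k] for k in data.files})
        return model


def build_model(cfg: ModelConfig) -> TSDNet:
    """Construct the wired end-to-end model from a validated config."""
    return TSDNet(cfg)


def small_config(n_classes: int = 3, seed: int = 0, **overrides) -> ModelConfig:
    """The reduced desk-scale configuration (64x64, widths 8/16/32, d_fuse 64)."""
    base = dict(
        image_size=64,
        backbone_widths=(8, 16, 32),
        d_fuse=64,
        n_classes=n_classes,
        seed=seed,
    )
    base.update(overrides)
    return ModelConfig(**base)
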