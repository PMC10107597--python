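"""Seeded training and evaluation loops around the model graph."""

from __future__ import annotations

import json
import subprocess
from pathlib import Path

import numpy as np
import pandas as pd

from . import autograd as ag
from . import metrics as mx
from .config import RunConfig, dump_run_config
from .fusion import TSDNet
from .layers import make_optimizer


def train_model(
    model: TSDNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    run_cfg: RunConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    knockout: frozenset[str] = frozenset(),
    verbose: bool = False,
) -> pd.DataFrame:
    """Minibatch training; returns the per-epoch history table."""
    rng = np.random.default_rng(run_cfg.seed)
    opt = make_optimizer(run_cfg.optimizer, model.params, run_cfg.learning_rate)
    n = len(x_train)
    history = []
    for epoch in range(run_cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, run_cfg.batch_size):
            idx = perm[start : start + run_cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs, details = model.forward(xb, knockout=knockout)
            loss = ag.softmax_cross_entropy(details["logits"], yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((probs.data.argmax(axis=1) == yb).sum())
        row = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "train_oa": correct / n,
        }
        if x_val is not None and len(x_val):
            preds = model.predict(x_val, batch_size=run_cfg.batch_size, knockout=knockout)
            row["val_oa"] = float((preds == y_val).mean())
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: " + " ".join(f"{k}={v:.4f}" for k, v in row.items() if k != "epoch"))
    return pd.DataFrame(history)


def evaluate_model(
    model: TSDNet,
    x: np.ndarray,
    y: np.ndarray,
    batch_size: int = 32,
    knockout: frozenset[str] = frozenset(),
) -> tuple[np.ndarray, dict[str, float]]:
    """Confusion matrix and the metrics report on a labelled set."""
    preds = model.predict(x, batch_size=batch_size, knockout=knockout)
    cm = mx.confusion_matrix(y, preds, model.cfg.n_classes)
    return cm, mx.report(cm)


def _git_describe() -> str:
    try:
        out = subprocess.run(
            ["git", "describe", "--always", "--dirty"],
            capture_output=True, text=True, timeout=10, check=False,
        )
        return out.stdout.strip() or "unknown"
    except OSError:
        return "unknown"


def write_run_artifacts(
    out_dir: str | Path,
    run_cfg: RunConfig,
    model: TSDNet,
    history: pd.DataFrame,
    cm: np.ndarray,
    rep: dict[str, float],
) -> Path:
    """Persist everything a run must leave behind: config snapshot, seed,
    git-describe, per-epoch CSV, checkpoint, confusion matrix, metrics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dump_run_config(run_cfg, out_dir / "config.yaml")
    (out_dir / "seed.txt").write_text(f"{run_cfg.seed}\n")
    (out_dir / "git_describe.txt").write_text(_git_describe() + "\n")
    history.to_csv(out_dir / "history.csv", index=False)
    model.save(out_dir / "checkpoint.npz")
    np.savetxt(out_dir / "confusion.csv", np.asarray(cm), fmt="%d", delimiter=",")
    (out_dir / "metrics.json").write_text(json.dumps(rep, indent=2, sort_keys=True) + "\n")
    return out_dir
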