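"""Classification agreement metrics from a confusion matrix.

Rows are true classes, columns predictions. ``kappa`` has two modes:

* ``"printed"`` — the literal published formula, whose expected-agreement
  term is ``sum(n_i * m_i) / S**2`` over raw counts (``n_i`` diagonal,
  ``m_i`` row total). It is not scale-invariant and can leave the [0, 1]
  range for large counts; it is kept verbatim for fidelity.
* ``"standard"`` — Cohen's kappa with expected agreement
  ``sum(row_i * col_i) / N**2``.

Both return exactly 1 on a perfect unit-count diagonal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

KAPPA_MODES = ("printed", "standard")


class MetricsError(ValueError):
    pass


def _validate(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 1:
        raise MetricsError(f"confusion matrix must be square, got shape {cm.shape}")
    if np.any(cm < 0):
        raise MetricsError("confusion matrix entries must be non-negative")
    return cm.astype(np.float64)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Integer S x S count matrix (rows true, columns predicted)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise MetricsError("label arrays must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def overall_accuracy(cm) -> float:
    """Trace over total count."""
    cm = _validate(cm)
    total = cm.sum()
    if total == 0:
        raise MetricsError("empty confusion matrix")
    return float(np.trace(cm) / total)


def average_accuracy(cm) -> float:
    """Mean per-class recall; every class must have at least one sample."""
    cm = _validate(cm)
    row = cm.sum(axis=1)
    if np.any(row == 0):
        bad = np.flatnonzero(row == 0).tolist()
        raise MetricsError(f"classes with no samples: {bad}")
    return float(np.mean(np.diag(cm) / row))


def kappa(cm, mode: str = "printed") -> float:
    """Chance-corrected agreement; see module docstring for the two modes."""
    cm = _validate(cm)
    if mode not in KAPPA_MODES:
        raise MetricsError(f"unknown kappa mode {mode!r}; expected one of {KAPPA_MODES}")
    oa = overall_accuracy(cm)
    s = cm.shape[0]
    if mode == "printed":
        n_i = np.diag(cm)
        m_i = cm.sum(axis=1)
        pe = float((n_i * m_i).sum() / (s * s))
    else:
        n = cm.sum()
        pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum() / (n * n))
    if pe == 1.0:
        raise MetricsError("expected agreement equals 1; kappa undefined")
    return float((oa - pe) / (1.0 - pe))


def report(cm) -> dict[str, float]:
    """OA, AA and both kappa variants in one dict."""
    return {
        "oa": overall_accuracy(cm),
        "aa": average_accuracy(cm),
        "kappa_printed": kappa(cm, "printed"),
        "kappa_standard": kappa(cm, "standard"),
    }


def write_report(cm, out_dir: str | Path, prefix: str = "metrics") -> dict[str, float]:
    """Write confusion matrix CSV and metrics JSON; return the metrics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm = np.asarray(cm)
    np.savetxt(out_dir / f"{prefix}_confusion.csv", cm, fmt="%d", delimiter=",")
    rep = report(cm)
    (out_dir / f"{prefix}.json").write_text(json.dumps(rep, indent=2, sort_keys=True) + "\n")
    return rep
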