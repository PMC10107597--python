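"""Independent pure-loop reference implementations used by the tests.

Deliberately written element-by-element with plain Python loops so they
share no code path with the vectorized package implementations.
"""

from __future__ import annotations

import math

import numpy as np


def loop_softmax(e: np.ndarray, axis: int) -> np.ndarray:
    """Elementwise exp/sum softmax along one axis, via explicit loops."""
    e = np.asarray(e, dtype=np.float64)
    moved = np.ascontiguousarray(np.moveaxis(e, axis, -1))
    out = np.empty_like(moved)
    flat = moved.reshape(-1, moved.shape[-1])
    oflat = out.reshape(-1, moved.shape[-1])
    for r in range(flat.shape[0]):
        mx = max(flat[r])
        exps = [math.exp(v - mx) for v in flat[r]]
        s = 0.0
        for v in exps:
            s += v
        for c, v in enumerate(exps):
            oflat[r, c] = v / s
    return np.moveaxis(out, -1, axis)


def seq_mean(values) -> float:
    """Sequential left-to-right mean."""
    s = 0.0
    for v in values:
        s += v
    return s / len(values)


def loop_cfsm(a_h, a_v, a_d, f, t1, t2, mode="printed", per_pixel=True):
    """Per-element pair -> cross-mean -> dual-gate -> apply chain.

    Returns (f1, f2, f3) with channel-concatenated branches in HV, HD,
    VD order, exactly like the package pipeline.
    """
    hh, ww, cc = f.shape
    pairs = {}
    for name, (x, y) in {"HV": (a_h, a_v), "HD": (a_h, a_d), "VD": (a_v, a_d)}.items():
        arr = np.empty_like(f)
        for i in range(hh):
            for j in range(ww):
                for k in range(cc):
                    arr[i, j, k] = (x[i, j, k] + y[i, j, k]) / 2.0
        pairs[name] = arr
    cross_src = {"HV": ("HV", "HD"), "HD": ("HD", "VD"), "VD": ("VD", "HV")}
    levels = [[], [], []]
    for branch in ("HV", "HD", "VD"):
        if mode == "printed":
            x, y = cross_src[branch]
            mean3 = np.empty_like(f)
            for i in range(hh):
                for j in range(ww):
                    for k in range(cc):
                        mean3[i, j, k] = (pairs[x][i, j, k] + pairs[y][i, j, k]) / 2.0
        else:
            mean3 = pairs[branch]
        gated = [np.zeros_like(f) for _ in range(3)]
        for i in range(hh):
            for j in range(ww):
                if per_pixel:
                    m = seq_mean([mean3[i, j, k] for k in range(cc)])
                    levels_at = [_gate_level(m, t1, t2)] * cc
                else:
                    levels_at = [_gate_level(mean3[i, j, k], t1, t2) for k in range(cc)]
                for k in range(cc):
                    gated[levels_at[k]][i, j, k] = f[i, j, k]
        for lvl in range(3):
            levels[lvl].append(gated[lvl])
    return tuple(np.concatenate(levels[lvl], axis=-1) for lvl in range(3))


def _gate_level(m: float, t1: float, t2: float) -> int:
    if m >= t1:
        return 0  # important
    if m >= t2:
        return 1  # secondary
    return 2  # redundant


def loop_sgdm(a_h, a_v, a_d, f_shallow, f_deep, t1, t3):
    """Per-element combined magnitude plus the two screenings."""
    hh, ww, cc = f_shallow.shape
    f_cg = np.zeros_like(f_shallow)
    f_cg_deep = np.zeros_like(f_deep)
    combined = np.empty((hh, ww, cc))
    for i in range(hh):
        for j in range(ww):
            for k in range(cc):
                vh = float(a_h[i, j, k])
                vv = float(a_v[i, j, k])
                vd = float(a_d[i, j, k])
                c = math.sqrt(vh * vh + vv * vv + vd * vd)
                combined[i, j, k] = c
                if c >= t1:
                    f_cg[i, j, k] = f_shallow[i, j, k]
                if c >= t3:
                    f_cg_deep[i, j, k] = f_deep[i, j, k]
    return combined, f_cg, f_cg_deep


def loop_metrics(cm: np.ndarray):
    """OA, AA, printed kappa and Cohen's kappa by explicit summation."""
    cm = np.asarray(cm, dtype=float)
    s = cm.shape[0]
    diag, rows, cols, total = [], [], [], 0.0
    for i in range(s):
        diag.append(cm[i, i])
        r = 0.0
        c = 0.0
        for j in range(s):
            r += cm[i, j]
            c += cm[j, i]
            total += cm[i, j]
        rows.append(r)
        cols.append(c)
    oa = sum(diag) / total
    aa = sum(d / r for d, r in zip(diag, rows)) / s
    pe_printed = sum(d * r for d, r in zip(diag, rows)) / (s * s)
    kappa_printed = (oa - pe_printed) / (1.0 - pe_printed)
    pe_std = sum(r * c for r, c in zip(rows, cols)) / (total * total)
    kappa_std = (oa - pe_std) / (1.0 - pe_std)
    return oa, aa, kappa_printed, kappa_std
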