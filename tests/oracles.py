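"""Independent brute-force oracles used by the test suite.

Everything here is written as plain Python loops over pixels, pairs, runs or
risk sets, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# photometric moments


def moments_loop(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    if var > 0:
        skew = sum((v - mean) ** 3 for v in values) / n / var**1.5
        kurt = sum((v - mean) ** 4 for v in values) / n / var**2 - 3.0
    else:
        skew = kurt = 0.0
    return {
        "iod": sum(values),
        "od_mean": mean,
        "od_var": var,
        "od_skew": skew,
        "od_kurt": kurt,
        "od_max": max(values),
    }


# ---------------------------------------------------------------------------
# co-occurrence by pair enumeration


def glcm_loop(quantized, q, offsets=((0, 1), (1, 0))):
    h, w = quantized.shape
    mat = np.zeros((q, q))
    for dy, dx in offsets:
        for y in range(h):
            for x in range(w):
                y2, x2 = y + dy, x + dx
                if 0 <= y2 < h and 0 <= x2 < w:
                    a, b = quantized[y, x], quantized[y2, x2]
                    if a >= 0 and b >= 0:
                        mat[a, b] += 1
                        mat[b, a] += 1
    total = mat.sum()
    return mat / total if total else mat


def glcm_stats_loop(p):
    q = p.shape[0]
    entropy = energy = contrast = homog = 0.0
    mu_i = mu_j = 0.0
    for i in range(q):
        for j in range(q):
            v = p[i, j]
            mu_i += i * v
            mu_j += j * v
            if v > 0:
                entropy -= v * math.log2(v)
            energy += v * v
            contrast += v * (i - j) ** 2
            homog += v / (1 + abs(i - j))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(q) for j in range(q))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(q) for j in range(q))
    if var_i > 0 and var_j > 0:
        corr = sum(
            (i - mu_i) * (j - mu_j) * p[i, j] for i in range(q) for j in range(q)
        ) / math.sqrt(var_i * var_j)
    else:
        corr = 0.0
    return {
        "glcm_entropy": entropy,
        "glcm_energy": energy,
        "glcm_contrast": contrast,
        "glcm_homogeneity": homog,
        "glcm_correlation": corr,
    }


# ---------------------------------------------------------------------------
# run length by explicit run enumeration


def runs_along_line(levels):
    """Run (level, length) pairs along one 1-d sequence; -1 breaks runs."""
    runs = []
    cur_level, cur_len = None, 0
    for v in list(levels) + [-1]:
        if v == cur_level and v >= 0:
            cur_len += 1
        else:
            if cur_level is not None and cur_level >= 0 and cur_len:
                runs.append((cur_level, cur_len))
            cur_level, cur_len = v, 1
    return runs


def rlm_loop(quantized, q, direction):
    h, w = quantized.shape
    dy, dx = direction
    mat = np.zeros((q, max(h, w)))
    starts = []
    for y in range(h):
        for x in range(w):
            py, px = y - dy, x - dx
            if not (0 <= py < h and 0 <= px < w):
                starts.append((y, x))
    for y0, x0 in starts:
        line = []
        y, x = y0, x0
        while 0 <= y < h and 0 <= x < w:
            line.append(quantized[y, x])
            y, x = y + dy, x + dx
        for level, length in runs_along_line(line):
            mat[level, length - 1] += 1
    return mat


def rl_stats_loop(mat, n_pixels):
    q, lmax = mat.shape
    n_runs = mat.sum()
    sre = lre = gln = rln = 0.0
    for g in range(q):
        row = mat[g].sum()
        gln += row * row
    for li in range(lmax):
        col = mat[:, li].sum()
        length = li + 1
        sre += col / length**2
        lre += col * length**2
        rln += col * col
    return {
        "rl_sre": sre / n_runs,
        "rl_lre": lre / n_runs,
        "rl_gln": gln / n_runs,
        "rl_rln": rln / n_runs,
        "rl_rp": n_runs / n_pixels,
    }


# ---------------------------------------------------------------------------
# discrete-texture fractions


def dt_fractions_loop(od, mask, thresholds):
    vals = [od[y, x] for y in range(od.shape[0]) for x in range(od.shape[1]) if mask[y, x]]
    mean = sum(vals) / len(vals)
    iod = sum(vals)
    lo, hi = thresholds[0] * mean, thresholds[1] * mean
    out = {}
    for state, cond in (
        ("low", lambda v: v < lo),
        ("high", lambda v: v >= hi),
        ("med", lambda v: lo <= v < hi),
    ):
        sel = [v for v in vals if cond(v)]
        out[f"dt_{state}_area_frac"] = len(sel) / len(vals)
        out[f"dt_{state}_iod_frac"] = sum(sel) / iod if iod else 0.0
    return out


# ---------------------------------------------------------------------------
# AUC by pair counting, KM and log-rank by hand


def auc_pairs(values, labels):
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def km_loop(times, events):
    """Product-limit estimate as (time, survival) step pairs over event times."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    s = 1.0
    curve = []
    at_risk = len(times)
    i = 0
    times = [times[k] for k in order]
    events = [events[k] for k in order]
    while i < len(times):
        t = times[i]
        d = sum(1 for j in range(len(times)) if times[j] == t and events[j])
        n_t = sum(1 for j in range(len(times)) if times[j] >= t)
        if d > 0:
            s *= 1.0 - d / n_t
            curve.append((t, s))
        while i < len(times) and times[i] == t:
            i += 1
    return curve


def km_survival_at_loop(times, events, t):
    s = 1.0
    for tt, ss in km_loop(times, events):
        if tt <= t:
            s = ss
    return s


def logrank_loop(times, events, groups):
    """Two-group log-rank chi-square via the observed-minus-expected table."""
    labels = sorted(set(groups))
    assert len(labels) == 2
    event_times = sorted({t for t, e in zip(times, events) if e})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n = sum(1 for tt in times if tt >= t)
        n1 = sum(1 for tt, g in zip(times, groups) if tt >= t and g == labels[0])
        d = sum(1 for tt, e in zip(times, events) if tt == t and e)
        d1 = sum(1 for tt, e, g in zip(times, events, groups) if tt == t and e and g == labels[0])
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0
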