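"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by direct enumeration or naive
sliding-window arithmetic, sharing no code with the library paths it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, factorial

import numpy as np


# -- preprocessing ----------------------------------------------------------

def sliding_polyfit(y: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Per-window least-squares polynomial fit evaluated at the window center
    (interior points only; edges are returned unchanged)."""
    half = window // 2
    out = y.astype(float).copy()
    x = np.arange(-half, half + 1)
    for i in range(half, len(y) - half):
        coef = np.polynomial.polynomial.polyfit(x, y[i - half:i + half + 1], polyorder)
        out[i] = np.polynomial.polynomial.polyval(0.0, coef)
    return out


def brute_moving_median(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving lower-median with reflect padding (even windows extend
    one extra point to the left)."""
    left = window // 2
    right = window - 1 - left
    padded = np.concatenate([y[1:left + 1][::-1], y, y[-right - 1:-1][::-1]]) \
        if window > 1 else y
    out = np.empty(len(y))
    for i in range(len(y)):
        w = np.sort(padded[i:i + window])
        out[i] = w[(window - 1) // 2]
    return out


def brute_tophat(y: np.ndarray, size: int) -> np.ndarray:
    """White top-hat via explicit sliding min then max with reflect padding."""
    def pad(a):
        half = size // 2
        return np.concatenate([a[1:half + 1][::-1], a, a[-half - 1:-1][::-1]])

    def erode(a):
        p = pad(a)
        return np.array([p[i:i + size].min() for i in range(len(a))])

    def dilate(a):
        p = pad(a)
        return np.array([p[i:i + size].max() for i in range(len(a))])

    return y - dilate(erode(y))


# -- alignment --------------------------------------------------------------

def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield part + [[first]]


def exhaustive_align(peaks: list[tuple[int, float, float]], tol_ppm: float):
    """Minimum-total-deviation feasible partition of (sample, mz, height) peaks.

    A block is feasible if it holds at most one peak per sample and every
    member lies within tol_ppm of the block's height-weighted centroid.
    The optimum is lexicographic: fewest blocks first (merge whenever the
    tolerance allows), then minimum total |deviation from centroid|; plain
    deviation alone is degenerate because all-singleton partitions cost 0.
    Returns (best_partition_as_frozensets, best_cost, unique_flag); None if no
    feasible partition exists.
    """
    tol = tol_ppm * 1e-6
    ids = list(range(len(peaks)))

    def feasible_cost(block):
        samples = [peaks[i][0] for i in block]
        if len(samples) != len(set(samples)):
            return None
        mz = np.array([peaks[i][1] for i in block])
        h = np.array([peaks[i][2] for i in block])
        c = np.average(mz, weights=h)
        if np.any(np.abs(mz - c) > tol * c):
            return None
        return float(np.abs(mz - c).sum())

    best, best_key, n_best = None, (np.inf, np.inf), 0
    for part in _partitions(ids):
        cost = 0.0
        ok = True
        for block in part:
            bc = feasible_cost(block)
            if bc is None:
                ok = False
                break
            cost += bc
        if not ok:
            continue
        key = (len(part), cost)
        if key[0] < best_key[0] or (key[0] == best_key[0]
                                    and key[1] < best_key[1] - 1e-12):
            best, best_key, n_best = part, key, 1
        elif key[0] == best_key[0] and abs(key[1] - best_key[1]) <= 1e-12:
            n_best += 1
    if best is None:
        return None
    return ({frozenset(b) for b in best}, best_key[1], n_best == 1)


# -- statistics -------------------------------------------------------------

def mw_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = u_stat(a, b)
    us = []
    for idx in combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, bool)
        mask[list(idx)] = True
        us.append(u_stat(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def auc_pairs(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the concordant-pair fraction over all positive-negative pairs."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = len(pos) * len(neg)
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(conc / total)


def brute_youden(values: np.ndarray, y: np.ndarray, thresholds: np.ndarray):
    """Per-threshold confusion enumeration; returns (sen, spec, best_t, best_j)."""
    sen, spec = [], []
    for t in thresholds:
        tp = fn = tn = fp = 0
        for v, lab in zip(values, y):
            pred = v >= t
            if lab == 1:
                tp, fn = tp + pred, fn + (not pred)
            else:
                fp, tn = fp + pred, tn + (not pred)
        sen.append(tp / (tp + fn))
        spec.append(tn / (tn + fp))
    j = np.array(sen) + np.array(spec) - 1
    best = int(np.argmax(j))
    return np.array(sen), np.array(spec), float(thresholds[best]), float(j[best])


def rand_pairs(a, b) -> float:
    """Rand index as the agreeing-pair fraction over all sample pairs."""
    n = len(a)
    agree = sum(
        (a[i] == a[j]) == (b[i] == b[j])
        for i in range(n) for j in range(i + 1, n))
    return agree / comb(n, 2)


# -- attribution ------------------------------------------------------------

def exact_shapley(model_fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Shapley values by direct subset enumeration of the background-masked
    value function v(S) = E_b f(x with features outside S from b)."""
    d = len(x)
    cache = {}

    def v(S):
        key = frozenset(S)
        if key not in cache:
            Z = background.copy()
            for j in S:
                Z[:, j] = x[j]
            cache[key] = float(np.mean(model_fn(Z)))
        return cache[key]

    phi = np.zeros(d)
    others = list(range(d))
    for i in range(d):
        rest = [j for j in others if j != i]
        for s in range(d):
            w = factorial(s) * factorial(d - s - 1) / factorial(d)
            for S in combinations(rest, s):
                phi[i] += w * (v(S + (i,)) - v(S))
    return phi


def vote_then_fill(rankings: list[dict[str, int]], k: int) -> list[str]:
    """Consensus oracle: brute-force vote counting then average-rank fill."""
    names = sorted(rankings[0])
    votes = {f: sum(1 for r in rankings
                    if r[f] <= k) for f in names}
    avg = {f: np.mean([r[f] for r in rankings]) for f in names}
    key = lambda f: (avg[f], float(f))
    selected = sorted([f for f in names if votes[f] >= 2], key=key)[:k]
    if len(selected) < k:
        selected += sorted([f for f in names if f not in selected],
                           key=key)[:k - len(selected)]
    return selected
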