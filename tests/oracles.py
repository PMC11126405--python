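"""Independent reference implementations used only as test oracles.

Deliberately naive: exhaustive enumeration for segmentation, all-pairs loops
for LOF, direct one-vs-rest formulas for metrics. They share no code path with
the package implementations they check.
"""

from itertools import combinations

import numpy as np


def brute_force_pcf(values, gamma, kmin=1):
    """Exhaustively enumerate all partitions of an ordered signal.

    Returns (breakpoints, cost, n_segments) of the optimum under the tie rule:
    lowest cost, then fewest segments, then earlier last breakpoint (comparing
    the reversed breakpoint tuple). Breakpoints are the indices after which a
    cut falls (segment [i..j] contributes breakpoint j unless it is last).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    _memo = {}

    def sse(i, j):
        if (i, j) not in _memo:
            s = v[i : j + 1]
            s = s[~np.isnan(s)]
            _memo[(i, j)] = 0.0 if s.size == 0 else float(np.sum((s - s.mean()) ** 2))
        return _memo[(i, j)]

    best = None
    for n_cuts in range(0, n):
        for cuts in combinations(range(1, n), n_cuts):
            bounds = [0, *cuts, n]
            if any(b - a < kmin for a, b in zip(bounds, bounds[1:])):
                continue
            cost = sum(sse(a, b - 1) for a, b in zip(bounds, bounds[1:]))
            cost += gamma * n_cuts
            key = (cost, n_cuts + 1, tuple(reversed(cuts)))
            if best is None or key < best[0]:
                best = (key, cuts)
    (cost, nseg, _), cuts = best
    return tuple(c - 1 for c in cuts), cost, nseg  # cuts as end-index of left segment


def naive_lof(points, k):
    """All-pairs LOF with exactly k neighbors (distance-then-index ties)."""
    x = np.asarray(points, dtype=float)
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    neighbors = []
    kdist = np.zeros(n)
    for i in range(n):
        order = sorted((d[i, j], j) for j in range(n) if j != i)
        nn = [j for _, j in order[:k]]
        neighbors.append(nn)
        kdist[i] = order[k - 1][0]
    lrd = np.zeros(n)
    for i in range(n):
        reach = [max(kdist[j], d[i, j]) for j in neighbors[i]]
        lrd[i] = 1.0 / (sum(reach) / k)
    lof = np.zeros(n)
    for i in range(n):
        lof[i] = sum(lrd[j] for j in neighbors[i]) / k / lrd[i]
    return lof


def ovr_rates(counts):
    """Per-class one-vs-rest rates from a confusion matrix, by direct loops."""
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    out = []
    total = counts.sum()
    for c in range(k):
        tp = counts[c, c]
        fn = counts[c, :].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = total - tp - fn - fp
        rec = tp / (tp + fn) if tp + fn else np.nan
        pre = tp / (tp + fp) if tp + fp else np.nan
        spe = tn / (tn + fp) if tn + fp else np.nan
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else np.nan
        out.append((rec, pre, spe, f1))
    return out


def binary_mcc(tp, fp, fn, tn):
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / den
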