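"""Exact penalized least-squares piecewise-constant segmentation (PCF).

The objective over a partition of an ordered signal into contiguous segments is

    sum_segments SSE(segment)  +  gamma * (number of breakpoints),

where SSE is the within-segment sum of squared deviations from the segment
mean (missing values are skipped but keep their grid position). The global
minimizer over all partitions with segment length >= kmin is found by Bellman
dynamic programming in O(n^2) with O(1) cost queries via prefix sums, so the
result is exact and can be verified against exhaustive enumeration.

Ties between equal-cost segmentations are broken toward fewer segments, then
toward the earlier last breakpoint (recursively), which makes the output
deterministic.

Segmentation is always per chromosome: breakpoints are forced at every
chromosome boundary and no segment ever spans two chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CHROMOSOMES, CopyNumberProfile


class SegmentationError(ValueError):
    pass


@dataclass
class Segment:
    chromosome: str
    start_index: int  # 0-based inclusive, into the per-chromosome locus grid
    end_index: int
    start_bp: int
    end_bp: int
    mean: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise SegmentationError("start_index > end_index")


@dataclass
class SegmentationResult:
    segments: list[Segment]
    gamma: float
    kmin: int
    total_cost: float
    chrom_offsets: dict[str, int] = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def breakpoints_bp(self) -> list[tuple[str, int]]:
        """Internal breakpoints as (chromosome, end_bp of the left segment)."""
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.chromosome == b.chromosome:
                out.append((a.chromosome, a.end_bp))
        return out


def segment_cost(values: np.ndarray) -> float:
    """Sum of squared deviations from the mean, ignoring NaN.

    Raises on an all-missing slice.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise SegmentationError("all-missing slice has no cost")
    return float(np.sum((v - v.mean()) ** 2))


def _prefix_sums(values: np.ndarray):
    obs = ~np.isnan(values)
    v = np.where(obs, values, 0.0)
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])
    cnt = np.concatenate([[0], np.cumsum(obs.astype(np.int64))])
    return s1, s2, cnt


def _sse(s1, s2, cnt, i: int, j: int) -> float:
    """SSE of the inclusive index slice [i, j]; 0 if no observed values."""
    c = cnt[j + 1] - cnt[i]
    if c == 0:
        return 0.0
    s = s1[j + 1] - s1[i]
    ss = s2[j + 1] - s2[i]
    return max(ss - s * s / c, 0.0)


def pcf_segment(
    values: np.ndarray, gamma: float, kmin: int = 1
) -> tuple[list[tuple[int, int, float, int]], float]:
    """Optimal penalized piecewise-constant partition of one ordered signal.

    Returns ``(segments, total_cost)`` where each segment is
    ``(start_index, end_index, mean, n_obs)`` (indices inclusive) and
    ``total_cost`` is recomputed canonically as
    ``sum of segment SSEs + gamma * (len(segments) - 1)``.
    """
    if gamma < 0:
        raise SegmentationError(f"gamma must be >= 0, got {gamma}")
    if kmin < 1:
        raise SegmentationError(f"kmin must be >= 1, got {kmin}")
    v = np.asarray(values, dtype=float)
    n = len(v)
    n_obs_total = int((~np.isnan(v)).sum())
    if n_obs_total < 1:
        raise SegmentationError("need at least one non-missing value")
    s1, s2, cnt = _prefix_sums(v)

    if n < kmin:
        warnings.warn(
            f"signal length {n} < kmin {kmin}; returning a single segment",
            stacklevel=2,
        )
        segs = [_finish_segment(v, s1, cnt, 0, n - 1)]
        return segs, _sse(s1, s2, cnt, 0, n - 1)

    # best[j]: optimal (cost, n_segments) for the prefix ending at index j,
    # back[j]: start index of that prefix's last segment.
    INF = float("inf")
    best_cost = np.full(n, INF)
    best_nseg = np.zeros(n, dtype=np.int64)
    back = np.zeros(n, dtype=np.int64)
    for j in range(n):
        bc, bn, bi = INF, 0, -1
        # last segment [i, j]; iterate i ascending so equal (cost, nseg)
        # keeps the earliest last breakpoint (at i - 1)
        for i in range(0, j - kmin + 2):
            if i == 0:
                c = _sse(s1, s2, cnt, 0, j)
                k = 1
            else:
                if best_cost[i - 1] == INF:
                    continue
                c = best_cost[i - 1] + gamma + _sse(s1, s2, cnt, i, j)
                k = best_nseg[i - 1] + 1
            if c < bc or (c == bc and k < bn):
                bc, bn, bi = c, k, i
        best_cost[j], best_nseg[j], back[j] = bc, bn, bi
    if not np.isfinite(best_cost[n - 1]):  # pragma: no cover - kmin handled above
        raise SegmentationError("no feasible segmentation")

    # backtrack
    bounds = []
    j = n - 1
    while j >= 0:
        i = int(back[j])
        bounds.append((i, j))
        j = i - 1
    bounds.reverse()
    segs = [_finish_segment(v, s1, cnt, i, j) for i, j in bounds]
    total = sum(_sse(s1, s2, cnt, i, j) for i, j in bounds) + gamma * (len(bounds) - 1)
    return segs, float(total)


def _finish_segment(v, s1, cnt, i: int, j: int) -> tuple[int, int, float, int]:
    c = int(cnt[j + 1] - cnt[i])
    mean = float((s1[j + 1] - s1[i]) / c) if c else float("nan")
    return (i, j, mean, c)


def segment_profile(
    profile: CopyNumberProfile, gamma: float, kmin: int = 1
) -> SegmentationResult:
    """Segment a profile chromosome by chromosome.

    Segment bp bounds: interior boundaries fall at the midpoint (floored)
    between the flanking probes, so the derived regions are grid-independent;
    the first/last segment of a chromosome starts/ends at the outermost probe.
    Chromosomes with no observed values are skipped with a warning.
    """
    segments: list[Segment] = []
    total = 0.0
    offsets: dict[str, int] = {}
    for code, sl in profile.chromosome_slices():
        chrom = CHROMOSOMES[code]
        vals = profile.values[sl]
        pos = profile.positions[sl]
        if np.all(np.isnan(vals)):
            warnings.warn(f"chromosome {chrom} has no observed values; skipped", stacklevel=2)
            continue
        offsets[chrom] = sl.start
        segs, cost = pcf_segment(vals, gamma=gamma, kmin=kmin)
        total += cost
        for si, (i, j, mean, n_obs) in enumerate(segs):
            start_bp = int(pos[i]) if si == 0 else segments[-1].end_bp + 1
            if si == len(segs) - 1:
                end_bp = int(pos[j])
            else:
                nxt = segs[si + 1][0]
                end_bp = int((int(pos[j]) + int(pos[nxt])) // 2)
            segments.append(
                Segment(chrom, int(i), int(j), start_bp, end_bp, mean, n_obs)
            )
    if not segments:
        raise SegmentationError("profile has no observed values on any chromosome")
    return SegmentationResult(segments, gamma=gamma, kmin=kmin, total_cost=total, chrom_offsets=offsets)
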