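"""Genome-partitioning feature regions and the samples x regions feature matrix.

The feature space is built once from a labeled reference cohort: the average
copy-number profile of each class is segmented (see :mod:`cnclust.pcf`), the
union of all classes' internal breakpoints is taken per chromosome, and the
observed chromosome extent is cut at those positions into abutting regions.
Regions never span a chromosome boundary.

Features are per-region mean copy number; cohort-wise per-region z-scoring
removes affine (platform/cellularity) differences between cohorts, which is
what makes the downstream classifier platform-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CHROM_TO_CODE, CHROMOSOMES, Cohort, CohortError, CopyNumberProfile
from .pcf import SegmentationResult


class RegionError(ValueError):
    pass


@dataclass(frozen=True)
class Region:
    chromosome: str
    start_bp: int
    end_bp: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.chromosome not in CHROM_TO_CODE:
            raise RegionError(f"unknown chromosome {self.chromosome!r}")
        if self.start_bp > self.end_bp:
            raise RegionError(f"start_bp {self.start_bp} > end_bp {self.end_bp}")

    @property
    def region_id(self) -> str:
        return f"{self.chromosome}:{self.start_bp}-{self.end_bp}"


@dataclass
class RegionSet:
    regions: list[Region]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = [CHROM_TO_CODE[r.chromosome] for r in self.regions]
        if codes != sorted(codes):
            raise RegionError("regions out of canonical chromosome order")
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chromosome == b.chromosome and b.start_bp != a.end_bp + 1:
                raise RegionError(
                    f"regions must abut within a chromosome: {a.region_id} then {b.region_id}"
                )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self.regions == other.regions


@dataclass
class FeatureMatrix:
    """Samples x regions mean-copy-number table; NaN marks regions with no probe."""

    df: pd.DataFrame  # index = sample ids, columns = region ids
    scaled: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


@dataclass
class ScalingParams:
    region_ids: list[str]
    center: np.ndarray
    spread: np.ndarray
    degenerate: np.ndarray  # True where the spread was undefined and set to 1

    def to_dict(self) -> dict:
        return {
            "region_ids": self.region_ids,
            "center": self.center.tolist(),
            "spread": self.spread.tolist(),
            "degenerate": self.degenerate.astype(bool).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            region_ids=list(d["region_ids"]),
            center=np.asarray(d["center"], dtype=float),
            spread=np.asarray(d["spread"], dtype=float),
            degenerate=np.asarray(d["degenerate"], dtype=bool),
        )


def class_average_profile(cohort: Cohort, class_id: int, method: str = "mean") -> CopyNumberProfile:
    """Per-locus average over one class's samples, ignoring missing values.

    A locus missing in every class sample stays missing. All profiles must
    share one probe grid.
    """
    members = [p for p in cohort.profiles if cohort.labels.get(p.sample_id) == class_id]
    if not members:
        raise CohortError(f"no samples labeled {class_id}")
    ref = members[0]
    for p in members[1:]:
        if not p.same_grid(ref):
            raise CohortError("class profiles do not share a probe grid")
    stack = np.vstack([p.values for p in members])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices -> NaN
        if method == "mean":
            avg = np.nanmean(stack, axis=0)
        elif method == "median":
            avg = np.nanmedian(stack, axis=0)
        else:
            raise ValueError(f"unknown averaging method {method!r}")
    return CopyNumberProfile(
        sample_id=f"class_{class_id}_{method}",
        chrom_codes=ref.chrom_codes,
        positions=ref.positions,
        values=avg,
        platform=ref.platform,
    )


def build_regions(
    class_segmentations: list[SegmentationResult],
    chromosome_extents: dict,
    provenance: dict | None = None,
) -> RegionSet:
    """Cut each chromosome extent at the union of all classes' breakpoints.

    ``chromosome_extents`` maps chromosome name or code to (min_bp, max_bp).
    Per chromosome the number of regions is (#unique internal breakpoints) + 1;
    chromosome boundaries always cut. Breakpoints are deduplicated, so the
    construction is idempotent and invariant to class ordering.
    """
    if not class_segmentations:
        raise RegionError("need at least one segmentation")
    extents: dict[str, tuple[int, int]] = {}
    for key, (lo, hi) in chromosome_extents.items():
        chrom = CHROMOSOMES[key] if isinstance(key, (int, np.integer)) else str(key)
        extents[chrom] = (int(lo), int(hi))
    bps: dict[str, set[int]] = {c: set() for c in extents}
    for seg_result in class_segmentations:
        for chrom, end_bp in seg_result.breakpoints_bp():
            if chrom in bps:
                bps[chrom].add(int(end_bp))
    regions: list[Region] = []
    for chrom in CHROMOSOMES:
        if chrom not in extents:
            continue
        lo, hi = extents[chrom]
        cuts = sorted(b for b in bps[chrom] if lo <= b < hi)
        start = lo
        for b in cuts:
            regions.append(Region(chrom, start, b))
            start = b + 1
        regions.append(Region(chrom, start, hi))
    prov = dict(provenance or {})
    prov.setdefault("n_classes", len(class_segmentations))
    prov.setdefault("gamma", class_segmentations[0].gamma)
    prov.setdefault("kmin", class_segmentations[0].kmin)
    return RegionSet(regions, provenance=prov)


def assign_probes(regions: RegionSet, chrom_codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Region index per probe, -1 where a probe falls in no region."""
    out = np.full(len(positions), -1, dtype=np.int64)
    by_chrom: dict[int, list[tuple[int, int, int]]] = {}
    for ridx, r in enumerate(regions):
        by_chrom.setdefault(CHROM_TO_CODE[r.chromosome], []).append((r.start_bp, r.end_bp, ridx))
    for code, items in by_chrom.items():
        starts = np.array([s for s, _, _ in items])
        ends = np.array([e for _, e, _ in items])
        idxs = np.array([i for _, _, i in items])
        mask = chrom_codes == code
        if not mask.any():
            continue
        pos = positions[mask]
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos <= ends[np.clip(k, 0, len(ends) - 1)])
        res = np.where(ok, idxs[np.clip(k, 0, len(idxs) - 1)], -1)
        out[mask] = res
    return out


def region_means(profile: CopyNumberProfile, regions: RegionSet) -> np.ndarray:
    """Mean of non-missing probe values per region; NaN where no probe falls."""
    assign = assign_probes(regions, profile.chrom_codes, profile.positions)
    return _means_from_assignment(profile.values, assign, len(regions))


def _means_from_assignment(values: np.ndarray, assign: np.ndarray, n_regions: int) -> np.ndarray:
    ok = (assign >= 0) & ~np.isnan(values)
    sums = np.bincount(assign[ok], weights=values[ok], minlength=n_regions)
    cnts = np.bincount(assign[ok], minlength=n_regions)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / cnts
    means[cnts == 0] = np.nan
    return means


def cohort_features(cohort: Cohort, regions: RegionSet) -> FeatureMatrix:
    """Region-mean feature matrix for a whole cohort.

    The probe-to-region assignment is computed once per distinct grid.
    """
    n = len(regions)
    rows = []
    cached: tuple[CopyNumberProfile, np.ndarray] | None = None
    for p in cohort.profiles:
        if cached is not None and p.same_grid(cached[0]):
            assign = cached[1]
        else:
            assign = assign_probes(regions, p.chrom_codes, p.positions)
            cached = (p, assign)
        rows.append(_means_from_assignment(p.values, assign, n))
    df = pd.DataFrame(np.vstack(rows), index=cohort.sample_ids, columns=regions.region_ids)
    return FeatureMatrix(df, scaled=False)


def fit_scaler(features: FeatureMatrix, min_samples: int = 3) -> ScalingParams:
    """Per-region center (mean) and spread (sd) over non-missing entries.

    Cohort-wise scaling needs several samples to estimate moments; with a
    single or few samples the per-region spread is meaningless, so a floor
    is enforced.
    """
    x = features.values
    if x.shape[0] < min_samples:
        raise RegionError(
            f"need at least {min_samples} samples to fit a cohort scaler "
            f"(got {x.shape[0]}); scaling is unreliable for single samples"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = np.nanmean(x, axis=0)
        spread = np.nanstd(x, axis=0, ddof=0)
    n_obs = (~np.isnan(x)).sum(axis=0)
    degenerate = (n_obs < 2) | (spread <= 1e-12) | ~np.isfinite(spread)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} region(s) with degenerate spread; using spread 1",
            stacklevel=2,
        )
    spread = np.where(degenerate, 1.0, spread)
    center = np.where(np.isfinite(center), center, 0.0)
    return ScalingParams(
        region_ids=features.region_ids,
        center=center,
        spread=spread,
        degenerate=degenerate,
    )


def apply_scaler(features: FeatureMatrix, params: ScalingParams) -> FeatureMatrix:
    """z-score each region; missing entries stay missing."""
    if features.region_ids != params.region_ids:
        raise RegionError("feature columns do not align with scaling parameters")
    scaled = (features.df - params.center) / params.spread
    return FeatureMatrix(scaled, scaled=True)


def scale_features(features: FeatureMatrix, min_samples: int = 3) -> tuple[FeatureMatrix, ScalingParams]:
    """Fit the cohort's own scaler and apply it (the default workflow)."""
    params = fit_scaler(features, min_samples=min_samples)
    return apply_scaler(features, params), params
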