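"""Core domain objects: genomic loci, copy-number profiles and cohorts.

Coordinates are 1-based inclusive throughout (SEG convention); BED export
converts at the boundary. Chromosomes are restricted to the autosomes plus X
(breast-cancer context); Y and mitochondrial loci are dropped with a warning
at parse time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Canonical chromosome order. Internal arrays store the index into this tuple.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

CHROM_TO_CODE: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}

_DROPPED = {"Y", "M", "MT"}


class CohortError(ValueError):
    """Raised on invalid profiles, cohorts or label tables."""


def normalize_chromosome(token: str) -> str | None:
    """Normalize a chromosome token ("chr1", "1", "X", ...).

    Returns the canonical name, or ``None`` for chromosomes outside the
    supported set (Y/MT), which callers drop with a warning.
    """
    tok = str(token).strip()
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    if tok in ("23",):  # some SEG exports encode X as 23
        tok = "X"
    if tok in _DROPPED:
        return None
    if tok not in CHROM_TO_CODE:
        raise CohortError(f"unknown chromosome {token!r}")
    return tok


@dataclass(frozen=True)
class Locus:
    """A single genomic position, 1-based."""

    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.chromosome not in CHROM_TO_CODE:
            raise CohortError(f"unknown chromosome {self.chromosome!r}")
        if self.position < 1:
            raise CohortError(f"position must be >= 1, got {self.position}")

    @property
    def chrom_code(self) -> int:
        return CHROM_TO_CODE[self.chromosome]


@dataclass
class CopyNumberProfile:
    """One sample's ordered log-ratio values along the genome.

    ``chrom_codes`` and ``positions`` define the probe grid (sorted by
    chromosome then position, strictly increasing within a chromosome);
    ``values`` holds the log ratios with NaN marking missing probes.
    """

    sample_id: str
    chrom_codes: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    platform: str = ""

    def __post_init__(self) -> None:
        self.chrom_codes = np.asarray(self.chrom_codes, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.chrom_codes)
        if len(self.positions) != n or len(self.values) != n:
            raise CohortError("chrom_codes, positions and values must have equal length")
        if n == 0:
            raise CohortError("empty profile")
        if self.chrom_codes.min() < 0 or self.chrom_codes.max() >= len(CHROMOSOMES):
            raise CohortError("chromosome code out of range")
        if np.any(np.diff(self.chrom_codes) < 0):
            raise CohortError("chromosomes out of canonical order")
        same = np.diff(self.chrom_codes) == 0
        if np.any(same & (np.diff(self.positions) <= 0)):
            raise CohortError("positions must be strictly increasing within a chromosome")
        finite_ok = np.isnan(self.values) | np.isfinite(self.values)
        if not np.all(finite_ok):
            raise CohortError("values must be finite where present")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def same_grid(self, other: "CopyNumberProfile") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.chrom_codes, other.chrom_codes)
            and np.array_equal(self.positions, other.positions)
        )

    def chromosome_slices(self):
        """Yield (chrom_code, slice) pairs covering the profile in order."""
        codes = self.chrom_codes
        bounds = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(codes)]])
        for s, e in zip(starts, stops):
            yield int(codes[s]), slice(int(s), int(e))


@dataclass
class Cohort:
    """A set of copy-number profiles with optional IntClust labels (1..10)."""

    profiles: list[CopyNumberProfile]
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate sample ids in cohort")
        missing = set(self.labels) - set(ids)
        if missing:
            raise CohortError(f"labels refer to unknown samples: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def __len__(self) -> int:
        return len(self.profiles)

    def profile(self, sample_id: str) -> CopyNumberProfile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)

    def shared_grid(self) -> CopyNumberProfile:
        """Return a reference profile after checking all grids are identical."""
        ref = self.profiles[0]
        for p in self.profiles[1:]:
            if not p.same_grid(ref):
                raise CohortError("cohort profiles do not share a probe grid")
        return ref

    def subset(self, sample_ids) -> "Cohort":
        keep = set(sample_ids)
        profiles = [p for p in self.profiles if p.sample_id in keep]
        labels = {s: l for s, l in self.labels.items() if s in keep}
        return Cohort(profiles, labels)

    def chromosome_extents(self) -> dict[int, tuple[int, int]]:
        """Observed probe span per chromosome code, pooled over all profiles."""
        ext: dict[int, tuple[int, int]] = {}
        for p in self.profiles:
            for code, sl in p.chromosome_slices():
                lo = int(p.positions[sl][0])
                hi = int(p.positions[sl][-1])
                if code in ext:
                    ext[code] = (min(ext[code][0], lo), max(ext[code][1], hi))
                else:
                    ext[code] = (lo, hi)
        return ext


def warn_dropped(n: int, what: str) -> None:
    if n:
        warnings.warn(f"dropped {n} {what} (unsupported chromosome)", stacklevel=3)
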