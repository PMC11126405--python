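"""Synthetic labeled copy-number cohorts with IntClust-like signal structure.

The generator emulates the statistical geometry the classifier targets rather
than real breast-cancer biology: 10 classes whose mean profiles are piecewise
constant over a probe grid, with four pairs of classes — (1,5), (3,8), (4,7),
(9,10) — sharing a common aberration backbone and differing only in a few
designated discriminative segments of effect size ``pair_delta``. Samples are
the class archetype plus homoscedastic Gaussian probe noise, optionally
attenuated/offset cohort-wide (emulating platform and tumor-cellularity signal
differences between cohorts), with missing probes masked uniformly at random.

All randomness flows through one seeded generator, so identical seeds give
identical cohorts byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CHROMOSOMES, Cohort, CopyNumberProfile
from .cascade import PAIRS

#: Approximate human chromosome lengths in Mb (1..22, X), used to apportion
#: probes across a desk-scale grid.
_CHROM_MB = np.array(
    [249, 243, 198, 190, 182, 171, 159, 145, 138, 134, 135, 133,
     114, 107, 102, 90, 83, 80, 59, 64, 47, 51, 155],
    dtype=float,
)

#: Uneven default class mixture, roughly the shape seen in large breast-cancer
#: cohorts (classes 3, 4 and 8 common; 2 and 6 rare).
DEFAULT_PROPORTIONS = np.array(
    [0.076, 0.045, 0.146, 0.169, 0.095, 0.044, 0.095, 0.149, 0.073, 0.108]
)
DEFAULT_PROPORTIONS = DEFAULT_PROPORTIONS / DEFAULT_PROPORTIONS.sum()


class SimulationError(ValueError):
    pass


def make_grid(n_probes: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic probe grid: (chrom_codes, positions).

    Probes are apportioned to the 23 chromosomes proportionally to length and
    evenly spaced along each chromosome.
    """
    if n_probes < len(CHROMOSOMES):
        raise SimulationError("need at least one probe per chromosome")
    raw = _CHROM_MB / _CHROM_MB.sum() * n_probes
    counts = np.maximum(np.floor(raw).astype(int), 1)
    # distribute the remainder to the largest fractional parts, deterministically
    short = n_probes - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    for i in range(short):
        counts[order[i % len(counts)]] += 1
    codes, positions = [], []
    for code, (mb, cnt) in enumerate(zip(_CHROM_MB, counts)):
        length = int(mb * 1_000_000)
        step = length // (cnt + 1)
        pos = (np.arange(1, cnt + 1) * step).astype(np.int64)
        codes.append(np.full(cnt, code, dtype=np.int64))
        positions.append(pos)
    return np.concatenate(codes), np.concatenate(positions)


@dataclass
class ArchetypeSet:
    """Per-class piecewise-constant mean profiles on a shared probe grid."""

    chrom_codes: np.ndarray
    positions: np.ndarray
    values: np.ndarray  # shape (10, n_probes), row i = class i+1
    pairs: tuple[tuple[int, int], ...]
    discriminative: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_probes(self) -> int:
        return len(self.positions)

    def class_values(self, class_id: int) -> np.ndarray:
        return self.values[class_id - 1]

    def realized_breakpoint_union(self) -> int:
        """Number of unique inter-probe boundaries where any class changes level.

        This is the ground-truth count of internal breakpoints the region
        builder should recover from a noise-free cohort.
        """
        changes = np.zeros(self.n_probes - 1, dtype=bool)
        same_chrom = np.diff(self.chrom_codes) == 0
        for row in self.values:
            changes |= (np.diff(row) != 0) & same_chrom
        return int(changes.sum())

    def expected_region_count(self) -> int:
        n_chrom = len(np.unique(self.chrom_codes))
        return self.realized_breakpoint_union() + n_chrom

    def values_at(self, chrom_codes: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Archetype matrix evaluated on another grid (nearest-probe step lookup)."""
        out = np.zeros((self.values.shape[0], len(positions)))
        for code in np.unique(chrom_codes):
            src = self.chrom_codes == code
            dst = chrom_codes == code
            if not src.any():
                continue
            sp = self.positions[src]
            qp = positions[dst]
            idx = np.searchsorted(sp, qp)
            left = np.clip(idx - 1, 0, len(sp) - 1)
            right = np.clip(idx, 0, len(sp) - 1)
            nearest = np.where(
                np.abs(qp - sp[left]) <= np.abs(sp[right] - qp), left, right
            )
            src_idx = np.flatnonzero(src)[nearest]
            out[:, dst] = self.values[:, src_idx]
        return out


@dataclass
class SimulationSpec:
    """Conditions for one simulated cohort."""

    n_samples: int
    proportions: np.ndarray = field(default_factory=lambda: DEFAULT_PROPORTIONS.copy())
    sigma: float = 0.2          # per-probe Gaussian noise sd (log-ratio units)
    attenuation: float = 1.0    # cohort-wide multiplicative signal factor a > 0
    offset: float = 0.0         # cohort-wide additive shift b
    missing_fraction: float = 0.02
    platform: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-8:
            raise SimulationError("class proportions must sum to 1")
        if self.sigma < 0:
            raise SimulationError("sigma must be >= 0")
        if self.attenuation <= 0:
            raise SimulationError("attenuation must be > 0")
        if not (0 <= self.missing_fraction < 1):
            raise SimulationError("missing_fraction must be in [0, 1)")


def _sample_disjoint_spans(
    rng: np.random.Generator,
    chrom_codes: np.ndarray,
    n_spans: int,
    min_len: int,
    max_len: int,
    taken: list[tuple[int, int]],
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    """Random probe-index spans, each within one chromosome, mutually disjoint
    with each other and with ``taken``."""
    bounds = {}
    for code in np.unique(chrom_codes):
        idx = np.flatnonzero(chrom_codes == code)
        bounds[code] = (idx[0], idx[-1])
    codes = np.array(sorted(bounds))
    sizes = np.array([bounds[c][1] - bounds[c][0] + 1 for c in codes], dtype=float)
    weights = sizes / sizes.sum()
    spans: list[tuple[int, int]] = []
    occupied = list(taken)
    for _ in range(n_spans):
        for attempt in range(max_tries):
            code = rng.choice(codes, p=weights)
            lo, hi = bounds[code]
            length = int(rng.integers(min_len, max_len + 1))
            if hi - lo + 1 < length:
                continue
            start = int(rng.integers(lo, hi - length + 2))
            end = start + length - 1
            if all(end < s or start > e for s, e in occupied):
                spans.append((start, end))
                occupied.append((start, end))
                break
        else:
            raise SimulationError("could not place a disjoint aberrant segment; grid too crowded")
    return spans


def make_archetypes(
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    n_classes: int = 10,
    pairs: tuple[tuple[int, int], ...] = PAIRS,
    segments_per_class: int = 8,
    amp_effect: float = 1.0,
    pair_delta: float = 0.4,
    n_discriminative: int = 3,
    level_sd: float = 0.1,
    min_len: int = 10,
    max_len: int = 60,
    seed: int = 0,
) -> ArchetypeSet:
    """Build the 10 class archetypes with four near-identical pairs.

    Each merged group gets ``segments_per_class`` mutually disjoint aberrant
    segments with levels drawn from ±``amp_effect`` plus N(0, level_sd)
    jitter. Paired classes copy one backbone; the higher-numbered class then
    adds ``pair_delta`` on ``n_discriminative`` extra disjoint segments (so
    ``pair_delta = 0`` makes the pair's archetypes identical).
    """
    if n_classes != 10:
        raise SimulationError("the archetype layout is defined for 10 classes")
    if grid is None:
        grid = make_grid()
    chrom_codes, positions = grid
    rng = np.random.default_rng(seed)
    n = len(positions)
    total_needed = (segments_per_class + n_discriminative) * (max_len)
    if total_needed > n:
        raise SimulationError(
            f"segments_per_class x max_len exceeds grid capacity ({total_needed} > {n})"
        )
    values = np.zeros((10, n))
    discriminative: dict[str, list[tuple[int, int]]] = {}

    paired = {c for p in pairs for c in p}
    groups: list[tuple[int, ...]] = [p for p in pairs] + [
        (c,) for c in range(1, 11) if c not in paired
    ]
    for group in sorted(groups):
        backbone_spans = _sample_disjoint_spans(
            rng, chrom_codes, segments_per_class, min_len, max_len, taken=[]
        )
        backbone = np.zeros(n)
        for s, e in backbone_spans:
            level = rng.choice([-amp_effect, amp_effect]) + rng.normal(0.0, level_sd)
            backbone[s : e + 1] = level
        for c in group:
            values[c - 1] = backbone
        if len(group) == 2:
            lo, hi = group
            disc = _sample_disjoint_spans(
                rng, chrom_codes, n_discriminative, min_len, max_len, taken=[]
            )
            discriminative[f"{lo}/{hi}"] = disc
            for s, e in disc:
                values[hi - 1, s : e + 1] = values[hi - 1, s : e + 1] + pair_delta
    return ArchetypeSet(
        chrom_codes=chrom_codes,
        positions=positions,
        values=values,
        pairs=pairs,
        discriminative=discriminative,
    )


def simulate_cohort(
    archetypes: ArchetypeSet,
    spec: SimulationSpec,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    sample_prefix: str = "S",
) -> Cohort:
    """Draw a labeled cohort: a * (archetype + N(0, sigma)) + b per probe.

    ``grid`` defaults to the archetypes' own probe grid; a different grid
    (other platform) is evaluated by nearest-probe step lookup.
    """
    # Attenuation damps the measured signal *including* its probe noise, so a
    # cohort re-measured with (a, b) is an exact affine image of the (1, 0)
    # cohort under the same seed — the invariance cohort-wise scaling removes.
    rng = np.random.default_rng(spec.seed)
    if grid is None:
        chrom_codes, positions = archetypes.chrom_codes, archetypes.positions
        arch_values = archetypes.values
    else:
        chrom_codes, positions = grid
        arch_values = archetypes.values_at(chrom_codes, positions)
    n_probes = len(positions)
    classes = np.arange(1, 11)
    labels_drawn = rng.choice(classes, size=spec.n_samples, p=spec.proportions)
    profiles = []
    labels: dict[str, int] = {}
    for i, cls in enumerate(labels_drawn):
        sid = f"{sample_prefix}{i:04d}"
        vals = arch_values[cls - 1].copy()
        if spec.sigma > 0:
            vals = vals + rng.normal(0.0, spec.sigma, size=n_probes)
        vals = spec.attenuation * vals + spec.offset
        if spec.missing_fraction > 0:
            mask = rng.random(n_probes) < spec.missing_fraction
            vals[mask] = np.nan
        profiles.append(
            CopyNumberProfile(
                sample_id=sid,
                chrom_codes=chrom_codes,
                positions=positions,
                values=vals,
                platform=spec.platform,
            )
        )
        labels[sid] = int(cls)
    return Cohort(profiles, labels)


def thinned_jittered_grid(
    archetypes: ArchetypeSet, thin: int = 2, jitter_frac: float = 0.25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """A second-platform grid: every ``thin``-th probe with jittered positions."""
    rng = np.random.default_rng(seed)
    codes = archetypes.chrom_codes[::thin].copy()
    pos = archetypes.positions[::thin].astype(float)
    if len(pos) > 1:
        spacing = np.median(np.diff(archetypes.positions[archetypes.chrom_codes == codes[0]]))
        pos = pos + rng.integers(
            -int(spacing * jitter_frac), int(spacing * jitter_frac) + 1, size=len(pos)
        )
    pos = np.maximum(pos.astype(np.int64), 1)
    # enforce strict monotonicity within chromosomes after jitter
    for code in np.unique(codes):
        m = codes == code
        p = np.maximum.accumulate(pos[m])
        dup = np.concatenate([[False], np.diff(p) <= 0])
        p = p + np.cumsum(dup)  # bump ties forward by 1 bp
        pos[m] = p
    return codes, pos


def simulate_two_platform_pair(
    archetypes: ArchetypeSet,
    spec_train: SimulationSpec,
    spec_test: SimulationSpec,
    thin: int = 2,
    grid_seed: int | None = None,
) -> tuple[Cohort, Cohort]:
    """Train/test cohorts from the same archetypes on different platforms.

    The test cohort lives on a thinned, jittered probe grid with its own
    attenuation/offset/noise, emulating an array-trained, sequencing-applied
    scenario. Labels come from the same class archetypes.
    """
    train = simulate_cohort(archetypes, spec_train, sample_prefix="TR")
    gseed = spec_test.seed if grid_seed is None else grid_seed
    test_grid = thinned_jittered_grid(archetypes, thin=thin, seed=gseed)
    test = simulate_cohort(archetypes, spec_test, grid=test_grid, sample_prefix="TE")
    return train, test
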