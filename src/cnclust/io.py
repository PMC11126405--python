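"""File formats: SEG (cBioPortal dialect), probe matrices, labels, BED3,
feature matrices and model-bundle persistence.

All coordinates are 1-based inclusive internally; BED export emits the usual
0-based half-open intervals and import converts back, so the round trip is the
identity. SEG headers follow the cBioPortal dialect (ID, chrom, loc.start,
loc.end, num.mark, seg.mean); "chr" prefixes are accepted and stripped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from . import __version__
from .cascade import PAIRS, ModelBundle, _tag_classifier, pair_key
from .core import (
    CHROM_TO_CODE,
    CHROMOSOMES,
    Cohort,
    CohortError,
    CopyNumberProfile,
    normalize_chromosome,
    warn_dropped,
)
from .regions import FeatureMatrix, Region, RegionSet, ScalingParams

SEG_COLUMNS = ("ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean")

BUNDLE_FORMAT_VERSION = 1


class ParseError(ValueError):
    pass


@dataclass
class SegRecord:
    sample_id: str
    chromosome: str
    start: int
    end: int
    num_marks: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.chromosome not in CHROM_TO_CODE:
            raise ParseError(f"unknown chromosome {self.chromosome!r}")
        if self.start > self.end:
            raise ParseError(f"segment start {self.start} > end {self.end}")
        if self.num_marks < 0:
            raise ParseError("num_marks must be nonnegative")


def read_seg(path) -> dict[str, list[SegRecord]]:
    """Parse a SEG file into records grouped by sample (file order preserved).

    Malformed rows raise with the offending line number; overlapping segments
    within one sample/chromosome violate the SEG invariant and raise too.
    """
    path = Path(path)
    records: dict[str, list[SegRecord]] = {}
    n_dropped = 0
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 6:
            raise ParseError(f"{path}: expected 6 tab-separated header columns, got {len(header)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            sid, chrom_tok, start_s, end_s, marks_s, mean_s = parts[:6]
            chrom = normalize_chromosome(chrom_tok)
            if chrom is None:
                n_dropped += 1
                continue
            try:
                rec = SegRecord(
                    sample_id=sid,
                    chromosome=chrom,
                    start=int(float(start_s)),
                    end=int(float(end_s)),
                    num_marks=int(float(marks_s)),
                    seg_mean=float(mean_s),
                )
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.setdefault(sid, []).append(rec)
    warn_dropped(n_dropped, "SEG records")
    for sid, recs in records.items():
        _check_no_overlap(sid, recs)
    return records


def _check_no_overlap(sample_id: str, recs: list[SegRecord]) -> None:
    by_chrom: dict[str, list[SegRecord]] = {}
    for r in recs:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom, rs in by_chrom.items():
        rs_sorted = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs_sorted, rs_sorted[1:]):
            if b.start <= a.end:
                raise ParseError(
                    f"sample {sample_id!r} chromosome {chrom}: overlapping segments "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def write_seg(records: dict[str, list[SegRecord]], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for sid, recs in records.items():
            for r in recs:
                fh.write(
                    f"{sid}\t{r.chromosome}\t{r.start}\t{r.end}\t{r.num_marks}\t{r.seg_mean:.6g}\n"
                )


def segments_to_profile(
    records: list[SegRecord], grid: tuple[np.ndarray, np.ndarray], platform: str = ""
) -> CopyNumberProfile:
    """Project one sample's segments onto a probe grid.

    Each grid locus takes the seg_mean of the segment whose [start, end]
    contains it (non-overlap makes this unambiguous); loci covered by no
    segment are missing.
    """
    chrom_codes, positions = grid
    if len(positions) == 0:
        raise ParseError("empty probe grid")
    if not records:
        raise ParseError("no segment records for sample")
    sid = records[0].sample_id
    _check_no_overlap(sid, records)
    values = np.full(len(positions), np.nan)
    by_chrom: dict[int, list[SegRecord]] = {}
    for r in records:
        by_chrom.setdefault(CHROM_TO_CODE[r.chromosome], []).append(r)
    for code, rs in by_chrom.items():
        rs_sorted = sorted(rs, key=lambda r: r.start)
        starts = np.array([r.start for r in rs_sorted])
        ends = np.array([r.end for r in rs_sorted])
        means = np.array([r.seg_mean for r in rs_sorted])
        mask = chrom_codes == code
        pos = positions[mask]
        k = np.searchsorted(starts, pos, side="right") - 1
        kk = np.clip(k, 0, len(ends) - 1)
        inside = (k >= 0) & (pos <= ends[kk])
        vals = np.where(inside, means[kk], np.nan)
        values[mask] = vals
    return CopyNumberProfile(sid, chrom_codes, positions, values, platform=platform)


# ---------------------------------------------------------------------------
# probe matrix and labels
# ---------------------------------------------------------------------------

def read_profile_matrix(path, platform: str = "") -> Cohort:
    """Read a tab-separated probe matrix (chrom, pos, one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise ParseError("probe matrix needs chrom, pos and at least one sample column")
    chrom_col, pos_col = df.columns[:2]
    keep_rows, codes = [], []
    n_dropped = 0
    for i, tok in enumerate(df[chrom_col]):
        chrom = normalize_chromosome(tok)
        if chrom is None:
            n_dropped += 1
            continue
        keep_rows.append(i)
        codes.append(CHROM_TO_CODE[chrom])
    warn_dropped(n_dropped, "probe rows")
    df = df.iloc[keep_rows].reset_index(drop=True)
    chrom_codes = np.array(codes, dtype=np.int64)
    positions = df[pos_col].to_numpy(dtype=np.int64)
    order = np.lexsort((positions, chrom_codes))
    if not np.array_equal(order, np.arange(len(order))):
        import warnings

        warnings.warn("probe matrix loci were unsorted; sorting", stacklevel=2)
        chrom_codes, positions = chrom_codes[order], positions[order]
        df = df.iloc[order].reset_index(drop=True)
    dup = (np.diff(chrom_codes) == 0) & (np.diff(positions) == 0)
    if dup.any():
        i = int(np.flatnonzero(dup)[0]) + 1
        raise ParseError(
            f"duplicate locus {CHROMOSOMES[chrom_codes[i]]}:{positions[i]} in probe matrix"
        )
    profiles = []
    for col in df.columns[2:]:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        profiles.append(CopyNumberProfile(str(col), chrom_codes, positions, values, platform))
    return Cohort(profiles)


def write_profile_matrix(cohort: Cohort, path) -> None:
    ref = cohort.shared_grid()
    data = {
        "chrom": [CHROMOSOMES[c] for c in ref.chrom_codes],
        "pos": ref.positions,
    }
    for p in cohort.profiles:
        data[p.sample_id] = p.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_labels(path) -> dict[str, int]:
    """Two-column TSV: sample_id, intclust in 1..10."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError("label table needs sample_id and intclust columns")
    labels: dict[str, int] = {}
    for sid, val in zip(df.iloc[:, 0], df.iloc[:, 1]):
        iv = int(val)
        if not 1 <= iv <= 10:
            raise ParseError(f"label for {sid!r} out of range 1..10: {val!r}")
        if sid in labels:
            raise ParseError(f"duplicate label row for sample {sid!r}")
        labels[str(sid)] = iv
    return labels


def write_labels(labels: dict[str, int], path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "intclust": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# regions (BED3) and feature matrices
# ---------------------------------------------------------------------------

def write_regions_bed(regions: RegionSet, path) -> None:
    """BED3 export: internal 1-based inclusive [start, end] -> [start-1, end)."""
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\n")


def read_regions_bed(path, provenance: dict | None = None) -> RegionSet:
    regs = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 BED columns")
            chrom = normalize_chromosome(parts[0])
            if chrom is None:
                continue
            regs.append(Region(chrom, int(parts[1]) + 1, int(parts[2])))
    return RegionSet(regs, provenance=provenance or {})


def write_feature_matrix(features: FeatureMatrix, path) -> None:
    features.df.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id", float_format="%.10g")


def read_feature_matrix(path, scaled: bool = False) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix(df, scaled=scaled)


def write_predictions(pred: pd.DataFrame, path) -> None:
    pred.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA", float_format="%.10g")


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# model bundle persistence
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, directory) -> None:
    """Write a bundle directory: JSON metadata + per-model JSON artifacts."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "package_version": __version__,
        "label_scheme": {str(k): v for k, v in bundle.label_scheme.items()},
        "scaler": bundle.scaler.to_dict() if bundle.scaler is not None else None,
        "region_provenance": bundle.regions.provenance,
        "metadata": bundle.metadata,
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))
    write_regions_bed(bundle.regions, d / "regions.bed")
    bundle.multiclass_model.save_model(d / "multiclass.model.json")
    for pair in PAIRS:
        key = pair_key(pair)
        bundle.binary_models[key].save_model(d / f"binary_{pair[0]}_{pair[1]}.model.json")


def load_bundle(directory) -> ModelBundle:
    d = Path(directory)
    meta_path = d / "metadata.json"
    if not meta_path.exists():
        raise ParseError(f"not a bundle directory (missing metadata.json): {d}")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ParseError(
            f"bundle format version mismatch: file has {version}, "
            f"this package reads {BUNDLE_FORMAT_VERSION}"
        )
    regions = read_regions_bed(d / "regions.bed", provenance=meta.get("region_provenance") or {})
    multi = _tag_classifier(xgb.XGBClassifier())
    multi.load_model(d / "multiclass.model.json")
    binaries: dict[str, xgb.XGBClassifier] = {}
    for pair in PAIRS:
        key = pair_key(pair)
        path = d / f"binary_{pair[0]}_{pair[1]}.model.json"
        if not path.exists():
            raise ParseError(f"bundle is missing the binary model for pair {key} ({path.name})")
        m = _tag_classifier(xgb.XGBClassifier())
        m.load_model(path)
        binaries[key] = m
    scaler = ScalingParams.from_dict(meta["scaler"]) if meta.get("scaler") else None
    label_scheme = {int(k): v for k, v in meta["label_scheme"].items()}
    return ModelBundle(
        multiclass_model=multi,
        binary_models=binaries,
        regions=regions,
        scaler=scaler,
        label_scheme=label_scheme,
        metadata=meta.get("metadata", {}),
    )
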