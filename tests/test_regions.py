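"""Region construction, region-mean features and cohort scaling."""

import numpy as np
import pandas as pd
import pytest

from cnclust.core import Cohort, CohortError, CopyNumberProfile
from cnclust.pcf import segment_profile
from cnclust.regions import (
    FeatureMatrix,
    Region,
    RegionError,
    RegionSet,
    apply_scaler,
    build_regions,
    class_average_profile,
    cohort_features,
    fit_scaler,
    region_means,
    scale_features,
)


def _profile(sid, codes, pos, vals):
    return CopyNumberProfile(sid, np.array(codes), np.array(pos), np.array(vals, dtype=float))


class TestClassAverage:
    def test_single_member_class_is_identity(self):
        p = _profile("a", [0, 0], [1, 2], [0.5, -0.5])
        cohort = Cohort([p], {"a": 3})
        avg = class_average_profile(cohort, 3)
        np.testing.assert_array_equal(avg.values, p.values)

    def test_two_samples_average(self):
        a = _profile("a", [0], [1], [0.0])
        b = _profile("b", [0], [1], [2.0])
        avg = class_average_profile(Cohort([a, b], {"a": 1, "b": 1}), 1)
        assert avg.values[0] == pytest.approx(1.0)

    def test_missing_aware_mean(self):
        profs = [
            _profile("a", [0], [1], [1.0]),
            _profile("b", [0], [1], [3.0]),
            _profile("c", [0], [1], [np.nan]),
        ]
        avg = class_average_profile(Cohort(profs, {s: 2 for s in "abc"}), 2)
        assert avg.values[0] == pytest.approx(2.0)

    def test_empty_class_rejected(self):
        p = _profile("a", [0], [1], [0.0])
        with pytest.raises(CohortError, match="no samples"):
            class_average_profile(Cohort([p], {"a": 1}), 5)

    def test_heterogeneous_grids_rejected(self):
        a = _profile("a", [0], [1], [0.0])
        b = _profile("b", [0], [2], [0.0])
        with pytest.raises(CohortError, match="grid"):
            class_average_profile(Cohort([a, b], {"a": 1, "b": 1}), 1)


class TestBuildRegions:
    def test_no_internal_breakpoints_one_region_per_chromosome(self):
        p = _profile("a", [c for c in range(23) for _ in range(2)],
                     [1, 100] * 23, [0.0] * 46)
        seg = segment_profile(p, gamma=1.0)
        rs = build_regions([seg], {c: (1, 100) for c in range(23)})
        assert len(rs) == 23

    def test_union_of_two_classes_breakpoints(self):
        # class A breaks after bp 100, class B after bp 150, extent 1-200
        a = _profile("a", [0] * 4, [50, 150, 151, 200], [0, 0, 4, 4])
        b = _profile("b", [0] * 4, [100, 200, 201, 300], [0, 0, 4, 4])
        sa = segment_profile(a, gamma=0.5)
        sb = segment_profile(b, gamma=0.5)
        assert sa.breakpoints_bp() == [("1", 150)]
        assert sb.breakpoints_bp() == [("1", 200)]
        rs = build_regions([sa, sb], {"1": (1, 300)})
        assert [(r.start_bp, r.end_bp) for r in rs] == [(1, 150), (151, 200), (201, 300)]

    def test_partition_properties(self, balanced_cohort):
        segs = [
            segment_profile(class_average_profile(balanced_cohort, c), gamma=0.01)
            for c in range(1, 11)
        ]
        extents = balanced_cohort.chromosome_extents()
        rs = build_regions(segs, extents)
        by_chrom = {}
        for r in rs:
            by_chrom.setdefault(r.chromosome, []).append(r)
        from cnclust.core import CHROMOSOMES, CHROM_TO_CODE

        for chrom, regs in by_chrom.items():
            lo, hi = extents[CHROM_TO_CODE[chrom]]
            assert regs[0].start_bp == lo
            assert regs[-1].end_bp == hi
            for x, y in zip(regs, regs[1:]):
                assert y.start_bp == x.end_bp + 1  # abutting: no gap, no overlap

    def test_idempotent_and_order_invariant(self, balanced_cohort):
        segs = [
            segment_profile(class_average_profile(balanced_cohort, c), gamma=0.01)
            for c in range(1, 11)
        ]
        extents = balanced_cohort.chromosome_extents()
        a = build_regions(segs, extents)
        b = build_regions(segs[::-1] + segs, extents)  # duplicated + reordered
        assert a == b

    def test_empty_segmentation_list_rejected(self):
        with pytest.raises(RegionError):
            build_regions([], {"1": (1, 100)})


class TestRegionMeans:
    def test_constant_profile(self):
        p = _profile("a", [0] * 4, [10, 20, 30, 40], [2.0] * 4)
        rs = RegionSet([Region("1", 1, 25), Region("1", 26, 50)])
        np.testing.assert_allclose(region_means(p, rs), [2.0, 2.0])

    def test_membership_filter_mean(self):
        p = _profile("a", [0] * 3, [10, 20, 30], [1.0, 2.0, 3.0])
        rs = RegionSet([Region("1", 1, 25), Region("1", 26, 100)])
        np.testing.assert_allclose(region_means(p, rs), [1.5, 3.0])

    def test_region_on_absent_chromosome_missing(self):
        p = _profile("a", [0], [10], [1.0])
        rs = RegionSet([Region("2", 1, 100)])
        assert np.isnan(region_means(p, rs)[0])

    def test_missing_probes_excluded(self):
        p = _profile("a", [0] * 3, [10, 20, 30], [1.0, np.nan, 3.0])
        rs = RegionSet([Region("1", 1, 100)])
        assert region_means(p, rs)[0] == pytest.approx(2.0)


class TestScaling:
    def test_center_and_spread(self):
        fm = FeatureMatrix(pd.DataFrame({"1:1-10": [1.0, 2.0, 3.0]}, index=list("abc")))
        params = fit_scaler(fm)
        assert params.center[0] == pytest.approx(2.0)
        assert params.spread[0] == pytest.approx(np.std([1, 2, 3]))

    def test_constant_column_flagged_spread_one(self):
        fm = FeatureMatrix(pd.DataFrame({"1:1-10": [5.0, 5.0, 5.0]}, index=list("abc")))
        with pytest.warns(UserWarning, match="degenerate"):
            params = fit_scaler(fm)
        assert params.degenerate[0]
        assert params.spread[0] == 1.0

    def test_scaled_columns_standardized(self):
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(50, 10)),
                                        index=[f"s{i}" for i in range(50)],
                                        columns=[f"1:{i*10+1}-{i*10+10}" for i in range(10)]))
        scaled, _ = scale_features(fm)
        np.testing.assert_allclose(scaled.df.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(scaled.df.std(axis=0, ddof=0), 1.0, atol=1e-10)

    def test_affine_shift_gives_identical_scaled_matrix(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 5)),
                          index=[f"s{i}" for i in range(30)],
                          columns=[f"1:{i+1}-{i+1}" for i in range(5)])
        s1, _ = scale_features(FeatureMatrix(df))
        s2, _ = scale_features(FeatureMatrix(0.5 * df + 0.2))
        np.testing.assert_allclose(s1.df.to_numpy(), s2.df.to_numpy(), atol=1e-10)

    def test_missing_entries_preserved(self):
        df = pd.DataFrame({"1:1-10": [1.0, np.nan, 3.0, 4.0]}, index=list("abcd"))
        scaled, _ = scale_features(FeatureMatrix(df))
        assert np.isnan(scaled.df.iloc[1, 0])
        assert np.isfinite(scaled.df.iloc[0, 0])

    def test_too_few_samples_rejected(self):
        fm = FeatureMatrix(pd.DataFrame({"1:1-10": [1.0, 2.0]}, index=list("ab")))
        with pytest.raises(RegionError, match="single sample"):
            fit_scaler(fm)

    def test_column_mismatch_rejected(self):
        a = FeatureMatrix(pd.DataFrame({"1:1-10": [1.0, 2.0, 3.0]}, index=list("abc")))
        b = FeatureMatrix(pd.DataFrame({"2:1-10": [1.0, 2.0, 3.0]}, index=list("abc")))
        params = fit_scaler(a)
        with pytest.raises(RegionError, match="align"):
            apply_scaler(b, params)


class TestCohortFeatures:
    def test_sigma_zero_features_equal_archetype_region_means(self, archetypes, balanced_cohort):
        from cnclust.workflow import derive_regions

        regions = derive_regions(balanced_cohort, gamma=0.01, kmin=1)
        feats = cohort_features(balanced_cohort, regions)
        # noise-free: every sample's features equal its archetype's region means
        for sid in balanced_cohort.sample_ids[:5]:
            cls = balanced_cohort.labels[sid]
            arch_prof = CopyNumberProfile(
                "arch", archetypes.chrom_codes, archetypes.positions,
                archetypes.class_values(cls))
            np.testing.assert_allclose(
                feats.df.loc[sid].to_numpy(), region_means(arch_prof, regions), atol=1e-12
            )
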