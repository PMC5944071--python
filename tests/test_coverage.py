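"""Depth and strand-bias model fitting, region detection and end correction."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from macall.coverage import (
    DepthCorrectionModel,
    DepthDistribution,
    StrandBiasDistribution,
    correct_depths,
    detect_abnormal_regions,
    distance_from_chromosome_end,
    fit_depth_correction,
    fit_depth_distribution,
    fit_strand_bias_distribution,
    strand_bias_p_value,
)
from macall.tracks import CopyNumberMap, DepthTrack, Interval


def _track(values: np.ndarray, chrom: str = "chr1") -> DepthTrack:
    return DepthTrack(depths={chrom: np.asarray(values, dtype=np.float64)})


class TestDepthDistribution:
    def test_recovers_per_copy_gaussian(self):
        rng = np.random.default_rng(21)
        depths = rng.normal(50, 6, size=1_000_000)
        dist = fit_depth_distribution(_track(depths), ploidy=2)
        assert abs(dist.mean - 25.0) < 0.5
        assert abs(dist.std - 3.0) < 0.5

    def test_copy_number_scaling_identity(self):
        rng = np.random.default_rng(22)
        depths = rng.normal(50, 6, size=200_000)
        depths[10_000:20_000] = rng.normal(100, 12, size=10_000)
        cn = CopyNumberMap([(Interval("chr1", 10_000, 20_000), 4)])
        dist = fit_depth_distribution(_track(depths), cn, ploidy=2)
        plain = fit_depth_distribution(
            _track(np.delete(depths, slice(10_000, 20_000))), ploidy=2
        )
        assert abs(dist.mean - plain.mean) < 0.3
        assert abs(dist.std - plain.std) < 0.3

    def test_constant_depth_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_depth_distribution(_track(np.full(1000, 50.0)), ploidy=2)

    def test_invalid_std_rejected(self):
        with pytest.raises(ValueError):
            DepthDistribution(mean=25.0, std=0.0)


class TestAbnormalRegions:
    DIST = DepthDistribution(mean=25.0, std=3.0)

    def test_flat_track_clean(self):
        track = _track(np.full(50_000, 50.0))
        assert detect_abnormal_regions(track, self.DIST, ploidy=2) == []

    def test_planted_high_depth_segment_found(self):
        rng = np.random.default_rng(31)
        depths = rng.normal(50, 6, size=50_000)
        depths[20_000:20_300] *= 3.0
        regions = detect_abnormal_regions(_track(depths), self.DIST, ploidy=2)
        overlapping = [r for r in regions if r.start < 20_300 and r.end > 20_000]
        assert len(overlapping) == 1
        assert not [r for r in regions if r.end < 19_000 or r.start > 21_500]

    def test_merge_distance_controls_region_count(self):
        base = np.full(50_000, 50.0)
        for gap in (1500, 800):
            depths = base.copy()
            depths[10_000:10_050] = 5.0
            depths[10_000 + gap : 10_050 + gap] = 5.0
            regions = detect_abnormal_regions(
                _track(depths), self.DIST, ploidy=2, merge_distance=1000
            )
            assert len(regions) == (2 if gap > 1000 else 1)

    def test_opposite_sides_not_merged(self):
        # boundaries must fall on the same side of the mean
        depths = np.full(20_000, 50.0)
        depths[10_000:10_050] = 5.0
        depths[10_200:10_250] = 150.0
        regions = detect_abnormal_regions(_track(depths), self.DIST, ploidy=2)
        assert len(regions) == 2

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            detect_abnormal_regions(_track(np.ones(100)), self.DIST, window=0)

    def test_null_track_rarely_flagged(self):
        # drawn exactly from the fitted Gaussian: expected significant tests
        # ~ n * p_threshold (window correlation inflates this only mildly)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            depths = rng.normal(50, 6, size=100_000)
            dist = DepthDistribution(mean=25.0, std=3.0 / np.sqrt(25))
            # window-averaged per-copy depths have std sigma/sqrt(window)
            regions = detect_abnormal_regions(_track(depths), dist, ploidy=2)
            hits += len(regions)
        assert hits <= 5 * (100_000 * 1e-4)


class TestStrandBias:
    def test_balanced_strands_mean_near_zero(self):
        rng = np.random.default_rng(41)
        depth = rng.poisson(60, size=100_000)
        top = rng.binomial(depth, 0.5)
        dist = fit_strand_bias_distribution(top, depth - top)
        assert abs(dist.mean) < 0.02

    def test_std_recovered_within_ten_percent(self):
        # counts realising ln-ratios drawn Normal(0, 0.4); depth large enough
        # that counting noise does not inflate the spread
        rng = np.random.default_rng(42)
        n = 100_000
        ln_ratio = rng.normal(0.0, 0.4, size=n)
        depth = 2000
        top = np.rint(depth / (1.0 + np.exp(-ln_ratio))).astype(int)
        dist = fit_strand_bias_distribution(top, depth - top)
        assert abs(dist.mean) < 0.02
        assert abs(dist.std - 0.4) / 0.4 < 0.10

    def test_single_position_rejected(self):
        with pytest.raises(ValueError):
            fit_strand_bias_distribution([30], [30])

    def test_p_value_symmetry(self):
        dist = StrandBiasDistribution(mean=0.0, std=0.3)
        assert strand_bias_p_value(25, 25, dist) == pytest.approx(1.0)

    def test_extreme_bias_tiny_p(self):
        dist = StrandBiasDistribution(mean=0.0, std=0.3)
        # closed-form Gaussian tail for ln(41/1)
        z = np.log(41.0) / 0.3
        expected = 2.0 * stats.norm.sf(z)
        assert strand_bias_p_value(40, 0, dist) == pytest.approx(expected, rel=1e-9)
        assert strand_bias_p_value(40, 0, dist) < 1e-6

    def test_p_monotone_in_imbalance(self):
        dist = StrandBiasDistribution(mean=0.0, std=0.3)
        ps = [strand_bias_p_value(30 + k, 30 - k, dist) for k in range(0, 30, 3)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            strand_bias_p_value(0, 0, StrandBiasDistribution(0.0, 0.3))


TRUE_MODEL = DepthCorrectionModel(
    intercept=1.0, scalar=1.5, mu=np.log(5000.0), sigma=0.5, slope=0.0
)


def _biased_track(seed: int, length: int = 400_000, mean_depth: float = 50.0) -> DepthTrack:
    rng = np.random.default_rng(seed)
    x = distance_from_chromosome_end(length)
    factor = np.asarray(TRUE_MODEL.factor(x))
    depths = rng.normal(mean_depth, 5.0, size=length) * factor
    return _track(depths)


class TestDepthCorrection:
    def test_parameter_recovery(self):
        model = fit_depth_correction(_biased_track(51))
        assert abs(model.intercept - 1.0) < 0.05
        assert abs(model.scalar - 1.5) / 1.5 < 0.15
        assert abs(model.mu - np.log(5000.0)) / np.log(5000.0) < 0.15
        assert abs(model.sigma - 0.5) / 0.5 < 0.15

    def test_unbiased_track_near_identity(self):
        rng = np.random.default_rng(52)
        track = _track(rng.normal(50, 5, size=300_000))
        model = fit_depth_correction(track)
        assert abs(model.intercept - 1.0) < 0.05
        assert abs(model.scalar) < 0.05
        assert abs(model.slope) < 1e-5

    def test_extreme_ratios_excluded_from_medians(self):
        # majority-outlier bins near the chromosome start: without the
        # ratio > 4 exclusion their medians would sit near 6 and drag the
        # fitted factor up; with it the fit stays flat
        rng = np.random.default_rng(53)
        depths = rng.normal(50, 2, size=300_000)
        idx = rng.choice(2500, size=1500, replace=False)
        depths[idx] = 300.0
        model = fit_depth_correction(_track(depths))
        assert float(np.asarray(model.factor(1250.0))) < 1.5
        np.testing.assert_allclose(
            np.asarray(model.factor(np.array([50_000.0, 140_000.0]))), 1.0, atol=0.06
        )

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            fit_depth_correction(_track(np.full(2000, 50.0)))

    def test_correct_depths_identity_when_factor_one(self):
        model = DepthCorrectionModel(intercept=1.0, scalar=0.0, mu=5.0, sigma=1.0, slope=0.0)
        track = _track(np.arange(100, dtype=float))
        out = correct_depths(track, model)
        np.testing.assert_allclose(out["chr1"], track["chr1"])

    def test_end_to_end_bias_removal(self):
        track = _biased_track(54)
        model = fit_depth_correction(track)
        corrected = correct_depths(track, model)
        arr = corrected["chr1"]
        ratios = arr / arr.mean()
        x = distance_from_chromosome_end(len(arr))
        bins = (x - 1) // 500
        medians = [
            np.median(ratios[bins == b]) for b in np.unique(bins)
        ]
        assert min(medians) > 0.95 and max(medians) < 1.05
        # idempotence: re-fitting the corrected track finds no residual bias
        refit = fit_depth_correction(corrected)
        assert abs(refit.scalar) < 0.05

    def test_zeros_preserved(self):
        track = _biased_track(55)
        track["chr1"][100:200] = 0.0
        model = fit_depth_correction(track)
        corrected = correct_depths(track, model)
        assert np.all(corrected["chr1"][100:200] == 0.0)
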