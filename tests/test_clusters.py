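"""Receptor-cluster segmentation, normalization and secondary scoring."""

import numpy as np
import pytest

from conftest import make_image
from nmjquant.clusters import (
    cluster_table,
    normalize_cluster_count,
    score_secondary_channel,
    segment_clusters,
    segment_myotubes_for_normalization,
)
from nmjquant.errors import DenominatorError, DimensionError, ParameterError
from nmjquant.synthetic import SynthSpec, generate_coculture_image


class TestSegmentClusters:
    def test_blank_channel_zero_clusters(self):
        assert segment_clusters(make_image(np.zeros((64, 64))), 10.0).n_labels == 0

    def test_single_square_forced_case(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 100.0
        mask = segment_clusters(make_image(img), threshold=50.0, min_area_px2=4)
        assert mask.n_labels == 1
        f = mask.features[0]
        assert f.area_px2 == 100
        assert f.mean_intensity == 100.0

    def test_planted_discs_recovered(self):
        spec = SynthSpec(n_clusters=25, snr=10, seed=31)
        channels, truth = generate_coculture_image(spec)
        btx = channels[1]
        thr = spec.background + 0.5 * 0.8 * spec.amplitude
        mask = segment_clusters(btx, thr, min_area_px2=4)
        assert mask.n_labels == 25
        got = sorted(f.area_px2 for f in mask.features)
        planted = sorted(r.true_area_px2 for r in truth.cluster_records)
        for g, p in zip(got, planted):
            assert abs(g - p) / p <= 0.10

    def test_raising_threshold_never_grows_total_area(self, rng):
        img = make_image(rng.uniform(0, 100, size=(64, 64)))
        areas = []
        for thr in (20.0, 40.0, 60.0, 80.0):
            mask = segment_clusters(img, thr, min_area_px2=0)
            areas.append(sum(f.area_px2 for f in mask.features))
        assert areas == sorted(areas, reverse=True)

    def test_mean_area_translation_invariant(self):
        img = np.zeros((64, 64))
        img[10:16, 10:18] = 90.0
        img[40:45, 30:36] = 90.0
        a = cluster_table(segment_clusters(make_image(img), 50.0), 0.5)
        b = cluster_table(segment_clusters(make_image(np.roll(img, (7, 5), (0, 1))), 50.0), 0.5)
        assert a.mean_area_um2 == b.mean_area_um2


class TestMyotubeNormalization:
    def test_blank_image_area_zero(self):
        mask, area = segment_myotubes_for_normalization(make_image(np.zeros((32, 32))))
        assert area == 0.0 and mask.n_labels == 0

    def test_planted_fraction_arithmetic(self):
        img = np.zeros((1000, 1000))
        img[:400, :] = 100.0  # 40% coverage
        _, area = segment_myotubes_for_normalization(
            make_image(img, pixel_size_um=0.5), (0, 100), threshold=0.5
        )
        assert area == pytest.approx(0.4 * 1000**2 * 0.25 / 1e6, rel=1e-12)  # 0.1 mm2

    def test_planted_blobs_recovered_within_ten_percent(self):
        spec = SynthSpec(snr=10, seed=33)
        channels, truth = generate_coculture_image(spec)
        _, area = segment_myotubes_for_normalization(channels[0], (1, 99), 0.5)
        true_area = truth.myotube_mask.sum() * spec.pixel_size_um**2 / 1e6
        assert abs(area - true_area) / true_area <= 0.10

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ParameterError):
            segment_myotubes_for_normalization(make_image(np.ones((8, 8))), (50, 50))


class TestNormalizeClusterCount:
    def test_zero_clusters(self):
        table = cluster_table(segment_clusters(make_image(np.zeros((16, 16))), 1.0), 0.5)
        assert normalize_cluster_count(table, 2.0).clusters_per_mm2 == 0.0

    def test_fifty_clusters_per_half_mm2(self):
        img = np.zeros((200, 200))
        for i in range(5):
            for j in range(10):
                img[5 + 19 * i: 10 + 19 * i, 5 + 19 * j: 10 + 19 * j] = 100.0
        table = cluster_table(segment_clusters(make_image(img), 50.0), 0.5)
        assert table.n_clusters == 50
        assert normalize_cluster_count(table, 0.5).clusters_per_mm2 == 100.0

    def test_ground_truth_normalization_exact(self):
        spec = SynthSpec(n_clusters=25, seed=35)
        _, truth = generate_coculture_image(spec)
        true_mm2 = truth.myotube_mask.sum() * spec.pixel_size_um**2 / 1e6
        table = cluster_table(
            segment_clusters(
                make_image(np.zeros((8, 8))), 1.0  # empty; only count matters below
            ),
            spec.pixel_size_um,
        )
        table.records = [{"area_um2": 0.0, "mean_intensity_au": 0.0}] * 25
        got = normalize_cluster_count(table, true_mm2).clusters_per_mm2
        assert got == pytest.approx(25 / true_mm2, rel=1e-12)

    def test_zero_area_rejected(self):
        table = cluster_table(segment_clusters(make_image(np.zeros((8, 8))), 1.0), 0.5)
        with pytest.raises(DenominatorError):
            normalize_cluster_count(table, 0.0)


class TestSecondaryScoring:
    def _one_cluster(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 100.0
        return segment_clusters(make_image(img), 50.0)

    def test_blank_secondary_zero_fraction(self):
        calls, frac = score_secondary_channel(
            self._one_cluster(), make_image(np.zeros((32, 32))), "mean_gt", 0.0
        )
        assert frac == 0.0

    def test_identical_secondary_full_fraction(self):
        sec = np.zeros((32, 32))
        sec[10:20, 10:20] = 100.0
        calls, frac = score_secondary_channel(
            self._one_cluster(), make_image(sec), "mean_gt", 50.0
        )
        assert frac == 1.0

    def test_overlap_rule_with_explicit_binarization(self):
        sec = np.zeros((32, 32))
        sec[10:20, 10:15] = 100.0  # covers half the cluster
        mask = self._one_cluster()
        _, frac_low = score_secondary_channel(
            mask, make_image(sec), "overlap_frac", 0.25, binarize_threshold=50.0
        )
        _, frac_high = score_secondary_channel(
            mask, make_image(sec), "overlap_frac", 0.75, binarize_threshold=50.0
        )
        assert frac_low == 1.0 and frac_high == 0.0

    def test_planted_copositive_fraction_recovered(self):
        spec = SynthSpec(n_clusters=25, rapsyn_fraction=0.6, snr=10, seed=37)
        channels, truth = generate_coculture_image(spec)
        mask = segment_clusters(channels[1], spec.background + 0.4 * spec.amplitude)
        _, frac = score_secondary_channel(
            mask, channels[2], "mean_gt", spec.background + 0.5 * spec.amplitude
        )
        assert abs(frac - 0.6) <= 0.05

    def test_unknown_rule_and_shape_mismatch(self):
        mask = self._one_cluster()
        with pytest.raises(ParameterError):
            score_secondary_channel(mask, make_image(np.zeros((32, 32))), "votes", 0.5)
        with pytest.raises(DimensionError):
            score_secondary_channel(mask, make_image(np.zeros((16, 16))), "mean_gt", 0.5)
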