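"""Ground-truth consistency and determinism of the synthetic generator."""

import numpy as np
import pytest

from nmjquant.elongation import ElongationParams, filter_residuals, narrow_residual
from nmjquant.errors import CapacityError, ParameterError
from nmjquant.synthetic import (
    SynthSpec,
    capsule_mask,
    generate_cell_body_image,
    generate_coculture_image,
    generate_nuclei_image,
)


class TestNucleiGenerator:
    def test_zero_nuclei_gives_blank_field(self):
        spec = SynthSpec(n_nuclei=0, seed=3)
        dapi, marker, truth = generate_nuclei_image(spec)
        assert len(truth.nucleus_centers) == 0
        # only background + noise remains
        assert dapi.pixels.max() < spec.background + 6 * spec.noise_sigma
        assert marker.pixels.max() < spec.background + 6 * spec.noise_sigma

    def test_positive_count_is_rounded_fraction(self):
        _, _, truth = generate_nuclei_image(SynthSpec(n_nuclei=200, positive_fraction=0.6, seed=0))
        assert truth.nucleus_positive_flags.sum() == 120

    def test_same_seed_bit_identical(self):
        spec = SynthSpec(n_nuclei=50, seed=11)
        a = generate_nuclei_image(spec)
        b = generate_nuclei_image(SynthSpec(n_nuclei=50, seed=11))
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1].pixels, b[1].pixels)
        np.testing.assert_array_equal(a[2].nucleus_centers, b[2].nucleus_centers)

    def test_minimum_center_separation(self):
        spec = SynthSpec(n_nuclei=100, seed=5)
        _, _, truth = generate_nuclei_image(spec)
        c = truth.nucleus_centers
        d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 2 * spec.nucleus_radius_px

    def test_infeasible_density_reports_capacity(self):
        with pytest.raises(CapacityError):
            generate_nuclei_image(SynthSpec(image_shape=(64, 64), n_nuclei=500, seed=0))

    def test_snr_contract_on_blank_field(self):
        # noise sd measured over >= 1e4 blank pixels within 5% of peak/snr
        spec = SynthSpec(n_nuclei=0, image_shape=(128, 128), snr=10.0, seed=7)
        dapi, _, _ = generate_nuclei_image(spec)
        measured = dapi.pixels.std()
        assert abs(measured - spec.noise_sigma) / spec.noise_sigma < 0.05


class TestCellBodyGenerator:
    def test_single_spindle_truth_is_one_capsule(self):
        spec = SynthSpec(n_nuclei=1, cell_morphology="spindle", seed=2)
        _, truth = generate_cell_body_image(spec)
        area = truth.cell_body_mask.sum()
        expected = (150 - 8) * 8 + np.pi * 16  # rectangle + caps
        assert area == pytest.approx(expected, rel=0.06)

    def test_round_bodies_leave_no_narrow_residual(self):
        # discs of this size contain no sub-17-px-wide parts, so the
        # radius-8 opening residual is filtered to nothing
        spec = SynthSpec(n_nuclei=5, cell_morphology="round", seed=4)
        _, truth = generate_cell_body_image(spec)
        params = ElongationParams()
        residual = narrow_residual(truth.cell_body_mask, params)
        assert filter_residuals(residual, params).n_labels == 0

    def test_same_seed_identical(self):
        spec = SynthSpec(n_nuclei=6, cell_morphology="spindle", seed=9)
        a, _ = generate_cell_body_image(spec)
        b, _ = generate_cell_body_image(SynthSpec(n_nuclei=6, cell_morphology="spindle", seed=9))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_bodies_respect_frame_margin(self):
        spec = SynthSpec(n_nuclei=8, cell_morphology="spindle", seed=1)
        _, truth = generate_cell_body_image(spec)
        border = np.zeros(spec.image_shape, bool)
        border[:19, :] = border[-19:, :] = True
        border[:, :19] = border[:, -19:] = True
        assert not (truth.cell_body_mask & border).any()

    def test_unknown_morphology_rejected(self):
        with pytest.raises(ParameterError):
            SynthSpec(cell_morphology="stellate")


class TestCocultureGenerator:
    def test_zero_clusters_blank_btx(self):
        spec = SynthSpec(n_clusters=0, seed=6)
        channels, truth = generate_coculture_image(spec)
        btx = channels[1]
        assert truth.cluster_records == []
        assert btx.pixels.max() < spec.background + 6 * spec.noise_sigma

    def test_cluster_records_match_request(self):
        channels, truth = generate_coculture_image(SynthSpec(n_clusters=25, seed=8))
        assert len(truth.cluster_records) == 25

    def test_clusters_lie_on_myotube_mask(self):
        _, truth = generate_coculture_image(SynthSpec(n_clusters=20, seed=12))
        for rec in truth.cluster_records:
            r, c = (int(round(x)) for x in rec.center)
            assert truth.myotube_mask[r, c]

    def test_analytic_count_per_mm2(self):
        spec = SynthSpec(n_clusters=25, seed=3)
        _, truth = generate_coculture_image(spec)
        area_px = truth.myotube_mask.sum()  # brute-force pixel count
        area_mm2 = area_px * spec.pixel_size_um**2 / 1e6
        expected = 25 / area_mm2
        assert len(truth.cluster_records) / (
            sum(truth.myotube_areas_um2) / 1e6
        ) == pytest.approx(expected, rel=1e-12)

    def test_noise_free_threshold_recovers_planted_masks(self):
        # at very high SNR, exact thresholding recovers planted geometry
        spec = SynthSpec(n_clusters=15, snr=1e6, seed=5)
        channels, truth = generate_coculture_image(spec)
        myo, btx, _ = channels
        recovered = myo.pixels > spec.background + 0.5 * spec.amplitude
        np.testing.assert_array_equal(recovered, truth.myotube_mask)
        btx_mask = btx.pixels > spec.background + 0.5 * 0.8 * spec.amplitude
        assert btx_mask.sum() == sum(r.true_area_px2 for r in truth.cluster_records)

    def test_myotube_fraction_approximate(self):
        spec = SynthSpec(myotube_fraction=0.4, seed=2)
        _, truth = generate_coculture_image(spec)
        frac = truth.myotube_mask.mean()
        assert frac == pytest.approx(0.4, abs=0.01)

    def test_determinism(self):
        a, _ = generate_coculture_image(SynthSpec(seed=13))
        b, _ = generate_coculture_image(SynthSpec(seed=13))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pixels, y.pixels)

    def test_fraction_bounds_validated(self):
        with pytest.raises(ParameterError):
            generate_coculture_image(SynthSpec(myotube_fraction=0.0))


def test_capsule_mask_dimensions():
    mask = capsule_mask((60, 200), (30.0, 100.0), 150.0, 8.0, 0.0)
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    assert len(rows) in (8, 9)
    assert len(cols) in (150, 151)
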