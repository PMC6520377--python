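"""Confocal image metrics on synthetic striated images and masks."""

import numpy as np
import pytest
from skimage.transform import rotate

from slicephys import (
    cell_morphometrics,
    gen_striated_image,
    heterogeneity_index,
    percent_positive_area,
    ttubule_density,
    ttubule_regularity,
)


class TestPercentPositiveArea:
    def test_all_background_with_fixed_threshold(self):
        assert percent_positive_area(np.zeros((32, 32)), 0.5) == 0.0

    def test_half_foreground(self):
        image = np.zeros((40, 40))
        image[:20] = 1.0
        assert percent_positive_area(image, 0.5) == pytest.approx(50.0)

    def test_generator_fraction_recovered(self):
        image, _, truth = gen_striated_image(positive_fraction=0.3)
        measured = percent_positive_area(image, 0.5)
        assert measured == pytest.approx(
            100.0 * truth.derived_truths["positive_fraction"], abs=2.0
        )

    def test_constant_image_with_otsu_rejected(self):
        with pytest.raises(ValueError):
            percent_positive_area(np.full((16, 16), 3.0), "otsu")

    def test_threshold_scaling_invariance(self):
        image, _, _ = gen_striated_image(positive_fraction=0.4)
        assert percent_positive_area(7.0 * image, 7.0 * 0.5) == pytest.approx(
            percent_positive_area(image, 0.5)
        )


class TestTtubuleDensity:
    def test_unstained_interior_is_zero(self):
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        assert ttubule_density(np.zeros((40, 40)), mask, 0.5) == 0.0

    def test_generator_fraction_recovered(self):
        image, mask, truth = gen_striated_image(
            positive_fraction=0.4, cell_mask_shape=(64, 256)
        )
        density = ttubule_density(image, mask, 0.5, pixel_um=0.1, erosion_margin_um=1.0)
        assert density == pytest.approx(truth.derived_truths["positive_fraction"], abs=0.02)

    def test_erosion_larger_than_cell_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        with pytest.raises(ValueError):
            ttubule_density(np.ones((20, 20)), mask, 0.5, pixel_um=1.0,
                            erosion_margin_um=10.0)


class TestTtubuleRegularity:
    def test_peak_at_generator_period(self):
        image, mask, _ = gen_striated_image(
            period_um=1.9, pixel_um=0.1, cell_mask_shape=(64, 256)
        )
        result = ttubule_regularity(image, mask, 0.0, 0.1)
        bin_hz = 1.0 / (256 * 0.1)  # spatial-frequency resolution
        assert abs(1.0 / result.peak_period_um - 1.0 / 1.9) <= bin_hz

    def test_pure_sinusoid_scores_near_one(self):
        image, mask, _ = gen_striated_image(pattern="sine", cell_mask_shape=(64, 256))
        result = ttubule_regularity(image, mask, 0.0, 0.1)
        assert result.regularity_power > 0.98

    def test_uniform_intensity_scores_zero(self):
        mask = np.ones((64, 256), bool)
        result = ttubule_regularity(np.full((64, 256), 2.0), mask, 0.0, 0.1)
        assert result.regularity_power == pytest.approx(0.0, abs=1e-9)

    def test_power_in_unit_interval(self):
        for seed in range(4):
            image, mask, _ = gen_striated_image(
                phase_jitter_sd_um=0.3, cell_mask_shape=(64, 256), seed=seed
            )
            power = ttubule_regularity(image, mask, 0.0, 0.1).regularity_power
            assert 0.0 <= power <= 1.0

    def test_regularity_decreases_with_phase_jitter(self):
        powers = []
        for sd in (0.0, 0.1, 0.25, 0.5):
            image, mask, _ = gen_striated_image(
                phase_jitter_sd_um=sd, pattern="sine", cell_mask_shape=(64, 256),
                seed=3,
            )
            powers.append(ttubule_regularity(image, mask, 0.0, 0.1).regularity_power)
        assert all(a > b for a, b in zip(powers, powers[1:]))

    def test_short_profile_rejected(self):
        image, mask, _ = gen_striated_image(cell_mask_shape=(16, 32))
        with pytest.raises(ValueError):
            ttubule_regularity(image, mask, 0.0, 0.1)


class TestMorphometrics:
    def test_rectangle_area_and_ratio(self):
        labels = np.zeros((200, 200), int)
        labels[50:70, 40:140] = 1
        frame = cell_morphometrics(labels, pixel_um=1.0)
        assert frame["area_um2"].iloc[0] == pytest.approx(2000.0)
        assert frame["length_width_ratio"].iloc[0] == pytest.approx(5.0, abs=0.2)

    def test_ratio_rotation_invariant(self):
        labels = np.zeros((200, 200), float)
        labels[50:70, 40:140] = 1.0
        ratios = []
        for angle in (0, 30, 60, 90):
            rotated = (rotate(labels, angle, order=0) > 0.5).astype(int)
            ratios.append(
                cell_morphometrics(rotated, 1.0)["length_width_ratio"].iloc[0]
            )
        assert max(ratios) / min(ratios) < 1.05

    def test_disc_ratio_near_one(self):
        yy, xx = np.mgrid[0:101, 0:101]
        labels = ((yy - 50) ** 2 + (xx - 50) ** 2 <= 40**2).astype(int)
        frame = cell_morphometrics(labels, 1.0)
        assert frame["length_width_ratio"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_small_regions_excluded(self):
        labels = np.zeros((50, 50), int)
        labels[10:30, 10:30] = 1
        labels[40:42, 40:43] = 2  # 6 px, below the exclusion limit
        frame = cell_morphometrics(labels, 1.0)
        assert list(frame["label"]) == [1]
        assert frame.attrs["excluded"] == [2]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cell_morphometrics(np.zeros((20, 20), int), 1.0)


class TestHeterogeneity:
    def test_uniform_random_stain_low_cv(self):
        rng = np.random.default_rng(1)
        image = (rng.random((200, 200)) < 0.3).astype(float)
        cv = heterogeneity_index(image, tile_um=50.0, pixel_um=1.0,
                                 threshold_method=0.5)
        assert cv < 0.1

    def test_single_quadrant_stain_cv_sqrt3(self):
        image = np.zeros((100, 100))
        image[:50, :50] = 1.0
        cv = heterogeneity_index(image, tile_um=50.0, pixel_um=1.0,
                                 threshold_method=0.5)
        assert cv == pytest.approx(np.sqrt(3.0), rel=1e-9)

    def test_too_few_tiles_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_index(np.ones((30, 30)), tile_um=30.0, pixel_um=1.0,
                                threshold_method=0.5)
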