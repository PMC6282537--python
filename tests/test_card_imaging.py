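"""Rasterization against a brute-force oracle; segmentation exactness."""

import math

import numpy as np
import pytest

from wspdeposit import (
    CardImage,
    PlacementError,
    SegmentationConfig,
    binarize,
    blank_card,
    extract_stains,
    generate_card,
    generate_touching_pair,
    rasterize_circle,
    read_card,
    sample_field_diameters,
    sample_log_uniform_diameters,
    segment_card,
    write_card,
)
from conftest import rasterize_oracle

PITCH_600 = 25400.0 / 600.0


class TestCardImage:
    def test_pixel_pitch_from_dpi(self):
        card = blank_card(10, 10, 600.0)
        assert card.pitch_um == pytest.approx(PITCH_600)

    def test_physical_area(self):
        card = blank_card(236, 236, 600.0)
        assert card.area_cm2 == pytest.approx(236 * 236 * PITCH_600**2 * 1e-8)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            CardImage(np.zeros((4, 4, 3)), 600.0)


class TestRasterizeCircle:
    def test_one_pitch_circle_sets_exactly_one_pixel(self):
        card = blank_card(11, 11, 600.0)
        n = rasterize_circle(card, (5, 5), PITCH_600)
        assert n == 1
        assert (card.pixels == 0).sum() == 1
        assert card.pixels[5, 5] == 0

    @pytest.mark.parametrize("diameter_um", [95.5, 200.0, 517.3, 1438.0])
    def test_matches_brute_force_pixel_oracle(self, diameter_um):
        card = blank_card(64, 64, 600.0)
        rasterize_circle(card, (31.0, 30.0), diameter_um)
        got = {(x, y) for y, x in zip(*np.nonzero(card.pixels == 0))}
        want = rasterize_oracle(64, 64, (31.0, 30.0), 0.5 * diameter_um / PITCH_600)
        assert got == want

    def test_large_stain_measured_diameter_close_to_true(self):
        # 1438 µm at 600 dpi is ~34 px across; equivalent-circle diameter
        # from the pixel count should land within 3% of the true diameter
        card = blank_card(64, 64, 600.0)
        n = rasterize_circle(card, (31.5, 31.5), 1438.0)
        measured = 2 * math.sqrt(n * PITCH_600**2 / math.pi)
        assert measured == pytest.approx(1438.0, rel=0.03)

    def test_subpixel_stain_still_rasterizes(self):
        # 95.5 µm is ~2.3 px across at 600 dpi
        card = blank_card(16, 16, 600.0)
        n = rasterize_circle(card, (8, 8), 95.5)
        assert 1 <= n <= 5

    def test_out_of_bounds_circle_rejected(self):
        card = blank_card(16, 16, 600.0)
        with pytest.raises(ValueError):
            rasterize_circle(card, (1, 8), 1438.0)

    def test_convergence_with_resolution(self):
        # relative diameter error < 1% at >= 2400 dpi for d >= 200 µm
        for d_um in (200.0, 600.0):
            dpi = 2400.0
            pitch = 25400.0 / dpi
            side = int(math.ceil(d_um / pitch)) + 8
            card = blank_card(side, side, dpi)
            n = rasterize_circle(card, ((side - 1) / 2, (side - 1) / 2), d_um)
            measured = 2 * math.sqrt(n * pitch**2 / math.pi)
            assert abs(measured - d_um) / d_um < 0.01


class TestTouchingPair:
    def test_separated_pair_segments_as_two(self):
        card = generate_touching_pair(200.0, touching=False)
        _, stains = segment_card(card)
        assert len(stains) == 2

    def test_tangent_pair_segments_as_one_matching_pixel_oracle(self):
        card = generate_touching_pair(200.0, touching=True)
        _, stains = segment_card(card)
        assert len(stains) == 1
        # the merged component must equal the union of the two rasterized
        # discs, pixel for pixel (brute-force center-in-circle oracle)
        r_px = 0.5 * 200.0 / PITCH_600
        ys, xs = np.nonzero(card.pixels == 0)
        cy = (card.height_px - 1) / 2.0
        cx1 = 4 + r_px + 0.5  # margin_px + radius + 0.5, as placed
        union = rasterize_oracle(card.width_px, card.height_px, (cx1, cy), r_px) | rasterize_oracle(
            card.width_px, card.height_px, (cx1 + 2 * r_px, cy), r_px
        )
        assert {(x, y) for y, x in zip(ys, xs)} == union
        assert stains[0].pixel_count == len(union)
        # and sit near double the analytic single-stain area, up to the
        # coarse 600-dpi discretization of a ~5-px disc
        assert stains[0].area_um2 == pytest.approx(2 * math.pi * 100.0**2, rel=0.10)

    def test_tangent_pair_area_within_5pct_at_moderate_size(self):
        # at 500 µm (~12 px across) discretization error is small enough
        # that the merged area lands within 5% of 2*pi*r^2
        card = generate_touching_pair(500.0, touching=True)
        _, stains = segment_card(card)
        assert len(stains) == 1
        assert stains[0].area_um2 == pytest.approx(2 * math.pi * 250.0**2, rel=0.05)

    @pytest.mark.parametrize("d_um", [95.5, 96.0, 250.0, 700.0, 1438.0])
    def test_tangent_merges_and_separated_splits_across_sizes(self, d_um):
        for touching, expected in ((True, 1), (False, 2)):
            card = generate_touching_pair(d_um, touching=touching)
            _, stains = segment_card(card)
            assert len(stains) == expected

    def test_tangent_pair_extent_is_2d_by_d(self):
        # merged bounding box spans ~two diameters horizontally, one vertically
        card = generate_touching_pair(96.0 * 5, touching=True)  # 480 µm, ~11 px
        mask = binarize(card)
        ys, xs = np.nonzero(mask)
        w = xs.max() - xs.min() + 1
        h = ys.max() - ys.min() + 1
        assert w == pytest.approx(2 * h, abs=2)


class TestGenerateCard:
    def test_empty_diameter_list_gives_blank_card(self):
        card, truth = generate_card([], rng=0)
        assert truth.empty
        assert (card.pixels == 255).all()

    def test_ground_truth_conserves_pixels_and_count(self, rng):
        diam = sample_log_uniform_diameters(33, rng=rng)
        card, truth = generate_card(diam, width_px=1024, height_px=1024, rng=rng)
        mask, stains = segment_card(card)
        assert len(stains) == 33
        assert int(mask.sum()) == int(truth["pixel_count"].sum())
        assert sum(s.pixel_count for s in stains) == int(mask.sum())

    def test_reproducible_from_seed(self):
        diam = [300.0, 150.0, 700.0]
        card1, truth1 = generate_card(diam, rng=42)
        card2, truth2 = generate_card(diam, rng=42)
        assert np.array_equal(card1.pixels, card2.pixels)
        assert truth1.equals(truth2)

    def test_placement_failure_raises_helpful_error(self):
        with pytest.raises(PlacementError, match="larger card"):
            generate_card([1438.0] * 50, width_px=80, height_px=80, rng=0)

    def test_field_diameter_sampler_is_right_skewed(self, rng):
        d = sample_field_diameters(4000, rng=rng)
        assert d.min() >= 52.8 and d.max() <= 1438.0
        frac_small = (d <= 100).mean()
        frac_under_200 = (d < 200).mean()
        assert 0.25 < frac_small < 0.45
        assert frac_under_200 > 0.65


class TestBinarize:
    def test_noiseless_card_exact(self, rng):
        card, _ = generate_card([200.0, 400.0, 900.0], rng=rng)
        truth_mask = card.pixels == 0
        assert np.array_equal(binarize(card), truth_mask)

    def test_all_background_card_empty_mask_with_warning(self):
        card = blank_card(32, 32, 600.0)
        with pytest.warns(UserWarning, match="uniform"):
            mask = binarize(card)
        assert not mask.any()

    def test_gaussian_noise_near_exact(self, rng):
        card, _ = generate_card([300.0, 500.0, 800.0], rng=rng)
        truth_mask = card.pixels == 0
        noisy = np.clip(card.pixels.astype(float) + rng.normal(0, 10, card.pixels.shape), 0, 255)
        mask = binarize(CardImage(np.round(noisy).astype(np.uint8), 600.0))
        disagreement = (mask != truth_mask).mean()
        assert disagreement < 0.01

    def test_fixed_threshold_and_lighter_stains(self):
        card = blank_card(8, 8, 600.0, background=0)
        card.pixels[2, 2] = 200
        cfg = SegmentationConfig(threshold_mode="fixed", fixed_threshold=100, stains_darker=False)
        assert binarize(card, cfg).sum() == 1


class TestExtractStains:
    def test_n_disjoint_discs_give_n_records(self, rng):
        card, truth = generate_card([250.0] * 6, rng=rng)
        _, stains = segment_card(card)
        assert len(stains) == 6
        assert sorted(s.pixel_count for s in stains) == sorted(truth["pixel_count"])

    def test_area_matches_rasterized_count(self):
        card = blank_card(32, 32, 600.0)
        n = rasterize_circle(card, (15, 15), 100.0)
        _, stains = segment_card(card)
        assert stains[0].pixel_count == n
        assert stains[0].area_um2 == pytest.approx(n * PITCH_600**2)

    def test_min_pixels_filters_specks(self):
        card = blank_card(32, 32, 600.0)
        rasterize_circle(card, (8, 8), PITCH_600)  # 1-px speck
        rasterize_circle(card, (22, 22), 400.0)
        cfg = SegmentationConfig(min_pixels=4)
        _, stains = segment_card(card, cfg)
        assert len(stains) == 1

    def test_connectivity_4_splits_diagonal_touch(self):
        px = np.full((4, 4), 255, dtype=np.uint8)
        px[0, 0] = px[1, 1] = 0
        card = CardImage(px, 600.0)
        mask = binarize(card, SegmentationConfig(threshold_mode="fixed", fixed_threshold=10))
        assert len(extract_stains(mask, 600.0, SegmentationConfig(connectivity=8))) == 1
        assert len(extract_stains(mask, 600.0, SegmentationConfig(connectivity=4))) == 2


class TestImageIO:
    def test_png_round_trip(self, tmp_path, rng):
        card, _ = generate_card([300.0, 600.0], rng=rng)
        path = tmp_path / "card.png"
        write_card(card, path)
        back = read_card(path, 600.0)
        assert np.array_equal(back.pixels, card.pixels)

    def test_color_input_converts_by_luminance(self, tmp_path):
        import imageio.v3 as iio

        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        rgb[:4] = [255, 0, 0]
        path = tmp_path / "color.png"
        iio.imwrite(path, rgb)
        card = read_card(path, 600.0)
        assert card.pixels.ndim == 2
        assert card.pixels[0, 0] == round(0.299 * 255)
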