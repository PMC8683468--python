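import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.ndimage import grey_opening
from skimage.morphology import disk

from miiquant.synthetic import SceneSpec, generate_scene
from miiquant.transform import (
    PipelineConfig,
    dilate,
    enhance_contrast,
    measure_mii,
    median_filter,
    remove_noise_objects,
    subtract_background,
    threshold,
    transform_image,
)

N_ORACLE_SEEDS = 100


# ---------------------------------------------------------------------------
# brute-force reference implementations

def brute_threshold(img, level, dark_on_bright=True):
    out = np.zeros(img.shape, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = img[i, j] <= level if dark_on_bright else img[i, j] >= level
    return out


def brute_dilate(mask, selem):
    h, w = mask.shape
    out = np.zeros_like(mask)
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
               if selem == "square3" or di == 0 or dj == 0]
    for i in range(h):
        for j in range(w):
            out[i, j] = any(
                0 <= i + di < h and 0 <= j + dj < w and mask[i + di, j + dj]
                for di, dj in offsets
            )
    return out


def brute_median(img, radius):
    h, w = img.shape
    out = np.zeros_like(img)
    for i in range(h):
        for j in range(w):
            vals = [img[a, b]
                    for a in range(max(0, i - radius), min(h, i + radius + 1))
                    for b in range(max(0, j - radius), min(w, j + radius + 1))]
            out[i, j] = int(np.floor(np.median(vals) + 0.5))
    return out


def brute_mii(img, mask, mode):
    total = count = 0
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            if mode == "whole_image" or mask[i, j]:
                total += float(img[i, j])
                count += 1
    return total / count if count else 0.0


# ---------------------------------------------------------------------------

class TestThreshold:
    def test_all_below_level(self):
        assert threshold(np.zeros((4, 4), np.uint8), 154).all()

    def test_boundary_pixel_is_foreground_both_polarities(self):
        img = np.array([[154]], np.uint8)
        assert threshold(img, 154, "dark_on_bright")[0, 0]
        assert threshold(img, 154, "bright_on_dark")[0, 0]

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            threshold(np.zeros((2, 2), np.uint8), 300)

    def test_matches_bruteforce_many_seeds(self):
        for seed in range(N_ORACLE_SEEDS):
            r = np.random.default_rng(seed)
            img = r.integers(0, 256, (16, 16), dtype=np.uint8)
            level = int(r.integers(0, 256))
            assert np.array_equal(threshold(img, level), brute_threshold(img, level))
            assert np.array_equal(
                threshold(img, level, "bright_on_dark"),
                brute_threshold(img, level, dark_on_bright=False),
            )

    @given(arrays(np.uint8, (8, 8)), st.integers(0, 255))
    def test_idempotent_through_mask_image(self, img, level):
        """Re-thresholding a mask rendered as 0/255 reproduces the mask."""
        mask = threshold(img, level)
        as_image = np.where(mask, 0, 255).astype(np.uint8)
        assert np.array_equal(threshold(as_image, level), mask)


class TestDilate:
    def test_single_pixel_becomes_3x3_block(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        out = dilate(mask, "square3")
        assert out.sum() == 9 and out[1:4, 1:4].all()

    def test_cross_selem(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert dilate(mask, "cross3").sum() == 5

    def test_all_false_stays_false(self):
        assert not dilate(np.zeros((4, 4), bool)).any()

    @pytest.mark.parametrize("selem", ["square3", "cross3"])
    def test_matches_bruteforce_many_seeds(self, selem):
        for seed in range(N_ORACLE_SEEDS):
            mask = np.random.default_rng(seed).random((16, 16)) < 0.2
            assert np.array_equal(dilate(mask, selem), brute_dilate(mask, selem))

    @given(arrays(bool, (10, 10)))
    def test_result_is_superset(self, mask):
        assert (dilate(mask) | mask == dilate(mask)).all()


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((6, 6), 42, np.uint8)
        assert np.array_equal(median_filter(img, 1), img)

    def test_single_outlier_removed(self):
        img = np.full((5, 5), 100, np.uint8)
        img[2, 2] = 255
        assert np.array_equal(median_filter(img, 1), np.full((5, 5), 100, np.uint8))

    def test_matches_bruteforce_many_seeds(self):
        for seed in range(N_ORACLE_SEEDS):
            img = np.random.default_rng(seed).integers(0, 256, (16, 16), dtype=np.uint8)
            assert np.array_equal(median_filter(img, 1), brute_median(img, 1))

    def test_radius_2_matches_bruteforce(self):
        img = np.random.default_rng(7).integers(0, 256, (12, 12), dtype=np.uint8)
        assert np.array_equal(median_filter(img, 2), brute_median(img, 2))


class TestSubtractBackground:
    def test_constant_image_fully_removed(self):
        img = np.full((30, 30), 180, np.uint8)
        assert subtract_background(img, 5).max() == 0

    def test_dark_spot_on_bright_field(self):
        img = np.full((40, 40), 220, np.uint8)
        img[20:23, 10:13] = 50
        out = subtract_background(img, 10)
        spot = np.zeros((40, 40), bool)
        spot[20:23, 10:13] = True
        assert (out[spot] > 0).all()
        assert out[~spot].max() == 0

    def test_linear_ramp_residual_small(self):
        col = np.linspace(0, 30, 128)[None, :]
        img = np.clip(180 + col + np.zeros((128, 128)), 0, 255).astype(np.uint8)
        assert subtract_background(img, 50).max() <= 5

    @pytest.mark.parametrize("ramp", [10, 20, 30])
    def test_matches_grayscale_opening_oracle(self, ramp):
        """Agreement with a flat-structuring-element opening on the
        inverted frame, the textbook background estimate."""
        col = np.linspace(-ramp / 2, ramp / 2, 64)[None, :]
        img = np.clip(200 + col + np.zeros((64, 64)), 0, 255)
        img[30:33, 30:33] = 60
        img = img.astype(np.uint8)
        inv = 255 - img.astype(np.int16)
        expected = np.clip(inv - grey_opening(inv, footprint=disk(10)), 0, 255)
        got = subtract_background(img, 10)
        assert np.abs(got.astype(int) - expected).max() <= 5


class TestEnhanceContrast:
    def test_full_range_fixed_point(self):
        img = np.linspace(0, 255, 256).astype(np.uint8).reshape(16, 16)
        assert np.array_equal(enhance_contrast(img, 0.0), img)

    def test_constant_unchanged(self):
        img = np.full((4, 4), 99, np.uint8)
        assert np.array_equal(enhance_contrast(img, 0.0035), img)

    def test_two_valued_stretched_to_extremes(self):
        img = np.array([[50, 100], [100, 50]], np.uint8)
        out = enhance_contrast(img, 0.0)
        assert set(out.ravel()) == {0, 255}
        assert out[0, 0] == 0 and out[0, 1] == 255

    def test_saturation_clips_tails(self):
        img = np.full((10, 10), 128, np.uint8)
        img[0, 0] = 0
        img[9, 9] = 255
        out = enhance_contrast(img, 0.05)
        # the lone extremes saturate; the bulk maps mid-range
        assert out[0, 0] == 0 and out[9, 9] == 255


class TestRemoveNoiseObjects:
    def test_single_pixel_component_removed(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        img = np.full((10, 10), 200, np.uint8)
        assert not remove_noise_objects(mask, img, 10, 20).any()

    def test_component_of_exactly_min_area_retained(self):
        mask = np.zeros((10, 10), bool)
        mask[2:6, 2:7] = True  # 20 px
        img = np.where(mask, 200, 10).astype(np.uint8)
        assert np.array_equal(remove_noise_objects(mask, img, 10, 20), mask)

    def test_result_is_subset(self, rng):
        for _ in range(20):
            mask = rng.random((16, 16)) < 0.3
            img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            out = remove_noise_objects(mask, img, 10, 5)
            assert not (out & ~mask).any()

    def test_speck_field_leaves_only_hyphae(self):
        """Hyphal components survive; isolated impulse specks do not."""
        scene = generate_scene(SceneSpec(
            n_hyphae=5, n_spores=0, salt_speck_count=0,
            gaussian_noise_sd=0.0, seed=42))
        truth = scene.truth_mask
        rng = np.random.default_rng(7)
        keepout = dilate(dilate(truth))
        mask = truth.copy()
        img = np.where(truth, 230, 5).astype(np.uint8)
        added = 0
        while added < 30:
            i, j = rng.integers(0, truth.shape[0]), rng.integers(0, truth.shape[1])
            if not keepout[i, j] and not mask[i, j]:
                mask[i, j] = True
                img[i, j] = 240
                added += 1
        cleaned = remove_noise_objects(mask, img, prominence=10, min_area=20)
        assert np.array_equal(cleaned, truth)


class TestMeasureMII:
    def test_all_zero_is_zero(self):
        assert measure_mii(np.zeros((10, 10), np.uint8)) == 0.0

    def test_half_at_100_gives_50(self):
        img = np.zeros((10, 10), np.uint8)
        img[:5] = 100
        assert measure_mii(img) == 50.0

    def test_empty_mask_mask_only_is_zero(self):
        img = np.full((4, 4), 200, np.uint8)
        assert measure_mii(img, np.zeros((4, 4), bool), "mask_only") == 0.0

    def test_matches_bruteforce_many_seeds(self):
        for seed in range(N_ORACLE_SEEDS):
            r = np.random.default_rng(seed)
            img = r.integers(0, 256, (16, 16), dtype=np.uint8)
            mask = r.random((16, 16)) < 0.4
            assert measure_mii(img) == pytest.approx(
                brute_mii(img, mask, "whole_image"), rel=1e-12)
            assert measure_mii(img, mask, "mask_only") == pytest.approx(
                brute_mii(img, mask, "mask_only"), rel=1e-12)

    @given(arrays(np.uint8, (8, 8)))
    def test_bounded(self, img):
        assert 0.0 <= measure_mii(img) <= 255.0


class TestPipelineConfig:
    def test_defaults_valid(self):
        cfg = PipelineConfig()
        assert cfg.threshold_primary == 154 and cfg.threshold_secondary == 180

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(threshold_primary=300)

    def test_from_file_and_hash_stable_under_reordering(self, tmp_path):
        a = tmp_path / "a.cfg"
        b = tmp_path / "b.cfg"
        a.write_text("threshold_primary = 150\nmedian_radius = 2\n")
        b.write_text("median_radius = 2\nthreshold_primary = 150\n")
        ca, cb = PipelineConfig.from_file(a), PipelineConfig.from_file(b)
        assert ca == cb and ca.config_hash() == cb.config_hash()

    def test_from_file_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.cfg"
        p.write_text("ball_radius = 3\n")
        with pytest.raises(ValueError, match="ball_radius"):
            PipelineConfig.from_file(p)


class TestTransformImage:
    def test_background_only_scene_yields_near_zero_mii(self):
        scene = generate_scene(SceneSpec(n_hyphae=0, n_spores=0, seed=11))
        res = transform_image(scene.image)
        assert res.mii < 1.0
        assert res.mask.mean() < 0.001

    def test_deterministic(self):
        scene = generate_scene(SceneSpec(seed=5, width=96, height=96))
        a = transform_image(scene.image)
        b = transform_image(scene.image)
        assert a.mii == b.mii
        assert np.array_equal(a.transformed, b.transformed)
        assert np.array_equal(a.mask, b.mask)
        assert a.provenance == b.provenance

    def test_result_invariants(self):
        scene = generate_scene(SceneSpec(seed=8, width=96, height=96))
        res = transform_image(scene.image)
        assert res.transformed[~res.mask].max(initial=0) == 0
        assert res.mii == measure_mii(res.transformed, res.mask, "whole_image")
        assert len(res.provenance) == 8

    def test_color_input_accepted(self):
        scene = generate_scene(SceneSpec(seed=9, width=64, height=64))
        rgb = np.stack([scene.image] * 3, axis=-1)
        gray_res = transform_image(scene.image)
        rgb_res = transform_image(rgb)
        assert rgb_res.mii == gray_res.mii

    def test_stage_error_names_stage(self):
        with pytest.raises(ValueError, match="to_grayscale"):
            transform_image(np.zeros((0, 0), np.uint8))

    def test_recovers_truth_mask_well(self):
        """Pixel-level F1 against ground truth across seeded scenes."""
        f1s = []
        for seed in range(10):
            scene = generate_scene(SceneSpec(seed=seed, width=128, height=128,
                                             n_hyphae=6, n_spores=8))
            res = transform_image(scene.image)
            tp = (res.mask & scene.truth_mask).sum()
            denom = res.mask.sum() + scene.truth_mask.sum()
            f1s.append(2 * tp / denom if denom else 1.0)
        assert min(f1s) >= 0.8
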