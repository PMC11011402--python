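"""Copy-paste, mosaic, mixup, letterbox, and the probability scheduler."""

import numpy as np
import pytest

from greenfruit.augment import (
    AugmentConfig,
    PastePool,
    apply_train_pipeline,
    copy_paste,
    draw_schedule,
    letterbox,
    mixup,
    mosaic,
    sample_mixup_lambda,
    transform_instance,
    _crop_instance,
)
from greenfruit.boxes import BBox, bbox_to_corners
from greenfruit.labels import LabeledImage


@pytest.fixture(scope="module")
def pool(tiny_scenes):
    return PastePool(tiny_scenes)


def flat_image(value=60, size=96, boxes=()):
    pixels = np.full((size, size, 3), value, dtype=np.uint8)
    return LabeledImage(pixels=pixels, boxes=list(boxes), image_id="flat")


class TestCopyPaste:
    def test_adds_exactly_n_fruit_boxes(self, tiny_scenes, pool, rng):
        target = tiny_scenes[0]
        out, records = copy_paste(target, pool, n_fruit=4, n_leaf=15, rng=rng)
        n_pasted_fruit = sum(1 for r in records if r.category == "fruit")
        assert n_pasted_fruit == 4
        assert sum(1 for r in records if r.category == "leaf") == 15
        # pre-existing boxes kept (cover rule) + one new box per pasted fruit
        assert len(out.boxes) == len(target.boxes) + n_pasted_fruit

    def test_zero_paste_is_identity(self, tiny_scenes, pool, rng):
        target = tiny_scenes[1]
        out, records = copy_paste(target, pool, n_fruit=0, n_leaf=0, rng=rng)
        assert records == []
        assert np.array_equal(out.pixels, target.pixels)
        assert out.boxes == list(target.boxes)

    def test_pasted_pixels_match_transformed_source_exactly(self, tiny_scenes, pool):
        """Re-applying each recorded transform to its source instance must
        reproduce the pasted pixels exactly under the transformed mask."""
        rng = np.random.default_rng(3)
        target = tiny_scenes[2]
        out, records = copy_paste(target, pool, n_fruit=3, n_leaf=2, rng=rng)
        # verify in reverse paste order so later pastes cannot overwrite
        covered = np.zeros(out.pixels.shape[:2], bool)
        for rec in reversed(records):
            inst, src_pixels = pool.entries[rec.pool_index]
            patch, mask = _crop_instance(inst, src_pixels)
            patch, mask = transform_instance(patch, mask, rec.flip, rec.angle_deg, rec.scale)
            assert (patch.shape[0], patch.shape[1]) == rec.patch_shape
            x0, y0 = rec.position
            region = out.pixels[y0 : y0 + mask.shape[0], x0 : x0 + mask.shape[1]]
            fresh = mask & ~covered[y0 : y0 + mask.shape[0], x0 : x0 + mask.shape[1]]
            assert np.array_equal(region[fresh], patch[fresh])
            covered[y0 : y0 + mask.shape[0], x0 : x0 + mask.shape[1]] |= mask

    def test_empty_pool_rejected(self, tiny_scenes, rng):
        empty = PastePool([])
        with pytest.raises(ValueError, match="pool"):
            copy_paste(tiny_scenes[0], empty, 4, 15, rng)


class TestMosaic:
    def test_output_size_contract(self, tiny_scenes, rng):
        out, _ = mosaic(tiny_scenes[:4], preset_size=128, rng=rng)
        assert out.pixels.shape == (128, 128, 3)

    def test_conservation_with_full_canvas(self):
        """Center fixed at (s, s) and no crop: all four central boxes survive."""
        s = 64
        images = [
            flat_image(80, 96, [BBox(0, 0.5, 0.5, 0.25, 0.25)]) for _ in range(4)
        ]
        out, _ = mosaic(images, s, center=(float(s), float(s)), crop_frac=1.0)
        assert len(out.boxes) == 4

    def test_fewer_than_four_rejected(self, tiny_scenes):
        with pytest.raises(ValueError):
            mosaic(tiny_scenes[:3], 96)

    def test_inverse_transform_maps_into_source_bounds(self, tiny_scenes, rng):
        images = tiny_scenes[:4]
        out, records = mosaic(images, 96, rng=rng)
        # every output box, pulled back through some quadrant's record, must
        # land inside that source image
        for b in out.boxes:
            x1, y1, x2, y2 = bbox_to_corners(b, (96, 96))
            ok = False
            for img, rec in zip(images, records):
                sx1, sy1 = rec.invert_point(x1, y1, img.size)
                sx2, sy2 = rec.invert_point(x2, y2, img.size)
                w, h = img.size
                if -1.0 <= sx1 <= w + 1 and -1.0 <= sy1 <= h + 1 \
                        and -1.0 <= sx2 <= w + 1 and -1.0 <= sy2 <= h + 1:
                    ok = True
                    break
            assert ok, f"box {b} traces to no source image"


class TestMixup:
    def test_lambda_one_keeps_first_pixels_and_concatenates_labels(self):
        a = flat_image(100, 64, [BBox(0, 0.5, 0.5, 0.2, 0.2)])
        b = flat_image(20, 64, [BBox(0, 0.3, 0.3, 0.1, 0.1)])
        out = mixup(a, b, 1.0)
        assert np.array_equal(out.pixels, a.pixels)
        assert out.boxes == a.boxes + b.boxes  # labels unweighted, both kept

    def test_single_pixel_arithmetic(self):
        out = mixup(flat_image(100, 4), flat_image(20, 4), 0.35)
        assert out.pixels[0, 0, 0] == 48  # 0.35*100 + 0.65*20

    def test_symmetry(self, tiny_scenes):
        """lam*a + (1-lam)*b == (1-lam)*b + lam*a up to the single 8-bit rounding
        (ties at exact .5 can flip by one count under float arithmetic)."""
        a, b = tiny_scenes[0], tiny_scenes[1]
        lam = 0.3
        x = mixup(a, b, lam).pixels.astype(np.int16)
        y = mixup(b, a, 1.0 - lam).pixels.astype(np.int16)
        diff = np.abs(x - y)
        assert diff.max() <= 1
        assert (diff > 0).mean() < 0.01

    def test_convex_combination_bounds(self, tiny_scenes, rng):
        a, b = tiny_scenes[0], tiny_scenes[1]
        lam = 0.42
        out = mixup(a, b, lam).pixels.astype(np.int16)
        lo = np.minimum(a.pixels, b.pixels).astype(np.int16) - 1  # rounding slack
        hi = np.maximum(a.pixels, b.pixels).astype(np.int16) + 1
        assert (out >= lo).all() and (out <= hi).all()

    def test_size_mismatch_rejected(self, tiny_scenes):
        with pytest.raises(ValueError):
            mixup(tiny_scenes[0], flat_image(10, 32), 0.5)


class TestMixupLambda:
    def test_symmetric_mean_and_variance(self):
        rng = np.random.default_rng(0)
        alpha = 8.0
        draws = np.array([sample_mixup_lambda(alpha, rng) for _ in range(100_000)])
        se = np.sqrt(1 / (4 * (2 * alpha + 1)) / len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se
        assert abs(draws.var() - 1 / (4 * (2 * alpha + 1))) < 0.05 / (4 * (2 * alpha + 1))

    def test_deterministic_sequence(self):
        a = [sample_mixup_lambda(2.0, np.random.default_rng(9)) for _ in range(1)]
        b = [sample_mixup_lambda(2.0, np.random.default_rng(9)) for _ in range(1)]
        assert a == b

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            sample_mixup_lambda(0.0)


class TestLetterbox:
    def test_pad_arithmetic(self):
        img = flat_image(50, 0)
        img = LabeledImage(pixels=np.zeros((960, 1280, 3), np.uint8), boxes=[])
        out, rec = letterbox(img, 640)
        assert out.pixels.shape == (640, 640, 3)
        assert rec.scale == (0.5, 0.5)
        assert rec.pad == (0, 80, 0, 80)

    def test_square_at_target_is_identity(self, tiny_scenes):
        img = tiny_scenes[0]
        out, rec = letterbox(img, img.size[0])
        assert np.array_equal(out.pixels, img.pixels)
        assert rec.pad == (0, 0, 0, 0)

    def test_box_mapping_invertible(self):
        img = LabeledImage(pixels=np.zeros((100, 200, 3), np.uint8),
                           boxes=[BBox(0, 0.5, 0.5, 0.2, 0.4)])
        out, rec = letterbox(img, 64)
        (bx1, by1, bx2, by2) = bbox_to_corners(out.boxes[0], (64, 64))
        sx1, sy1 = rec.invert_point(bx1, by1, img.size)
        ox1, oy1, _, _ = bbox_to_corners(img.boxes[0], img.size)
        assert (sx1, sy1) == pytest.approx((ox1, oy1), abs=1e-6)


class TestPipeline:
    def test_all_probabilities_zero_yields_letterboxed_originals(self, tiny_scenes):
        cfg = AugmentConfig(p_copy_paste=0, p_mosaic=0, p_mixup=0, flip_prob=0,
                            hsv_jitter=(0, 0, 0), preset_size=96)
        rng = np.random.default_rng(0)
        samples = list(apply_train_pipeline(tiny_scenes, cfg, rng, n_samples=4))
        originals = {s.image_id: s for s in tiny_scenes}
        for s in samples:
            assert not any(s.applied.values())
            src = originals[s.image.image_id]
            expected, _ = letterbox(src, 96)
            assert np.array_equal(s.image.pixels, expected.pixels)

    def test_deterministic_stream(self, tiny_scenes):
        cfg = AugmentConfig(preset_size=96, seed=4)
        a = [s.image.pixels for s in apply_train_pipeline(
            tiny_scenes, cfg, np.random.default_rng(4), n_samples=3)]
        b = [s.image.pixels for s in apply_train_pipeline(
            tiny_scenes, cfg, np.random.default_rng(4), n_samples=3)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            next(apply_train_pipeline([], AugmentConfig(), n_samples=1))


class TestScheduler:
    def test_frequencies_converge_to_probabilities(self):
        """Scheduler draws follow the configured 1 / 0.8 / 0.3 probabilities."""
        cfg = AugmentConfig()
        rng = np.random.default_rng(12)
        n = 10_000
        counts = {"copy_paste": 0, "mosaic": 0, "mixup": 0}
        for _ in range(n):
            sched = draw_schedule(cfg, rng)
            for k in counts:
                counts[k] += sched[k]
        for key, p in (("copy_paste", 1.0), ("mosaic", 0.8), ("mixup", 0.3)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) <= max(3 * se, 1e-12)
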