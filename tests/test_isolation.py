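"""Isolation pipeline: each stage against brute-force oracles and contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneegrade.isolation import (
    ColumnInterval,
    IsolationParams,
    KneeSeparationError,
    crop_knees,
    detect_knee_columns,
    fix_identical_rows,
    isolate,
    morphological_opening,
    otsu_threshold,
    pad_and_normalize,
    sharpen,
    standardize,
)
from kneegrade.phantom import PhantomConfig, generate_phantom


# -- standardize ------------------------------------------------------------

def test_standardize_resizes_any_input():
    out = standardize(np.random.default_rng(0).integers(0, 255, (400, 600)))
    assert out.shape == (224, 224)
    assert 0 <= out.min() and out.max() <= 255


def test_standardize_is_identity_on_224_gray():
    img = np.random.default_rng(1).integers(0, 255, (224, 224)).astype(float)
    assert np.array_equal(standardize(img), img)


def test_standardize_constant_rgb_preserves_value():
    # any convex channel weighting maps (k, k, k) to k
    img = np.full((100, 120, 3), 77.0)
    out = standardize(img)
    assert np.allclose(out, 77.0)


def test_standardize_rejects_degenerate_input():
    with pytest.raises(ValueError):
        standardize(np.zeros((0, 10)))
    with pytest.raises(ValueError):
        standardize(np.zeros((5, 1)))


# -- sharpen ----------------------------------------------------------------

def test_sharpen_constant_image_unchanged():
    img = np.full((32, 32), 90.0)
    assert np.allclose(sharpen(img), img)


def test_sharpen_amount_zero_is_identity():
    img = np.random.default_rng(2).uniform(0, 255, (16, 16))
    assert np.array_equal(sharpen(img, amount=0.0), img)


def test_sharpen_boosts_isolated_bright_pixel():
    img = np.zeros((5, 5))
    img[2, 2] = 100.0
    out = sharpen(img, amount=1.0, sigma=1.0)
    # unsharp formula evaluated directly: center gains img - blur > 0
    from scipy.ndimage import gaussian_filter
    expected = np.clip(img + (img - gaussian_filter(img, 1.0)), 0, 255)
    assert np.allclose(out, expected)
    assert out[2, 2] > img[2, 2] or out[2, 2] == 255.0


def test_sharpen_rejects_negative_amount():
    with pytest.raises(ValueError):
        sharpen(np.zeros((4, 4)), amount=-1.0)


# -- otsu -------------------------------------------------------------------

def brute_force_otsu(image):
    """Exhaustive search over all 256 thresholds maximizing the
    between-class variance; smallest maximizer wins."""
    levels = np.clip(np.rint(np.asarray(image, float)), 0, 255).astype(int).ravel()
    best_t, best_v = 0, -np.inf
    for t in range(256):
        lo, hi = levels[levels <= t], levels[levels > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(levels), len(hi) / len(levels)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t


def test_otsu_bimodal_split_is_clean():
    img = np.concatenate([np.full(50, 50.0), np.full(50, 200.0)]).reshape(10, 10)
    t, mask = otsu_threshold(img)
    assert np.all(mask[img == 200])
    assert not np.any(mask[img == 50])


def test_otsu_matches_brute_force_on_toy():
    img = np.array([10] * 12 + [240] * 4, float).reshape(4, 4)
    t, _ = otsu_threshold(img)
    assert t == brute_force_otsu(img)


def test_otsu_matches_brute_force_on_random_images():
    rng = np.random.default_rng(7)
    for _ in range(50):
        img = rng.integers(0, 256, size=(12, 12))
        assert otsu_threshold(img)[0] == brute_force_otsu(img)


def test_otsu_rejects_constant_image():
    with pytest.raises(ValueError, match="degenerate"):
        otsu_threshold(np.full((8, 8), 3.0))


def test_otsu_captures_phantom_bone(default_cfg):
    rec = generate_phantom(2, 2, default_cfg, rng_state=5)
    _, mask = otsu_threshold(rec.image)
    bright = rec.image >= default_cfg.bone_intensity - 3 * default_cfg.noise_sd
    assert mask[bright].mean() >= 0.99


# -- morphological opening --------------------------------------------------

def test_opening_trivial_cases():
    assert not morphological_opening(np.zeros((9, 9), int), 3).any()
    speck = np.zeros((9, 9), int)
    speck[4, 4] = 1
    assert not morphological_opening(speck, 3).any()


def test_opening_identity_on_solid_square():
    sq = np.zeros((24, 24), int)
    sq[2:22, 2:22] = 1
    opened = morphological_opening(sq, 3)
    # direct erosion-then-dilation with scipy agrees (kernel-open set)
    assert np.array_equal(opened.astype(int), sq)


def test_opening_rejects_nonbinary():
    with pytest.raises(ValueError, match="binary"):
        morphological_opening(np.full((4, 4), 2), 3)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_opening_is_idempotent(seed):
    m = np.random.default_rng(seed).random((20, 20)) < 0.5
    once = morphological_opening(m, 3)
    assert np.array_equal(morphological_opening(once, 3), once)


# -- fix_identical_rows -----------------------------------------------------

def test_fix_identical_rows_examples():
    img = np.arange(12.0).reshape(3, 4)
    img[1] = 255.0
    fixed = fix_identical_rows(img)
    assert np.all(fixed[1] == 0)
    assert np.array_equal(fixed[0], img[0]) and np.array_equal(fixed[2], img[2])


def test_fix_identical_rows_counts_by_row_scan():
    rng = np.random.default_rng(3)
    img = rng.uniform(1, 255, (224, 224))
    const_rows = [5, 17, 200]
    for r in const_rows:
        img[r] = 42.0
    fixed = fix_identical_rows(img)
    zeroed = [r for r in range(224) if np.all(fixed[r] == 0)]
    expected = [r for r in range(224) if len(set(img[r].tolist())) == 1]
    assert zeroed == expected == const_rows


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_fix_identical_rows_is_idempotent(seed):
    img = np.random.default_rng(seed).integers(0, 4, (10, 6)).astype(float)
    once = fix_identical_rows(img)
    assert np.array_equal(fix_identical_rows(once), once)


# -- column detection -------------------------------------------------------

def test_detect_columns_forced_toy():
    mask = np.zeros((6, 16), int)
    mask[:, 2:6] = 1
    mask[:, 10:14] = 1
    left, right = detect_knee_columns(mask, min_gap=4, min_run=2)
    assert (left.start, left.end) == (2, 6)
    assert (right.start, right.end) == (10, 14)


def test_detect_columns_errors_on_empty_mask():
    with pytest.raises(KneeSeparationError):
        detect_knee_columns(np.zeros((8, 8), int))


def test_detect_columns_bridges_small_gaps_and_drops_short_runs():
    mask = np.zeros((10, 40), int)
    mask[:, 2:10] = 1
    mask[:, 12:20] = 1   # 2-col gap -> bridged into [2, 20)
    mask[:, 30:33] = 1   # 3 cols < min_run -> dropped
    mask[:, 34:44 - 10] = 1
    with pytest.raises(KneeSeparationError):
        detect_knee_columns(mask, min_gap=5, min_run=10)
    left, right = detect_knee_columns(mask, min_gap=3, min_run=3)
    assert (left.start, left.end) == (2, 20)


def test_detected_intervals_match_truth_boxes():
    """Jaccard >= 0.8 against generator truth over seeded phantoms."""
    hits = total = 0
    for seed in range(25):
        rng = np.random.default_rng(seed)
        rec = generate_phantom(int(rng.integers(5)), int(rng.integers(5)), rng_state=rng)
        std = standardize(rec.image)
        _, mask = otsu_threshold(sharpen(std))
        opened = morphological_opening(mask, 5)
        intervals = detect_knee_columns(opened)
        scale = 224.0 / rec.image.shape[1]
        for iv, box in zip(intervals, rec.truth_boxes):
            truth = ColumnInterval(int(round(box[0] * scale)), int(round(box[1] * scale)))
            total += 1
            hits += iv.jaccard(truth) >= 0.8
    assert hits == total


# -- crop + pad -------------------------------------------------------------

def test_crop_contains_knee_bright_pixels(default_cfg):
    rec = generate_phantom(3, 2, default_cfg, rng_state=11)
    std = standardize(rec.image)
    _, mask = otsu_threshold(sharpen(std))
    opened = morphological_opening(mask, 5)
    ivs = detect_knee_columns(opened)
    crop_l, crop_r = crop_knees(std, ivs, opened)
    for crop, iv in zip((crop_l, crop_r), ivs):
        bright_in_crop = (crop > 128).sum()
        bright_in_band = (std[:, iv.start:iv.end] > 128).sum()
        assert bright_in_crop >= 0.95 * bright_in_band


def test_crop_degenerate_interval_rejected():
    img = np.zeros((10, 10))
    mask = np.ones((10, 10), int)
    with pytest.raises(ValueError):
        crop_knees(img, (ColumnInterval(0, 1), ColumnInterval(5, 10)), mask)


def test_pad_symmetric_before_resize():
    crop = np.full((100, 50), 200.0)
    padded_like = pad_and_normalize(crop)
    assert padded_like.shape == (224, 224)
    # 25 zero columns each side of the 100x100 square -> zeros survive resize
    assert np.allclose(padded_like[:, :40], 0.0, atol=1e-6)
    assert np.allclose(padded_like[:, -40:], 0.0, atol=1e-6)
    assert padded_like[112, 112] == pytest.approx(200 / 255, abs=1e-6)


def test_pad_constant_255_gives_unit_pixels():
    out = pad_and_normalize(np.full((30, 30), 255.0))
    assert np.allclose(out, 1.0)


def test_pad_preserves_aspect_ratio_of_content():
    crop = np.zeros((120, 60))
    crop[10:110, 5:55] = 255.0  # content box 100 x 50, ratio 2.0
    out = pad_and_normalize(crop)
    rows = np.flatnonzero((out > 0.5).any(axis=1))
    cols = np.flatnonzero((out > 0.5).any(axis=0))
    ratio = (rows[-1] - rows[0] + 1) / (cols[-1] - cols[0] + 1)
    assert ratio == pytest.approx(2.0, abs=0.1)


# -- end to end -------------------------------------------------------------

def test_isolate_slices_carry_labels(default_cfg):
    rec = generate_phantom(0, 4, default_cfg, rng_state=21, patient_id="P0042")
    left, right = isolate(rec)
    assert (left.side, left.grade, left.patient_id) == ("left", 0, "P0042")
    assert (right.side, right.grade, right.patient_id) == ("right", 4, "P0042")


def test_isolate_output_contract(small_slices):
    for s in small_slices:
        assert s.pixels.shape == (224, 224)
        assert 0.0 <= s.pixels.min() and s.pixels.max() <= 1.0
        content = (s.pixels > 0.3).mean()
        assert content > 0.2  # knee fills a substantial part of the slice


def test_isolate_yields_two_slices_per_record(small_cohort, small_slices):
    assert len(small_slices) == 2 * len(small_cohort)
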