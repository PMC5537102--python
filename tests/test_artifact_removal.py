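"""Texture segmentation, level estimation, removal and POCS restoration."""

import numpy as np
import pytest

from thyroprep import (EmptyImageError, PocsParams, ValidationError,
                       clean_image, estimate_artifact_levels,
                       remove_artifacts, restore_pocs,
                       segment_texture_region)


def test_single_block_is_the_texture():
    img = np.zeros((80, 80), dtype=np.uint8)
    img[10:60, 10:60] = 120
    seg = segment_texture_region(img)
    assert seg.labeling.K == 1
    assert seg.texture_mask.sum() == 50 * 50
    assert not seg.possible_artifact_mask.any()


def test_largest_component_wins_by_one_pixel():
    img = np.zeros((60, 120), dtype=np.uint8)
    img[5:15, 5:15] = 50          # 100 px
    img[30:41, 30:39] = 50        # 99 px
    seg = segment_texture_region(img)
    assert seg.labeling.K == 2
    assert seg.texture_mask[10, 10] and not seg.texture_mask[35, 35]
    assert seg.possible_artifact_mask.sum() == 99


def test_component_sizes_sum_to_nonzero_count(default_phantom):
    seg = segment_texture_region(default_phantom.pixels)
    assert seg.labeling.sizes.sum() == np.count_nonzero(default_phantom.pixels)


def test_detached_text_block_is_possible_artifact(default_phantom):
    ph = default_phantom
    seg = segment_texture_region(ph.pixels)
    # the lowest planted level appears only in the detached blocks
    low = min(ph.spec.artifact_levels)
    block_px = ph.truth_artifact_mask & (ph.pixels == low)
    detached = block_px & ~seg.texture_mask
    assert detached.sum() > 0
    assert (detached & seg.possible_artifact_mask).sum() == detached.sum()


def test_all_zero_image_raises():
    with pytest.raises(EmptyImageError):
        segment_texture_region(np.zeros((20, 20), dtype=np.uint8))


def test_estimate_levels_single_value():
    assert estimate_artifact_levels(np.full(50, 255, dtype=np.uint8)) == (255,)


def test_estimate_levels_empty_input():
    assert estimate_artifact_levels(np.array([], dtype=np.uint8)) == ()


def test_estimate_levels_one_peak_per_partition():
    pixels = np.concatenate([
        np.full(30, 40), np.full(10, 90),   # [0,100]: mode 40
        np.full(25, 150), np.full(5, 180),  # [101,200]: mode 150
        np.full(40, 230),                   # [201,255]: mode 230
    ]).astype(np.uint8)
    assert estimate_artifact_levels(pixels) == (40, 150, 230)


def test_phantom_levels_recovered_exactly(default_phantom):
    ph = default_phantom
    seg = segment_texture_region(ph.pixels)
    levels = estimate_artifact_levels(ph.pixels[seg.possible_artifact_mask])
    assert set(levels) == set(ph.spec.artifact_levels)


def test_remove_nothing_with_empty_levels(default_phantom):
    seg = segment_texture_region(default_phantom.pixels)
    gapped, am = remove_artifacts(default_phantom.pixels, (), seg.texture_mask)
    assert not am.mask.any()
    assert np.array_equal(gapped, default_phantom.pixels)


def test_remove_artifacts_full_recall_no_false_positives(default_phantom):
    ph = default_phantom
    seg = segment_texture_region(ph.pixels)
    levels = estimate_artifact_levels(ph.pixels[seg.possible_artifact_mask])
    gapped, am = remove_artifacts(ph.pixels, levels, seg.texture_mask)
    truth = ph.truth_artifact_mask
    recall = (am.mask & truth).sum() / truth.sum()
    assert recall >= 0.95
    # collision handling makes texture pixels never equal a level,
    # so the only extra detections can be the 255-valued tick dots
    false_pos = am.mask & ~truth
    assert not (false_pos & (ph.pixels != 255)).any()
    assert np.array_equal(gapped[~am.mask], ph.pixels[~am.mask])


def test_restore_empty_mask_is_identity(default_phantom):
    img = default_phantom.pixels
    out = restore_pocs(img, np.zeros_like(img, dtype=bool))
    assert np.array_equal(out, img)


def test_restore_constant_image_stays_constant():
    img = np.full((64, 64), 90, dtype=np.uint8)
    mask = np.zeros_like(img, dtype=bool)
    mask[20:30, 20:40] = True
    out = restore_pocs(img, mask)
    assert np.all(out == 90)


def test_restore_rejects_all_unknown():
    img = np.zeros((32, 32), dtype=np.uint8)
    with pytest.raises(ValidationError, match="nothing known"):
        restore_pocs(img, np.ones_like(img, dtype=bool))


def test_restore_preserves_known_pixels_exactly(default_phantom):
    ph = default_phantom
    seg = segment_texture_region(ph.pixels)
    levels = estimate_artifact_levels(ph.pixels[seg.possible_artifact_mask])
    gapped, am = remove_artifacts(ph.pixels, levels, seg.texture_mask)
    out, history = restore_pocs(gapped, am.mask, return_history=True)
    assert np.array_equal(out[~am.mask], gapped[~am.mask])
    # convergence: change non-increasing after the first 3 iterations
    tail = history[3:]
    assert all(b <= a + 1e-9 for a, b in zip(tail, tail[1:]))
    assert history[-1] <= PocsParams().tol or len(history) == PocsParams().max_iters


def test_end_to_end_restoration_halves_masked_error(default_phantom):
    ph = default_phantom
    restored, am, _ = clean_image(ph.pixels)
    truth = ph.truth_artifact_mask
    clean = ph.clean_pixels.astype(float)
    mae_restored = np.abs(restored[truth] - clean[truth]).mean()
    gapped = ph.pixels.copy()
    gapped[am.mask] = 0
    mae_none = np.abs(gapped[truth].astype(float) - clean[truth]).mean()
    assert mae_restored <= 0.5 * mae_none


def test_band_matching_widens_the_mask():
    img = np.zeros((40, 40), dtype=np.uint8)
    img[5:35, 5:35] = 100
    img[10, 10] = 150
    img[11, 11] = 151
    tex = img > 0
    _, exact = remove_artifacts(img, (150,), tex, band=0)
    _, banded = remove_artifacts(img, (150,), tex, band=1)
    assert exact.mask.sum() == 1 and banded.mask.sum() == 2


@pytest.mark.parametrize("kwargs", [
    {"block_size": 2}, {"kept_coeffs": 0}, {"kept_coeffs": 100},
    {"max_iters": 0}, {"tol": 0.0},
])
def test_pocs_params_validated(kwargs):
    with pytest.raises(ValidationError):
        PocsParams(**kwargs)
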