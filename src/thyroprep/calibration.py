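"""Tick-bar scale calibration.

Clinical ultrasound captures carry a vertical ruler of evenly spaced tick
dots in the right margin; the dot spacing encodes the physical size of a
pixel. Images acquired on different machines or depth settings therefore
show the same tissue at different pixel scales. This module finds the
tick column and its spacing m (in pixels) by adaptive thresholding of the
right portion of the image followed by a per-column autocorrelation peak
search, then rescales every image of a cohort by the ratio of the largest
tick spacing in the cohort to its own, using bicubic interpolation, so
all images share one relative scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.filters import threshold_local
from skimage.transform import resize

from .errors import TickBarNotFoundError, ValidationError

logger = logging.getLogger(__name__)

#: pixel must exceed its 15x15 local mean by this much to count as a tick
ADAPTIVE_BLOCK = 15
ADAPTIVE_OFFSET = -10.0

MIN_TICK_PIXELS = 4


@dataclass(frozen=True)
class TickDetection:
    """Detected tick column (full-image coordinates) and spacing."""

    column: int
    spacing_m: int
    score: float

    def __post_init__(self) -> None:
        if self.spacing_m < 2:
            raise ValidationError("spacing_m must be >= 2")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError("score must lie in [0, 1]")


@dataclass(frozen=True)
class RescalePlan:
    """Per-image rescaling ratios toward the cohort's coarsest scale.

    ``reference_spacing`` is the largest tick spacing in the cohort; each
    image is scaled by reference_spacing / own_spacing, so every ratio is
    >= 1 and the reference image keeps ratio exactly 1.
    """

    reference_spacing: int
    per_image_ratio: dict

    def __post_init__(self) -> None:
        for img_id, r in self.per_image_ratio.items():
            if r < 1.0:
                raise ValidationError(f"ratio for {img_id!r} is {r} < 1")


def _binarize_ticks(region: np.ndarray) -> np.ndarray:
    thr = threshold_local(region.astype(float), block_size=ADAPTIVE_BLOCK,
                          method="mean", offset=ADAPTIVE_OFFSET)
    return region > thr


def _column_autocorr(binary: np.ndarray) -> np.ndarray:
    """Autocorrelation of each column's mean-centred 0/1 profile (FFT).

    Centring matters: a dense aperiodic column (binarized speckle) has
    near-zero coefficients at every nonzero lag, while a periodic tick
    column keeps peaks close to the zero-lag value, so the two cannot be
    confused however many pixels the speckle column carries.
    """
    h = binary.shape[0]
    b = binary.astype(float)
    b -= b.mean(axis=0, keepdims=True)
    f = np.fft.rfft(b, n=2 * h, axis=0)
    r = np.fft.irfft(f * np.conj(f), n=2 * h, axis=0)[:h]
    return r


def _first_periodic_peak(r: np.ndarray, max_lag: int) -> tuple[int, float] | None:
    """First local max at lag >= 2 exceeding half the zero-lag value."""
    r0 = r[0]
    if r0 <= 0:
        return None
    hi = min(max_lag, r.size - 2)
    for k in range(2, hi + 1):
        if r[k] > 0.5 * r0 and r[k] > r[k - 1] and r[k] >= r[k + 1]:
            return k, float(r[k] / r0)
    return None


def detect_tick_column(
    image: np.ndarray,
    search_fraction: float = 0.30,
    score_floor: float = 0.5,
) -> TickDetection:
    """Locate the tick-bar column and tick spacing m.

    The right ``search_fraction`` of the image is binarized by adaptive
    local-mean thresholding; each column's 0/1 profile is autocorrelated
    and the column with the strongest periodic peak wins. The peak lag is
    the tick spacing, the normalized peak height the detection score.

    Raises :class:`TickBarNotFoundError` when no column shows periodic
    structure above ``score_floor`` (e.g. constant images).
    """
    if image.ndim != 2:
        raise ValidationError("image must be a 2-D array")
    h, w = image.shape
    n_cols = int(np.ceil(w * search_fraction))
    if n_cols < 8:
        raise ValidationError("search region narrower than 8 columns")
    col0 = w - n_cols
    region = image[:, col0:]

    if region.max() == region.min():
        raise TickBarNotFoundError("no tick bar found: constant search region")

    binary = _binarize_ticks(region)
    counts = binary.sum(axis=0)
    candidates = np.flatnonzero(counts >= MIN_TICK_PIXELS)
    if candidates.size == 0:
        raise TickBarNotFoundError("no tick bar found: no candidate tick pixels")

    r = _column_autocorr(binary[:, candidates])
    best: tuple[float, int, int] | None = None  # (score, spacing, column)
    max_lag = h // 2
    for j, col in enumerate(candidates):
        peak = _first_periodic_peak(r[:, j], max_lag)
        if peak is None:
            continue
        lag, score = peak
        if best is None or score > best[0]:
            best = (score, lag, int(col))
    if best is None or best[0] < score_floor:
        raise TickBarNotFoundError("no tick bar found: no periodic column above floor")
    score, spacing, col = best
    return TickDetection(column=col0 + col, spacing_m=spacing,
                         score=min(score, 1.0))


def build_rescale_plan(detections: Mapping[str, TickDetection]) -> RescalePlan:
    """Ratio of the cohort's largest tick spacing to each image's own."""
    if len(detections) == 0:
        raise ValidationError("build_rescale_plan requires at least one detection")
    reference = max(d.spacing_m for d in detections.values())
    ratios = {img_id: reference / d.spacing_m for img_id, d in detections.items()}
    return RescalePlan(reference_spacing=reference, per_image_ratio=ratios)


def rescale_image(image: np.ndarray, ratio: float) -> np.ndarray:
    """Resample by ``ratio`` with bicubic interpolation, clipped to 8 bit."""
    if ratio <= 0:
        raise ValidationError("ratio must be positive")
    if image.ndim != 2:
        raise ValidationError("image must be a 2-D array")
    if ratio == 1.0:
        return image.copy()
    out_shape = (int(round(image.shape[0] * ratio)),
                 int(round(image.shape[1] * ratio)))
    if out_shape[0] < 2 or out_shape[1] < 2:
        raise ValidationError(f"ratio {ratio} yields degenerate output {out_shape}")
    out = resize(image.astype(float), out_shape, order=3, mode="reflect",
                 anti_aliasing=ratio < 1.0, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def calibrate_cohort(
    images: Mapping[str, np.ndarray],
    search_fraction: float = 0.30,
) -> tuple[dict, RescalePlan, list[str]]:
    """Detect ticks on every image and build the cohort rescale plan.

    Images where no tick bar is found are left at native scale (ratio 1)
    and reported in the returned failure list, with a logged warning.
    """
    detections: dict[str, TickDetection] = {}
    failed: list[str] = []
    for img_id, img in images.items():
        try:
            detections[img_id] = detect_tick_column(img, search_fraction)
        except TickBarNotFoundError as exc:
            logger.warning("calibration failed for %s: %s; passing through", img_id, exc)
            failed.append(img_id)
    if not detections:
        raise ValidationError("tick detection failed on every image in the cohort")
    plan = build_rescale_plan(detections)
    for img_id in failed:
        plan.per_image_ratio[img_id] = 1.0
    return detections, plan, failed
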