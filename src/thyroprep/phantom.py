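"""Synthetic ultrasound phantoms with full ground truth.

A phantom emulates the structural features a clinical B-mode capture
carries besides the anatomy itself: a speckle-textured scan region
surrounded by a zero-valued frame, a hypoechoic elliptical nodule, a
vertical ruler of evenly spaced tick dots in the right margin (whose
spacing encodes the physical scale), and burned-in operator annotations
(caliper crosses, a dashed nodule outline, detached text-like blocks)
drawn at fixed 8-bit intensity levels. Every phantom records its clean
(pre-annotation) pixels, the exact artifact mask, the tick column and
spacing, and an ROI annotation, so each downstream stage can be scored
against ground truth.

The speckle model is deliberately simple: low-pass-filtered Gaussian
noise pushed through an exponential map, giving a granular texture with
a tunable correlation length. It is not an acoustic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw

from .augmentation import BENIGN, MALIGNANT, ROIAnnotation
from .errors import ValidationError

ARTIFACT_KINDS = frozenset({"caliper_cross", "dashed_outline", "text_block"})

#: Histogram partitions used by the artifact-level estimator; the phantom
#: validates that each requested level falls in a distinct partition.
LEVEL_PARTITIONS = ((0, 100), (101, 200), (201, 255))

TICK_INTENSITY = 255
_TICK_HALF_WIDTH = 1  # tick dots are 2 px wide and 2 px tall


def _partition_index(level: int) -> int:
    for i, (lo, hi) in enumerate(LEVEL_PARTITIONS):
        if lo <= level <= hi:
            return i
    raise ValidationError(f"artifact level {level} outside [0, 255]")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``nodule_axes`` are the (row, col) semi-axes of the nodule ellipse.
    ``speckle_params`` is (mean intensity, correlation length in pixels).
    ``tick_column_frac`` must put the tick ruler strictly inside the right
    30% of the image, which is the region the calibration stage searches.
    """

    height: int = 360
    width: int = 560
    tick_spacing: int = 20
    tick_column_frac: float = 0.92
    nodule_centre: tuple[int, int] = (180, 230)
    nodule_axes: tuple[int, int] = (50, 70)
    artifact_kinds: frozenset = frozenset(ARTIFACT_KINDS)
    artifact_levels: tuple[int, ...] = (40, 150, 230)
    class_label: str = BENIGN
    speckle_params: tuple[float, float] = (120.0, 2.0)

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValidationError("height/width: phantom must be at least 64x64")
        if int(self.tick_spacing) < 4:
            raise ValidationError("tick_spacing: must be an integer >= 4")
        if not 0.7 < self.tick_column_frac < 1.0:
            raise ValidationError(
                "tick_column_frac: must lie strictly inside (0.7, 1.0) "
                "so the ruler falls in the searched right region"
            )
        if int(round(self.tick_column_frac * self.width)) >= self.width - 2:
            raise ValidationError("tick_column_frac: tick column too close to the right edge")
        kinds = set(self.artifact_kinds)
        if not kinds <= ARTIFACT_KINDS:
            raise ValidationError(f"artifact_kinds: unknown kinds {kinds - ARTIFACT_KINDS}")
        if len(self.artifact_levels) > 3:
            raise ValidationError("artifact_levels: at most three levels")
        parts = []
        for lv in self.artifact_levels:
            if not 1 <= int(lv) <= 255:
                raise ValidationError(f"artifact_levels: level {lv} outside [1, 255]")
            parts.append(_partition_index(int(lv)))
        if len(set(parts)) != len(parts):
            raise ValidationError("artifact_levels: at most one level per histogram partition")
        cr, cc = self.nodule_centre
        a, b = self.nodule_axes
        if a < 2 or b < 2:
            raise ValidationError("nodule_axes: semi-axes must be >= 2 px")
        if not (a <= cr < self.height - a and b <= cc < self.width - b):
            raise ValidationError("nodule_centre/nodule_axes: ellipse must fit inside the image")
        if self.class_label not in (BENIGN, MALIGNANT):
            raise ValidationError(f"class_label: {self.class_label!r}")
        mean, corr = self.speckle_params
        if not (1.0 <= mean <= 250.0) or corr <= 0:
            raise ValidationError("speckle_params: mean in [1, 250] and correlation length > 0")


@dataclass(frozen=True)
class PhantomImage:
    """A generated phantom plus the ground truth of every planted feature."""

    pixels: np.ndarray          # uint8, with annotations burned in
    clean_pixels: np.ndarray    # uint8, same image before annotations
    truth_tick_column: int
    truth_tick_spacing: int
    truth_artifact_mask: np.ndarray  # bool, True where annotations were drawn
    roi: ROIAnnotation
    label: str
    spec: PhantomSpec
    image_id: str = "phantom"

    def __post_init__(self) -> None:
        if self.truth_artifact_mask.shape != self.pixels.shape:
            raise ValidationError("truth_artifact_mask must match pixel shape")


def _texture_bounds(spec: PhantomSpec) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1) of the speckle-textured scan region."""
    mt = max(4, int(round(0.08 * spec.height)))
    ml = max(4, int(round(0.05 * spec.width)))
    tick_col = int(round(spec.tick_column_frac * spec.width))
    col1 = min(int(round(0.76 * spec.width)), tick_col - 3)
    return mt, spec.height - mt, ml, col1


def _speckle(shape: tuple[int, int], mean: float, corr: float,
             rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(shape)
    z = ndimage.gaussian_filter(z, sigma=corr)
    z /= max(z.std(), 1e-9)
    img = mean * np.exp(0.45 * z)
    return np.clip(img, 1, 255)


def _shift_collisions(img: np.ndarray, levels: Sequence[int]) -> np.ndarray:
    """Nudge non-artifact pixels off the reserved artifact intensities.

    Guarantees level-matched detection has zero ambiguity: after this,
    no clean non-zero pixel equals a requested artifact level.
    """
    out = img.copy()
    level_set = set(int(l) for l in levels)
    for lv in level_set:
        hit = out == lv
        if not hit.any():
            continue
        up = lv + 1
        down = lv - 1
        repl = up if (up <= 255 and up not in level_set) else down
        if repl < 1 or repl in level_set:
            repl = up if up <= 255 else down
        out[hit] = repl
    return out


def _draw_cross(mask: np.ndarray, img: np.ndarray, centre: tuple[int, int],
                level: int, arm: int = 6, thick: int = 2) -> None:
    r, c = centre
    h, w = img.shape
    r0, r1 = max(0, r - arm), min(h, r + arm + 1)
    c0, c1 = max(0, c - arm), min(w, c + arm + 1)
    tr0, tr1 = max(0, r - thick // 2), min(h, r + (thick + 1) // 2)
    tc0, tc1 = max(0, c - thick // 2), min(w, c + (thick + 1) // 2)
    img[r0:r1, tc0:tc1] = level
    img[tr0:tr1, c0:c1] = level
    mask[r0:r1, tc0:tc1] = True
    mask[tr0:tr1, c0:c1] = True


def _draw_dashed_ellipse(mask: np.ndarray, img: np.ndarray, spec: PhantomSpec,
                         level: int) -> None:
    cr, cc = spec.nodule_centre
    a, b = spec.nodule_axes
    rr, ccs = draw.ellipse_perimeter(cr, cc, a + 3, b + 3, shape=img.shape)
    # dash pattern: keep 5 of every 9 perimeter pixels, ordered by angle
    ang = np.arctan2(rr - cr, ccs - cc)
    order = np.argsort(ang)
    rr, ccs = rr[order], ccs[order]
    keep = (np.arange(rr.size) % 9) < 5
    img[rr[keep], ccs[keep]] = level
    mask[rr[keep], ccs[keep]] = True


def _draw_text_blocks(mask: np.ndarray, img: np.ndarray, spec: PhantomSpec,
                      levels: Sequence[int]) -> None:
    """Detached annotation blocks in the bottom margin, one per level.

    Each block is larger than the whole tick ruler so it is the modal
    intensity of its histogram partition among detached pixels.
    """
    h = spec.height
    r0 = h - max(4, int(round(0.08 * h))) + 2
    r1 = min(h - 1, r0 + 12)
    c = 8
    for lv in levels:
        c1 = min(img.shape[1] - 1, c + 30)
        img[r0:r1, c:c1] = lv
        mask[r0:r1, c:c1] = True
        c = c1 + 6


def generate_phantom(spec: PhantomSpec, seed: int,
                     image_id: str = "phantom") -> PhantomImage:
    """Generate one phantom; deterministic for fixed (spec, seed)."""
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    img = np.zeros((h, w), dtype=float)

    r0, r1, c0, c1 = _texture_bounds(spec)
    mean, corr = spec.speckle_params
    img[r0:r1, c0:c1] = _speckle((r1 - r0, c1 - c0), mean, corr, rng)

    # hypoechoic nodule; malignancy shows as a markedly darker interior
    factor = 0.35 if spec.class_label == MALIGNANT else 0.65
    rr, cc = draw.ellipse(*spec.nodule_centre, *spec.nodule_axes, shape=img.shape)
    img[rr, cc] *= factor

    # tick ruler: 2x2 bright dots every tick_spacing rows
    tick_col = int(round(spec.tick_column_frac * w))
    phase = spec.tick_spacing // 2
    tick_rows = np.arange(phase, h - 1, spec.tick_spacing)
    for tr in tick_rows:
        img[tr:tr + 2, tick_col:tick_col + 2] = TICK_INTENSITY

    clean = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    clean = _shift_collisions(clean, spec.artifact_levels)

    pixels = clean.copy()
    artifact_mask = np.zeros((h, w), dtype=bool)
    levels = sorted(int(l) for l in spec.artifact_levels)
    if levels and spec.artifact_kinds:
        if "caliper_cross" in spec.artifact_kinds:
            cr, cc_ = spec.nodule_centre
            a, b = spec.nodule_axes
            lv = levels[-1]
            for pt in ((cr - a, cc_), (cr, cc_ - b), (cr + a, cc_), (cr, cc_ + b)):
                _draw_cross(artifact_mask, pixels, pt, lv)
        if "dashed_outline" in spec.artifact_kinds:
            _draw_dashed_ellipse(artifact_mask, pixels, spec,
                                 levels[len(levels) // 2])
        if "text_block" in spec.artifact_kinds:
            _draw_text_blocks(artifact_mask, pixels, spec, levels)

    cr, cc_ = spec.nodule_centre
    a, b = spec.nodule_axes
    roi = ROIAnnotation(
        top=(cc_, cr - a), left=(cc_ - b, cr), bottom=(cc_, cr + a),
        right=(cc_ + b, cr),
        tirads="5" if spec.class_label == MALIGNANT else "2",
    )
    return PhantomImage(
        pixels=pixels, clean_pixels=clean, truth_tick_column=tick_col,
        truth_tick_spacing=int(spec.tick_spacing),
        truth_artifact_mask=artifact_mask, roi=roi,
        label=spec.class_label, spec=spec, image_id=image_id,
    )


def generate_cohort(
    n_images: int,
    malignant_fraction: float,
    size_mix: Sequence[tuple[int, int]] = ((360, 560),),
    seed: int = 0,
    tick_spacing_range: tuple[int, int] = (8, 40),
    base_spec: PhantomSpec | None = None,
) -> list[PhantomImage]:
    """Generate a cohort with a fixed malignant fraction and varied scales.

    Exactly ``round(n_images * malignant_fraction)`` phantoms are
    malignant; tick spacings cycle through ``tick_spacing_range`` so the
    calibration stage has genuine rescaling work to do. Per-phantom seeds
    derive from the cohort seed, so cohorts are fully reproducible.
    """
    if n_images < 1:
        raise ValidationError("n_images must be >= 1")
    if not 0.0 <= malignant_fraction <= 1.0:
        raise ValidationError("malignant_fraction must be in [0, 1]")
    if len(size_mix) == 0:
        raise ValidationError("size_mix must not be empty")

    rng = np.random.default_rng(seed)
    n_mal = int(round(n_images * malignant_fraction))
    labels = np.array([MALIGNANT] * n_mal + [BENIGN] * (n_images - n_mal))
    rng.shuffle(labels)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_images)

    lo, hi = tick_spacing_range
    spacings = lo + (np.arange(n_images) * 7) % (hi - lo + 1)

    phantoms = []
    for i in range(n_images):
        hgt, wid = size_mix[i % len(size_mix)]
        proto = base_spec if base_spec is not None else PhantomSpec()
        # jitter nodule geometry within safe bounds, derived from cohort rng
        a = int(rng.integers(int(0.09 * hgt), int(0.16 * hgt)))
        b = int(rng.integers(int(0.09 * wid) // 2, int(0.14 * wid)))
        cr = int(rng.integers(a + int(0.1 * hgt), hgt - a - int(0.1 * hgt)))
        cc = int(rng.integers(b + int(0.06 * wid), int(0.7 * wid) - b))
        spec = replace(
            proto, height=hgt, width=wid, tick_spacing=int(spacings[i]),
            nodule_centre=(cr, cc), nodule_axes=(a, b),
            class_label=str(labels[i]),
        )
        phantoms.append(
            generate_phantom(spec, int(child_seeds[i]), image_id=f"phantom{i:04d}")
        )
    return phantoms
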