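"""Nine-crop patch augmentation around an annotated nodule.

Each annotated image yields exactly nine ``patch_size`` x ``patch_size``
sub-images whose centres sit on a 3x3 grid (stride = half the patch size)
around the nodule centre, so that every patch contains nodule texture and
the off-centre patches also contain surrounding tissue. Labels are
inherited from the parent image; all nine crops share the parent's case
identity so that train/test splits can be made at case level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

BENIGN = "benign"
MALIGNANT = "malignant"

#: TI-RADS scores treated as suspicious/positive (malignant side).
MALIGNANT_TIRADS = frozenset({"3", "4a", "4b", "4c", "5"})
VALID_TIRADS = frozenset({"1", "2"}) | MALIGNANT_TIRADS


def tirads_label(tirads: str) -> str:
    """Binarize a TI-RADS score: >= 3 is malignant-suspicious."""
    t = str(tirads).lower()
    if t not in VALID_TIRADS:
        raise ValidationError(f"unknown TI-RADS score {tirads!r}; expected one of {sorted(VALID_TIRADS)}")
    return MALIGNANT if t in MALIGNANT_TIRADS else BENIGN


@dataclass(frozen=True)
class ROIAnnotation:
    """Four boundary points of a nodule plus its TI-RADS score.

    Points are (x, y) pixel coordinates with x = column and y = row,
    top-left origin. ``label`` is a pure function of ``tirads``.
    """

    top: tuple[int, int]
    left: tuple[int, int]
    bottom: tuple[int, int]
    right: tuple[int, int]
    tirads: str = "2"

    def __post_init__(self) -> None:
        if str(self.tirads).lower() not in VALID_TIRADS:
            raise ValidationError(f"tirads: unknown score {self.tirads!r}")
        if self.left[0] > self.right[0]:
            raise ValidationError("left.x must be <= right.x")
        if self.top[1] > self.bottom[1]:
            raise ValidationError("top.y must be <= bottom.y")
        for name in ("top", "left", "bottom", "right"):
            x, y = getattr(self, name)
            if x < 0 or y < 0:
                raise ValidationError(f"{name}: negative coordinate ({x}, {y})")

    @property
    def label(self) -> str:
        return tirads_label(self.tirads)

    def validate_inside(self, shape: tuple[int, int]) -> None:
        h, w = shape[:2]
        for name in ("top", "left", "bottom", "right"):
            x, y = getattr(self, name)
            if not (0 <= x < w and 0 <= y < h):
                raise ValidationError(f"{name}: point ({x}, {y}) outside {h}x{w} image")

    def to_dict(self) -> dict:
        return {
            "points": {
                "top": list(self.top),
                "left": list(self.left),
                "bottom": list(self.bottom),
                "right": list(self.right),
            },
            "tirads": self.tirads,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROIAnnotation":
        pts = d["points"]
        return cls(
            top=tuple(pts["top"]),
            left=tuple(pts["left"]),
            bottom=tuple(pts["bottom"]),
            right=tuple(pts["right"]),
            tirads=str(d["tirads"]),
        )


@dataclass(frozen=True)
class Sample:
    """One labelled crop with provenance back to its parent image."""

    patch: np.ndarray
    label: str
    parent_id: str
    crop_index: int
    offset: tuple[int, int]  # (row, col) of the patch origin in the parent

    def __post_init__(self) -> None:
        if self.patch.ndim != 2:
            raise ValidationError("patch must be a 2-D array")
        if not 0 <= self.crop_index <= 8:
            raise ValidationError("crop_index must be in 0..8")


def nodule_centre(roi: ROIAnnotation) -> tuple[int, int]:
    """Midpoint of the ROI bounding box, as integer (row, col)."""
    col = int(round((roi.left[0] + roi.right[0]) / 2.0))
    row = int(round((roi.top[1] + roi.bottom[1]) / 2.0))
    return row, col


def crop_nine(
    image: np.ndarray,
    roi: ROIAnnotation,
    patch_size: int = 256,
    stride: int | None = None,
    parent_id: str = "image",
) -> list[Sample]:
    """Crop the nine labelled sub-images covering nodule and surroundings.

    Patch centres sit at the nodule centre plus the 3x3 grid of offsets
    {-s, 0, +s}^2 with stride ``s = patch_size // 2`` by default; each
    patch origin is clamped so the patch lies fully inside the image.
    Images smaller than the patch are zero-padded (bottom/right) first.
    """
    if image.ndim != 2:
        raise ValidationError("image must be a 2-D array")
    roi.validate_inside(image.shape)
    if stride is None:
        stride = patch_size // 2

    h, w = image.shape
    if h < patch_size or w < patch_size:
        logger.warning(
            "image %s (%dx%d) smaller than patch %d; zero-padding",
            parent_id, h, w, patch_size,
        )
        image = np.pad(
            image,
            ((0, max(0, patch_size - h)), (0, max(0, patch_size - w))),
            mode="constant",
        )
        h, w = image.shape

    ctr_row, ctr_col = nodule_centre(roi)
    label = roi.label
    half = patch_size // 2
    samples: list[Sample] = []
    idx = 0
    for dr in (-stride, 0, stride):
        for dc in (-stride, 0, stride):
            r0 = int(np.clip(ctr_row + dr - half, 0, h - patch_size))
            c0 = int(np.clip(ctr_col + dc - half, 0, w - patch_size))
            patch = image[r0:r0 + patch_size, c0:c0 + patch_size].copy()
            samples.append(
                Sample(patch=patch, label=label, parent_id=parent_id,
                       crop_index=idx, offset=(r0, c0))
            )
            idx += 1
    return samples


def augment_dataset(
    images: Sequence[tuple[np.ndarray, ROIAnnotation]],
    patch_size: int = 256,
    stride: int | None = None,
    parent_ids: Sequence[str] | None = None,
) -> tuple[list[Sample], pd.DataFrame]:
    """Apply ``crop_nine`` to every annotated image.

    Returns the flat sample list (9 x n_images entries) and a per-class
    count report with case and sample counts.
    """
    if len(images) == 0:
        raise ValidationError("augment_dataset requires a non-empty image list")
    if parent_ids is None:
        parent_ids = [f"img{i:04d}" for i in range(len(images))]
    if len(parent_ids) != len(images):
        raise ValidationError("parent_ids length must match images")

    samples: list[Sample] = []
    case_labels: list[str] = []
    for pid, (image, roi) in zip(parent_ids, images):
        samples.extend(crop_nine(image, roi, patch_size=patch_size,
                                 stride=stride, parent_id=pid))
        case_labels.append(roi.label)

    rows = []
    for cls in (MALIGNANT, BENIGN):
        n_cases = sum(1 for lb in case_labels if lb == cls)
        rows.append({"class": cls, "cases": n_cases, "samples": 9 * n_cases})
    rows.append({
        "class": "total",
        "cases": len(case_labels),
        "samples": len(samples),
    })
    report = pd.DataFrame(rows, columns=["class", "cases", "samples"])
    return samples, report
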