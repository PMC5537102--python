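"""Reading and writing images, annotation sidecars and datasets.

Inputs are 8-bit PNG/TIFF images, single-channel or 3-channel replicated
grayscale, each accompanied by a JSON sidecar holding the four ROI
boundary points and the TI-RADS score. Datasets of crops are written as
patch PNGs plus a manifest CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .augmentation import ROIAnnotation, Sample
from .errors import ValidationError
from .phantom import PhantomImage

logger = logging.getLogger(__name__)


def sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale-content image as a 2-D uint8 array.

    3-channel inputs are reduced to luminance after checking the channels
    are (near) identical replicated grayscale; a mismatch is only warned
    about, since some capture chains tint overlays.
    """
    path = Path(path)
    img = Image.open(path)
    if img.mode in ("I;16", "I;16B", "I;16L", "I", "F"):
        raise ValidationError(
            f"{path.name}: {img.mode} input rejected; images must be 8-bit")
    if img.mode == "L":
        return np.asarray(img, dtype=np.uint8)
    if img.mode in ("RGB", "RGBA"):
        arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
        chan_dev = np.abs(arr.astype(int) - arr[:, :, :1].astype(int)).max()
        if chan_dev > 2:
            logger.warning("%s: channels differ by up to %d; using luminance",
                           path.name, chan_dev)
        return np.asarray(Image.fromarray(arr).convert("L"), dtype=np.uint8)
    raise ValidationError(f"{path.name}: unsupported image mode {img.mode!r}")


def read_annotated_image(path: str | Path) -> tuple[np.ndarray, ROIAnnotation]:
    """Load an image and its JSON annotation sidecar."""
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise ValidationError(
            f"missing annotation sidecar: expected {side.name} next to {path.name}")
    image = load_image(path)
    with open(side) as fh:
        roi = ROIAnnotation.from_dict(json.load(fh))
    roi.validate_inside(image.shape)
    return image, roi


def write_image(image: np.ndarray, path: str | Path, channels: int = 1) -> None:
    """Write a 2-D uint8 array as PNG; channels=3 replicates to RGB."""
    if image.dtype != np.uint8 or image.ndim != 2:
        raise ValidationError("write_image expects a 2-D uint8 array")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if channels == 3:
        Image.fromarray(np.stack([image] * 3, axis=2)).save(path)
    elif channels == 1:
        Image.fromarray(image).save(path)
    else:
        raise ValidationError("channels must be 1 or 3")


def write_phantom(phantom: PhantomImage, out_dir: str | Path,
                  channels: int = 1) -> Path:
    """Write a phantom PNG plus a JSON sidecar with its full ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{phantom.image_id}.png"
    write_image(phantom.pixels, img_path, channels=channels)
    side = phantom.roi.to_dict()
    side["truth"] = {
        "tick_column": phantom.truth_tick_column,
        "tick_spacing": phantom.truth_tick_spacing,
        "artifact_levels": [int(l) for l in phantom.spec.artifact_levels],
        "label": phantom.label,
    }
    with open(sidecar_path(img_path), "w") as fh:
        json.dump(side, fh, indent=1, sort_keys=True)
    return img_path


def write_dataset(samples: list[Sample], out_dir: str | Path) -> Path:
    """Write patch PNGs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        sid = f"{s.parent_id}_c{s.crop_index}"
        write_image(s.patch, out_dir / f"{sid}.png")
        rows.append({"sample_id": sid, "parent_id": s.parent_id,
                     "label": s.label, "crop_index": s.crop_index,
                     "offset_row": s.offset[0], "offset_col": s.offset[1]})
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_dataset(out_dir: str | Path) -> list[Sample]:
    """Read back a dataset written by :func:`write_dataset`."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    samples = []
    for _, row in manifest.iterrows():
        patch = load_image(out_dir / f"{row.sample_id}.png")
        samples.append(Sample(patch=patch, label=row.label,
                              parent_id=row.parent_id,
                              crop_index=int(row.crop_index),
                              offset=(int(row.offset_row), int(row.offset_col))))
    return samples
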