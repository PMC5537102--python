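"""Caliper/annotation artifact removal and POCS restoration.

Operator annotations (caliper crosses, outlines, text) are burned into
ultrasound captures at a small set of fixed intensities. The removal
procedure: (1) take the non-zero pixels as a binary image, (2) label its
2-D connected components, (3) call the largest component the texture
region and the remaining non-zero pixels "possible artifacts", (4) split
the possible-artifact histogram into the partitions [0,100], [101,200],
[201,255], (5) take the modal intensity of each partition as an artifact
level, and (6) erase every pixel (on texture or detached) whose intensity
matches a level. The erased gaps are then restored by projection onto
convex sets (POCS): alternating a data-consistency projection (reset all
known pixels) with a smoothness projection (per-tile block DCT keeping
only the lowest-frequency coefficients) until the masked pixels stop
changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn
from skimage.measure import label as cc_label

from .errors import EmptyImageError, ValidationError


@dataclass(frozen=True)
class ComponentLabeling:
    """Connected components of the non-zero pixels (8-connectivity)."""

    labels: np.ndarray  # int array, 0 = background
    K: int
    sizes: np.ndarray  # sizes[k-1] = pixel count of component k


@dataclass(frozen=True)
class TextureSegmentation:
    labeling: ComponentLabeling
    texture_mask: np.ndarray           # largest component
    possible_artifact_mask: np.ndarray  # non-zero pixels minus texture


@dataclass(frozen=True)
class ArtifactMask:
    """Detected artifact pixels plus the intensity levels that define them."""

    mask: np.ndarray
    levels: tuple[int, ...]
    texture_mask: np.ndarray


@dataclass(frozen=True)
class PocsParams:
    """Knobs of the POCS restoration.

    ``block_size`` is the DCT tile edge (8 is the standard block-transform
    tile); ``kept_coeffs`` low-frequency coefficients per tile survive the
    smoothness projection (10 of 64 keeps the local mean and the gentlest
    gradients); iteration stops when the mean absolute change on masked
    pixels drops to ``tol`` intensity levels or after ``max_iters``.
    """

    block_size: int = 8
    kept_coeffs: int = 10
    max_iters: int = 50
    tol: float = 0.1

    def __post_init__(self) -> None:
        if self.block_size < 4:
            raise ValidationError("block_size must be >= 4")
        if not 1 <= self.kept_coeffs <= self.block_size ** 2:
            raise ValidationError("kept_coeffs must be in [1, block_size^2]")
        if self.max_iters < 1:
            raise ValidationError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")


def segment_texture_region(image: np.ndarray) -> TextureSegmentation:
    """Label non-zero regions; the largest component is the texture."""
    if image.ndim != 2:
        raise ValidationError("image must be a 2-D array")
    nonzero = image > 0
    if not nonzero.any():
        raise EmptyImageError("empty image: no non-zero pixels")
    labels = cc_label(nonzero, connectivity=2)
    k = int(labels.max())
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1  # ties -> lowest label
    texture = labels == largest
    return TextureSegmentation(
        labeling=ComponentLabeling(labels=labels, K=k, sizes=sizes),
        texture_mask=texture,
        possible_artifact_mask=nonzero & ~texture,
    )


#: histogram partitions searched for one artifact level each
PARTITIONS = ((0, 100), (101, 200), (201, 255))


def estimate_artifact_levels(pixels: np.ndarray) -> tuple[int, ...]:
    """Modal intensity of each histogram partition among the given pixels.

    Empty partitions are omitted; ties break toward the lower intensity.
    """
    pixels = np.asarray(pixels).ravel()
    levels = []
    if pixels.size:
        hist = np.bincount(pixels.astype(np.int64), minlength=256)
        for lo, hi in PARTITIONS:
            part = hist[lo:hi + 1]
            if part.sum() > 0:
                levels.append(lo + int(np.argmax(part)))
    return tuple(levels)


def remove_artifacts(
    image: np.ndarray,
    levels: tuple[int, ...],
    texture_mask: np.ndarray,
    band: int = 0,
) -> tuple[np.ndarray, ArtifactMask]:
    """Erase every non-zero pixel whose intensity matches an artifact level.

    ``band`` widens exact matching to |pixel - level| <= band for real
    captures where anti-aliased overlays smear the levels; the default is
    exact matching, appropriate for hard-burned annotations. Erased pixels
    are set to 0 in the returned gapped image; the mask is authoritative.
    """
    if image.shape != texture_mask.shape:
        raise ValidationError("texture_mask shape must match image")
    nonzero = image > 0
    match = np.zeros_like(nonzero)
    for lv in levels:
        if band == 0:
            match |= image == lv
        else:
            match |= np.abs(image.astype(int) - int(lv)) <= band
    mask = match & nonzero
    gapped = image.copy()
    gapped[mask] = 0
    return gapped, ArtifactMask(mask=mask, levels=tuple(int(l) for l in levels),
                                texture_mask=texture_mask)


@lru_cache(maxsize=8)
def _zigzag_keep(block_size: int, kept: int) -> np.ndarray:
    """Boolean tile keeping the ``kept`` lowest-frequency DCT coefficients."""
    idx = [(i, j) for i in range(block_size) for j in range(block_size)]
    idx.sort(key=lambda ij: (ij[0] + ij[1], ij[0] if (ij[0] + ij[1]) % 2 else ij[1]))
    keep = np.zeros((block_size, block_size), dtype=bool)
    for i, j in idx[:kept]:
        keep[i, j] = True
    return keep


def _block_dct_lowpass(img: np.ndarray, params: PocsParams) -> np.ndarray:
    """Smoothness projection: per-tile DCT truncation."""
    bs = params.block_size
    h, w = img.shape
    ph = (-h) % bs
    pw = (-w) % bs
    x = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    nh, nw = x.shape[0] // bs, x.shape[1] // bs
    tiles = x.reshape(nh, bs, nw, bs).transpose(0, 2, 1, 3)
    coef = dctn(tiles, axes=(2, 3), norm="ortho")
    coef *= _zigzag_keep(bs, params.kept_coeffs)
    tiles = idctn(coef, axes=(2, 3), norm="ortho")
    x = tiles.transpose(0, 2, 1, 3).reshape(nh * bs, nw * bs)
    return x[:h, :w]


def _initialize_unknowns(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Seed masked pixels with the median of their 5x5 known neighbours.

    Pixels deep inside a thick artifact (no known pixel within the 5x5
    window) take the value of their nearest known pixel instead, so the
    iteration starts from locally plausible intensities everywhere —
    block-DCT smoothing alone cannot carry information into tiles that
    contain no known pixels.
    """
    x = image.astype(float)
    _, (ir, ic) = ndimage.distance_transform_edt(mask, return_indices=True)
    nearest = x[ir, ic]
    pad = np.pad(x, 2, mode="edge")
    padmask = np.pad(mask, 2, mode="constant", constant_values=True)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        win = pad[r:r + 5, c:c + 5]
        wmask = padmask[r:r + 5, c:c + 5]
        vals = win[~wmask]
        x[r, c] = np.median(vals) if vals.size else nearest[r, c]
    return x


def restore_pocs(
    gapped: np.ndarray,
    mask: np.ndarray,
    params: PocsParams = PocsParams(),
    return_history: bool = False,
):
    """Fill masked pixels by POCS with block-DCT smoothness.

    Alternates (P2) per-tile DCT truncation with (P1) resetting known
    pixels to their observed values; P1 is applied last, so known pixels
    of the output equal the input exactly. Returns the restored uint8
    image (and the per-iteration mean absolute change on masked pixels
    when ``return_history`` is set).
    """
    if gapped.shape != mask.shape:
        raise ValidationError("mask shape must match image")
    if mask.all():
        raise ValidationError("nothing known: mask covers the whole image")
    observed = gapped.astype(float)
    if not mask.any():
        restored = np.clip(np.rint(observed), 0, 255).astype(np.uint8)
        return (restored, []) if return_history else restored

    x = _initialize_unknowns(gapped, mask)
    x[~mask] = observed[~mask]
    changes: list[float] = []
    for _ in range(params.max_iters):
        prev = x[mask].copy()
        x = _block_dct_lowpass(x, params)   # P2: smoothness
        x[~mask] = observed[~mask]          # P1: data consistency
        delta = float(np.mean(np.abs(x[mask] - prev)))
        changes.append(delta)
        if delta <= params.tol:
            break
    restored = np.clip(np.rint(x), 0, 255).astype(np.uint8)
    restored[~mask] = gapped[~mask]  # bit-exact known pixels
    return (restored, changes) if return_history else restored


def clean_image(
    image: np.ndarray,
    params: PocsParams = PocsParams(),
    band: int = 0,
    tick_column: int | None = None,
) -> tuple[np.ndarray, ArtifactMask, list[float]]:
    """Full artifact pass: segment, estimate levels, remove, restore.

    When ``tick_column`` is given (from calibration), the tick-ruler strip
    around that column is added to the removal mask so the ruler does not
    survive into the texture-learning stages.
    """
    seg = segment_texture_region(image)
    levels = estimate_artifact_levels(image[seg.possible_artifact_mask])
    gapped, amask = remove_artifacts(image, levels, seg.texture_mask, band=band)
    mask = amask.mask
    if tick_column is not None:
        strip = np.zeros_like(mask)
        c0 = max(0, tick_column - 1)
        strip[:, c0:tick_column + 3] = image[:, c0:tick_column + 3] > 0
        mask = mask | strip
        gapped = gapped.copy()
        gapped[strip] = 0
        amask = ArtifactMask(mask=mask, levels=amask.levels,
                             texture_mask=amask.texture_mask)
    restored, history = restore_pocs(gapped, mask, params, return_history=True)
    return restored, amask, history
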