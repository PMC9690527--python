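"""Slice preprocessing: binarization, hole filling, effective-region
cropping, and min-max intensity normalization.

Raw MRI exports vary in global brightness across scanners and contrast
doses, and most of each slice is empty background. The pipeline here
(a) thresholds a slice at its mean intensity, (b) fills enclosed holes to
get a solid anatomy silhouette, (c) crops both the slice and its label
mask to the bounding box of that silhouette, and (d) rescales intensities
to [0, 1] before resizing to the network input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.transform import resize


class Plane(str, Enum):
    TRANSVERSE = "transverse"
    CORONAL = "coronal"
    SAGITTAL = "sagittal"
    UNKNOWN = "unknown"


@dataclass
class GrayscaleSlice:
    """One 2-D MRI slice: intensity array plus provenance metadata."""
    pixels: np.ndarray
    patient_id: str = ""
    plane: Plane = Plane.UNKNOWN

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("slice must be a nonempty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Per-pixel {0, 1} labeling, shape-locked to its slice."""
    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("mask must be a nonempty 2-D array")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class BoundingBox:
    """0-based, inclusive-on-both-ends pixel box."""
    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if not (0 <= self.row_min <= self.row_max and 0 <= self.col_min <= self.col_max):
            raise ValueError(f"invalid box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min + 1, self.col_max - self.col_min + 1)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_min, self.row_max + 1),
                slice(self.col_min, self.col_max + 1))


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing options.

    tie_to_foreground
        Pixels exactly equal to the slice mean count as foreground; keeps
        uniform regions inside the effective area instead of being
        undefined at the threshold.
    target_size
        (H, W) the model consumes; slices are resized bilinearly, masks
        with nearest-neighbour so labels stay binary.
    constant_image_value
        Normalized value assigned to every pixel of a constant slice
        (where min-max scaling is degenerate).
    """
    tie_to_foreground: bool = True
    target_size: tuple[int, int] = (256, 256)
    constant_image_value: float = 0.0

    def __post_init__(self):
        h, w = self.target_size
        if h < 1 or w < 1:
            raise ValueError("target_size must be positive")


class NoForegroundError(ValueError):
    """Raised when an operation requires at least one foreground pixel."""


def binarize(slc: GrayscaleSlice, cfg: PreprocessConfig = PreprocessConfig()) -> BinaryMask:
    """Threshold a slice at its mean intensity.

    A pixel maps to 1 iff p > mean (or p >= mean when ``tie_to_foreground``).
    """
    p = slc.pixels
    mu = p.mean()
    fg = p >= mu if cfg.tie_to_foreground else p > mu
    return BinaryMask(fg.astype(np.uint8))


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background regions not 4-connected to the image border."""
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    filled = ndimage.binary_fill_holes(mask.pixels.astype(bool), structure=structure)
    return BinaryMask(filled.astype(np.uint8))


def effective_region(mask: BinaryMask) -> BoundingBox:
    """Smallest box containing every foreground pixel."""
    rows = np.flatnonzero(mask.pixels.any(axis=1))
    cols = np.flatnonzero(mask.pixels.any(axis=0))
    if rows.size == 0:
        raise NoForegroundError("mask has no foreground pixels")
    return BoundingBox(int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1]))


def normalize(slc: GrayscaleSlice, cfg: PreprocessConfig = PreprocessConfig()) -> GrayscaleSlice:
    """Min-max rescale intensities to [0, 1].

    Constant slices (max == min) map uniformly to ``constant_image_value``.
    """
    p = slc.pixels
    pmin, pmax = p.min(), p.max()
    if pmax > pmin:
        out = (p - pmin) / (pmax - pmin)
    else:
        out = np.full_like(p, cfg.constant_image_value)
    return GrayscaleSlice(out, patient_id=slc.patient_id, plane=slc.plane)


def preprocess_sample(slc: GrayscaleSlice, mask: BinaryMask,
                      cfg: PreprocessConfig = PreprocessConfig()
                      ) -> tuple[GrayscaleSlice, BinaryMask]:
    """Full pipeline: binarize -> fill -> crop both to the box -> normalize
    -> resize to ``cfg.target_size``.

    The crop box derived from the slice is applied to the label mask as
    well (they must stay aligned). Slices are resized bilinearly; masks
    with nearest-neighbour interpolation so they remain strictly binary.
    """
    if slc.shape != mask.shape:
        raise ValueError(f"slice shape {slc.shape} != mask shape {mask.shape}")
    silhouette = fill_holes(binarize(slc, cfg))
    box = effective_region(silhouette)
    rs, cs = box.slices()
    cropped = GrayscaleSlice(slc.pixels[rs, cs], patient_id=slc.patient_id,
                             plane=slc.plane)
    cropped_mask = mask.pixels[rs, cs]
    normed = normalize(cropped, cfg)
    img = resize(normed.pixels, cfg.target_size, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    lab = resize(cropped_mask, cfg.target_size, order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    out_slice = GrayscaleSlice(np.clip(img, 0.0, 1.0),
                               patient_id=slc.patient_id, plane=slc.plane)
    return out_slice, BinaryMask(lab.astype(np.uint8))
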