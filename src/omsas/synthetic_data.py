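"""MRI-like phantom generator with ground-truth tumor masks.

Each phantom is a dark background holding a bright elliptical "limb"
(anatomy cross-section) with mild internal texture, containing a single
irregular tumor blob of different intensity. Per-image global brightness
offsets emulate inter-scanner brightness differences, and the tumor
boundary is a smooth periodic perturbation of a circle so its
irregularity is controllable. Slices of one synthetic patient share a
tumor geometry with small per-slice variation, mirroring multiple
cross-sectional planes of one lesion.

Everything is fully determined by (seed, index), so datasets regenerate
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BinaryMask, GrayscaleSlice, Plane

_PLANES = (Plane.TRANSVERSE, Plane.CORONAL, Plane.SAGITTAL)


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity settings of the phantom generator.

    All lengths are in pixels; intensities are on a nominal [0, 1] scale
    before the per-image brightness offset is added (slices are raw,
    i.e. not yet normalized).
    """
    image_size: tuple[int, int] = (128, 128)
    limb_axes_range: tuple[int, int] = (36, 56)
    tumor_radius_range: tuple[int, int] = (10, 22)
    tumor_irregularity: float = 0.2
    tumor_contrast: float = 0.35
    brightness_jitter: float = 0.15
    texture_noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if min(h, w) < 32:
            raise ValueError("image_size must be at least 32x32")
        if self.limb_axes_range[0] > self.limb_axes_range[1] or \
                self.tumor_radius_range[0] > self.tumor_radius_range[1]:
            raise ValueError("ranges must be (low, high) with low <= high")
        if not 0 <= self.tumor_irregularity <= 1:
            raise ValueError("tumor_irregularity must lie in [0, 1]")
        if self.tumor_contrast == 0:
            raise ValueError("tumor_contrast must be nonzero")
        # tumor (with boundary perturbation) must fit inside the limb
        max_tumor = self.tumor_radius_range[1] * (1 + self.tumor_irregularity)
        if max_tumor >= self.limb_axes_range[0]:
            raise ValueError("tumor cannot fit inside the smallest limb")
        if max(self.limb_axes_range[1], 1) >= min(h, w) // 2:
            raise ValueError("limb does not fit in the image")


def _scaled_geometry(image_size: tuple[int, int]) -> dict:
    """Limb and tumor sizes proportional to the frame (128 px reference)."""
    s = min(image_size)
    return dict(limb_axes_range=(max(10, int(0.28 * s)), int(0.44 * s)),
                tumor_radius_range=(max(3, int(0.08 * s)), int(0.17 * s)))


def easy_params(seed: int = 0, image_size: tuple[int, int] = (128, 128)) -> PhantomParams:
    """High-contrast, low-irregularity phantoms (training probes)."""
    return PhantomParams(image_size=image_size, tumor_contrast=0.4,
                         tumor_irregularity=0.12, brightness_jitter=0.1,
                         texture_noise_sigma=0.02, seed=seed,
                         **_scaled_geometry(image_size))


def hard_params(seed: int = 0, image_size: tuple[int, int] = (128, 128)) -> PhantomParams:
    """Low-contrast, jittery phantoms (robustness tests)."""
    return PhantomParams(image_size=image_size, tumor_contrast=0.15,
                         tumor_irregularity=0.35, brightness_jitter=0.3,
                         texture_noise_sigma=0.05, seed=seed,
                         **_scaled_geometry(image_size))


PRESETS = {"easy": easy_params, "hard": hard_params, "default": PhantomParams}


def _tumor_radius_profile(rng: np.random.Generator, r0: float,
                          irregularity: float, n_harmonics: int = 4):
    """r(theta) = r0 * (1 + a * sum of smooth random harmonics)."""
    amps = rng.uniform(0.2, 1.0, n_harmonics)
    amps /= amps.sum()
    orders = rng.integers(2, 6, n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)

    def profile(theta: np.ndarray) -> np.ndarray:
        pert = sum(a * np.cos(k * theta + p)
                   for a, k, p in zip(amps, orders, phases))
        return r0 * (1.0 + irregularity * pert)

    return profile


def _patient_geometry(rng: np.random.Generator, params: PhantomParams):
    """Shared per-patient limb/tumor geometry (varied slightly per slice)."""
    h, w = params.image_size
    cy, cx = h / 2 + rng.uniform(-4, 4), w / 2 + rng.uniform(-4, 4)
    a = rng.uniform(*params.limb_axes_range)
    b = rng.uniform(params.limb_axes_range[0], a)
    angle = rng.uniform(0, np.pi)
    r0 = rng.uniform(*params.tumor_radius_range)
    # place the tumor centre so the maximally perturbed boundary stays inside
    margin = r0 * (1 + params.tumor_irregularity) + 2.0
    rad = rng.uniform(0, max(0.0, min(a, b) - margin))
    ang = rng.uniform(0, 2 * np.pi)
    ty = cy + rad * np.sin(ang)
    tx = cx + rad * np.cos(ang)
    return dict(cy=cy, cx=cx, a=a, b=b, angle=angle, r0=r0, ty=ty, tx=tx)


def generate_phantom(params: PhantomParams, index: int
                     ) -> tuple[GrayscaleSlice, BinaryMask, str]:
    """Generate phantom ``index`` deterministically from (seed, index).

    Returns the raw (un-normalized) slice, its tumor mask, and a synthetic
    patient id. Slice ``index`` belongs to patient ``index // 3`` so each
    synthetic patient contributes three planes.
    """
    if index < 0:
        raise ValueError("index must be non-negative")
    patient = index // 3
    plane = _PLANES[index % 3]
    geom_rng = np.random.default_rng(
        np.random.SeedSequence((params.seed, patient)))
    geom = _patient_geometry(geom_rng, params)
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, index, 7)))

    h, w = params.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # small per-slice variation of the shared geometry
    cy = geom["cy"] + rng.uniform(-1.5, 1.5)
    cx = geom["cx"] + rng.uniform(-1.5, 1.5)
    a = geom["a"] * rng.uniform(0.95, 1.05)
    b = geom["b"] * rng.uniform(0.95, 1.05)
    r0 = geom["r0"] * rng.uniform(0.95, 1.05)
    ty = geom["ty"] + rng.uniform(-1.0, 1.0)
    tx = geom["tx"] + rng.uniform(-1.0, 1.0)
    angle = geom["angle"]

    cos_t, sin_t = np.cos(angle), np.sin(angle)
    xr = (xx - cx) * cos_t + (yy - cy) * sin_t
    yr = -(xx - cx) * sin_t + (yy - cy) * cos_t
    limb = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    profile = _tumor_radius_profile(rng, r0, params.tumor_irregularity)
    dy, dx = yy - ty, xx - tx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    tumor = dist <= profile(theta)

    img = np.full((h, w), 0.05)
    img[limb] = 0.45 + 0.08 * np.sin(xr[limb] / 9.0) * np.cos(yr[limb] / 11.0)
    if params.texture_noise_sigma > 0:
        img += rng.normal(0.0, params.texture_noise_sigma, size=(h, w))
    img[tumor] += params.tumor_contrast
    img += rng.uniform(-params.brightness_jitter, params.brightness_jitter)
    img = np.clip(img, 0.0, 1.5)

    slc = GrayscaleSlice(img, patient_id=f"P{patient:04d}", plane=plane)
    return slc, BinaryMask(tumor.astype(np.uint8)), slc.patient_id


def generate_samples(n: int, params: PhantomParams
                     ) -> list[tuple[GrayscaleSlice, BinaryMask]]:
    """Convenience: the first ``n`` phantoms as in-memory pairs."""
    return [generate_phantom(params, i)[:2] for i in range(n)]


def generate_dataset(n_patients: int, slices_per_patient: int,
                     params: PhantomParams, out_dir: str | Path
                     ) -> pd.DataFrame:
    """Write a phantom dataset to disk and return its manifest.

    Layout: ``<out>/images/<id>_<k>.png``, ``<out>/masks/<id>_<k>.png``
    (masks use {0, 255}), plus ``manifest.csv`` with columns
    (patient_id, slice_path, mask_path, plane). Plane labels cycle
    transverse/coronal/sagittal.
    """
    if n_patients < 1 or slices_per_patient < 1:
        raise ValueError("need at least one patient and one slice")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    from imageio.v3 import imwrite

    rows = []
    for p in range(n_patients):
        for s in range(slices_per_patient):
            # index encodes (patient, plane-cycling slice)
            index = p * 3 + (s % 3)
            # distinct slices beyond the 3 planes perturb via a sub-seed
            sub = PhantomParams(**{**params.__dict__,
                                   "seed": params.seed + 100003 * (s // 3)})
            slc, mask, pid = generate_phantom(sub, index)
            img_path = out_dir / "images" / f"{pid}_{s:03d}.png"
            mask_path = out_dir / "masks" / f"{pid}_{s:03d}.png"
            imwrite(img_path,
                    np.clip(slc.pixels / 1.5 * 255, 0, 255).astype(np.uint8))
            imwrite(mask_path, (mask.pixels * 255).astype(np.uint8))
            rows.append(dict(patient_id=pid,
                             slice_path=str(img_path.relative_to(out_dir)),
                             mask_path=str(mask_path.relative_to(out_dir)),
                             plane=slc.plane.value))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
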