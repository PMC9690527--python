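"""Dihedral (D4) augmentation and noise injection.

Rotating a square image by quarter turns and flipping it generates the
8-element dihedral orbit. Emitting the orbit of every training sample
multiplies the dataset by exactly 8; the same transforms (with their
inverses) drive test-time-augmentation fusion at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import BinaryMask, GrayscaleSlice


@dataclass(frozen=True)
class DihedralTransform:
    """One symmetry of the square: ``rotation`` quarter-turns
    counterclockwise, then an optional horizontal (left-right) flip.

    The 8 (rotation, flip) pairs form the dihedral group D4; composition
    and inversion stay inside the set.
    """
    rotation: int = 0
    flip: bool = False

    def __post_init__(self):
        if self.rotation not in (0, 1, 2, 3):
            raise ValueError("rotation must be 0..3 quarter turns")

    def apply_array(self, arr: np.ndarray) -> np.ndarray:
        out = np.rot90(arr, self.rotation)
        if self.flip:
            out = out[:, ::-1]
        return np.ascontiguousarray(out)

    def inverse(self) -> "DihedralTransform":
        # reflections are involutions; pure rotations invert by negation
        if self.flip:
            return self
        return DihedralTransform((-self.rotation) % 4, False)

    def compose(self, first: "DihedralTransform") -> "DihedralTransform":
        """The transform equivalent to applying ``first`` then ``self``."""
        sign = -1 if first.flip else 1
        return DihedralTransform((first.rotation + sign * self.rotation) % 4,
                                 self.flip ^ first.flip)


@dataclass(frozen=True)
class AugmentationConfig:
    """Noise-injection settings for training-set augmentation.

    noise_sigma
        Std of additive Gaussian noise, as a fraction of the normalized
        [0, 1] intensity range.
    noise_fraction
        Fraction of augmented images that receive noise.
    """
    noise_sigma: float = 0.05
    noise_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must lie in [0, 1]")


def d4_orbit() -> list[DihedralTransform]:
    """The 8 square symmetries, identity first, rotations before reflections."""
    return [DihedralTransform(k, f) for f in (False, True) for k in range(4)]


def apply(t: DihedralTransform, slc: GrayscaleSlice,
          mask: BinaryMask | None = None
          ) -> GrayscaleSlice | tuple[GrayscaleSlice, BinaryMask]:
    """Apply one dihedral transform to a slice (and its mask, identically)."""
    out_slice = GrayscaleSlice(t.apply_array(slc.pixels),
                               patient_id=slc.patient_id, plane=slc.plane)
    if mask is None:
        return out_slice
    if mask.shape != slc.shape:
        raise ValueError("slice and mask shapes differ")
    return out_slice, BinaryMask(t.apply_array(mask.pixels))


def inverse(t: DihedralTransform) -> DihedralTransform:
    return t.inverse()


def add_noise(slc: GrayscaleSlice, cfg: AugmentationConfig,
              rng: np.random.Generator | None = None) -> GrayscaleSlice:
    """Additive Gaussian noise on a normalized slice, clipped back to [0, 1]."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    noisy = slc.pixels + rng.normal(0.0, cfg.noise_sigma, size=slc.shape) \
        if cfg.noise_sigma > 0 else slc.pixels.copy()
    return GrayscaleSlice(np.clip(noisy, 0.0, 1.0),
                          patient_id=slc.patient_id, plane=slc.plane)


def augment_dataset(samples: list[tuple[GrayscaleSlice, BinaryMask]],
                    cfg: AugmentationConfig = AugmentationConfig()
                    ) -> list[tuple[GrayscaleSlice, BinaryMask]]:
    """Expand each sample to its full 8-element dihedral orbit, then add
    noise to a seeded random subset of the images (never to the masks).

    Output length is exactly ``8 * len(samples)``.
    """
    orbit = d4_orbit()
    augmented: list[tuple[GrayscaleSlice, BinaryMask]] = []
    for slc, mask in samples:
        for t in orbit:
            augmented.append(apply(t, slc, mask))
    rng = np.random.default_rng(cfg.seed)
    n_noisy = int(round(cfg.noise_fraction * len(augmented)))
    if n_noisy and cfg.noise_sigma > 0:
        chosen = rng.choice(len(augmented), size=n_noisy, replace=False)
        for idx in chosen:
            slc, mask = augmented[idx]
            augmented[idx] = (add_noise(slc, cfg, rng), mask)
    return augmented
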