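"""Compound-decision inference: test-time-augmentation fusion.

A trained network need not be equivariant to rotations and flips, so the
8 dihedral copies of one slice generally yield 8 different predictions.
Compound decision runs the model on every copy, re-aligns each output
with the inverse transform, and fuses the aligned stack by per-pixel
majority vote (ties count as tumor — recall is prioritized). By
construction the fused prediction is exactly equivariant under the
dihedral group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acrnet import ACRNet
from .augmentation import DihedralTransform, apply, d4_orbit
from .preprocess import BinaryMask, GrayscaleSlice


@dataclass
class VoteStack:
    """Aligned binary prediction maps awaiting the per-pixel vote."""
    copies: np.ndarray  # (n, H, W) in {0, 1}

    def __post_init__(self):
        arr = np.asarray(self.copies)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("need a nonempty (n, H, W) stack")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("stack values must be binary")
        self.copies = arr.astype(np.uint8)

    @property
    def n(self) -> int:
        return self.copies.shape[0]


def predict_single(model: ACRNet, slc: GrayscaleSlice,
                   threshold: float = 0.5) -> BinaryMask:
    """Single forward pass, thresholded at ``threshold`` (ties -> tumor)."""
    h, w = model.config.input_size
    if slc.shape != (h, w):
        raise ValueError(f"slice shape {slc.shape} != model input {(h, w)}")
    probs = model.forward(slc.pixels[None, None])[0, 0]
    return BinaryMask((probs >= threshold).astype(np.uint8))


def compound_decision(stack: VoteStack, literal_eq6: bool = False) -> BinaryMask:
    """Fuse an aligned stack by per-pixel majority vote.

    A pixel is tumor iff at least half the copies vote tumor (ties ->
    tumor). ``literal_eq6`` instead applies the printed sign-function
    form r = 1/2 - 1/2 * sign(sigma - n/2), which votes *against* the
    majority; it is exposed only for auditing that formulation.
    """
    sigma = stack.copies.sum(axis=0, dtype=np.int64)
    half = stack.n / 2.0
    if literal_eq6:
        r = 0.5 - 0.5 * np.sign(sigma - half)
        return BinaryMask((r >= 0.5).astype(np.uint8))
    return BinaryMask((sigma >= half).astype(np.uint8))


def predict_compound(model: ACRNet, slc: GrayscaleSlice,
                     threshold: float = 0.5,
                     average_probabilities: bool = False) -> BinaryMask:
    """Predict on all 8 dihedral copies, re-align, and fuse.

    With ``average_probabilities`` the aligned probability maps are
    averaged and thresholded once instead of voting on binary maps.
    """
    h, w = model.config.input_size
    if slc.shape != (h, w):
        raise ValueError(f"slice shape {slc.shape} != model input {(h, w)}")
    aligned_probs = []
    for t in d4_orbit():
        transformed = apply(t, slc)
        probs = model.forward(transformed.pixels[None, None])[0, 0]
        aligned_probs.append(t.inverse().apply_array(probs))
    if average_probabilities:
        mean = np.mean(aligned_probs, axis=0)
        return BinaryMask((mean >= threshold).astype(np.uint8))
    stack = VoteStack(np.stack([(p >= threshold).astype(np.uint8)
                                for p in aligned_probs]))
    return compound_decision(stack)


def attention_overlay(model: ACRNet, slc: GrayscaleSlice, stage_index: int = 0,
                      cmap: str = "magma", alpha: float = 0.5) -> np.ndarray:
    """Render where a stage's attention condenser focuses, as an RGB image.

    Runs the model, takes the channel-mean of the stage's gate map,
    upsamples it to the input size, maps it through a colormap, and
    blends it over the grayscale slice. Brighter overlay = more
    attention. Returns an (H, W, 3) float array in [0, 1].
    """
    from matplotlib import colormaps
    from skimage.transform import resize

    model.forward(slc.pixels[None, None])
    gates = model.attention_gates(stage_index)[0]  # (C, h', w')
    heat = gates.mean(axis=0)
    heat = resize(heat, slc.shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    lo, hi = heat.min(), heat.max()
    heat_unit = (heat - lo) / (hi - lo) if hi > lo else np.zeros_like(heat)
    colored = colormaps[cmap](heat_unit)[..., :3]
    gray = slc.pixels
    span = float(np.ptp(gray))
    g = (gray - gray.min()) / (span if span > 0 else 1.0)
    return np.clip((1 - alpha) * g[..., None] + alpha * colored, 0.0, 1.0)
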