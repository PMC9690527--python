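"""Manifests, image I/O, and run configuration.

Datasets are indexed by a CSV manifest with columns
(patient_id, slice_path, mask_path, plane); paths are stored relative to
the manifest's directory. Run configuration is a YAML document merged
over defaults, schema-checked, and rejecting unknown keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import BinaryMask, GrayscaleSlice, Plane

MANIFEST_COLUMNS = ["patient_id", "slice_path", "mask_path", "plane"]


@dataclass
class DatasetManifest:
    rows: pd.DataFrame
    root: Path

    def __len__(self) -> int:
        return len(self.rows)

    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["patient_id"]))

    def resolve(self, rel_path: str) -> Path:
        return self.root / rel_path


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF (8- or 16-bit) as float64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread
        arr = imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) exports to luminance
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(np.float64)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a {0, 255} PNG mask as a {0, 1} BinaryMask."""
    arr = read_image(path)
    return BinaryMask((arr > 127).astype(np.uint8))


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    from imageio.v3 import imwrite
    imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG."""
    from imageio.v3 import imwrite
    imwrite(Path(path), np.clip(pixels * 255, 0, 255).astype(np.uint8))


def load_slice(manifest: DatasetManifest, row) -> GrayscaleSlice:
    return GrayscaleSlice(read_image(manifest.resolve(row.slice_path)),
                          patient_id=str(row.patient_id),
                          plane=Plane(row.plane))


def read_manifest(path: str | Path, check_paths: bool = True) -> DatasetManifest:
    """Load and validate a manifest CSV.

    mask_path may be empty for inference-only rows. Raises descriptive
    errors on a missing file, bad header, duplicate slice paths, or
    dangling paths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    rows = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    if (rows["patient_id"] == "").any():
        bad = rows.index[rows["patient_id"] == ""].tolist()
        raise ValueError(f"empty patient_id at rows {bad}")
    dup = rows["slice_path"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate slice_path at rows {rows.index[dup].tolist()}")
    root = path.parent
    if check_paths:
        for i, row in rows.iterrows():
            if not (root / row.slice_path).exists():
                raise FileNotFoundError(
                    f"row {i}: slice file missing: {row.slice_path}")
            if row.mask_path and not (root / row.mask_path).exists():
                raise FileNotFoundError(
                    f"row {i}: mask file missing: {row.mask_path}")
    return DatasetManifest(rows=rows, root=root)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    manifest.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_DEFAULTS: dict = {
    "preprocess": {"tie_to_foreground": True, "target_size": [256, 256],
                   "constant_image_value": 0.0},
    "augmentation": {"noise_sigma": 0.05, "noise_fraction": 0.25},
    "model": {"input_size": [256, 256], "stage_widths": [32, 64, 128, 256],
              "units_per_stage": 2, "condenser_ratio": 4,
              "spatial_condense": 2},
    "training": {"learning_rate": 1.0e-4, "epochs": 460, "batch_size": 8},
    "split": {"train_fraction": 0.7, "k_folds": 10},
    "loss": {"alpha": 0.25, "beta": 0.75, "epsilon": 1.0e-8},
    "seed": 0,
}


@dataclass
class RunConfig:
    """Resolved nested configuration (defaults merged with user overrides)."""
    values: dict = field(default_factory=lambda: _deep_copy(_DEFAULTS))

    def __getitem__(self, key):
        return self.values[key]

    def hash(self) -> str:
        import hashlib
        import json
        blob = json.dumps(self.values, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _deep_copy(d):
    import copy
    return copy.deepcopy(d)


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in override:
            value = override[key]
            if isinstance(default, dict):
                if not isinstance(value, dict):
                    raise TypeError(f"{here}: expected a mapping")
                out[key] = _merge(default, value, here)
            else:
                if default is not None and value is not None and \
                        not isinstance(value, type(default)) and \
                        not (isinstance(default, float) and isinstance(value, int)):
                    raise TypeError(
                        f"{here}: expected {type(default).__name__}, "
                        f"got {type(value).__name__}")
                out[key] = value
        else:
            out[key] = _deep_copy(default)
    unknown = set(override) - set(defaults)
    if unknown:
        where = path or "top level"
        raise KeyError(f"unknown config keys at {where}: {sorted(unknown)}")
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load YAML config merged over the defaults; unknown keys are rejected.

    An empty or missing document yields pure defaults.
    """
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config {path}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config {path} must be a mapping")
            user = loaded
    if overrides:
        user = _merge_shallow(user, overrides)
    return RunConfig(values=_merge(_DEFAULTS, user))


def _merge_shallow(base: dict, extra: dict) -> dict:
    out = _deep_copy(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_shallow(out[k], v)
        else:
            out[k] = v
    return out
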