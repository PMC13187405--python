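"""Reading and writing mask volumes, parametric maps, biomarker tables and run config.

Arrays are indexed ``(slice, row, col)``. Spacing is ``(sx, sy, sz)`` in mm,
where ``sx`` is the in-plane row spacing, ``sy`` the in-plane column spacing
and ``sz`` the slice thickness, so the voxel volume is ``sx * sy * sz`` mm^3.
NIfTI is the single on-disk dialect for volumes; tables are CSV and label
maps / run configuration are YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mskmark")
if not logger.handlers:  # structured default: stderr, level INFO
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

VALID_UNITS = {"mm", "cm3", "ms", "z"}

BIOMARKER_COLUMNS = ["subject_id", "visit_month", "compartment", "biomarker", "value", "units"]


@dataclass(frozen=True)
class MaskVolume:
    """A 3D integer label volume with physical spacing and a label map.

    ``label_map`` maps label id -> (structure name, tissue class), e.g.
    ``{1: ("femoral cartilage", "cartilage")}``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_map: Mapping[int, tuple[str, str]]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-valued, got dtype={labels.dtype}")
        object.__setattr__(self, "labels", labels)
        sx, sy, sz = (float(s) for s in self.spacing)
        if min(sx, sy, sz) <= 0:
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "spacing", (sx, sy, sz))
        present = set(np.unique(labels)) - {0}
        unknown = sorted(int(v) for v in present if int(v) not in self.label_map)
        if unknown:
            raise ValueError(f"mask contains labels absent from label_map: {unknown}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        return self.spacing[0], self.spacing[1]


@dataclass(frozen=True)
class ParametricMap:
    """A 3D relaxometry map (values in ms) on the same grid as its mask."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    modality: str  # "T1rho" or "T2"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"map must be 3D, got ndim={values.ndim}")
        object.__setattr__(self, "values", values)
        if self.modality not in {"T1rho", "T2"}:
            raise ValueError(f"modality must be 'T1rho' or 'T2', got {self.modality!r}")
        sx, sy, sz = (float(s) for s in self.spacing)
        if min(sx, sy, sz) <= 0:
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "spacing", (sx, sy, sz))

    def check_paired(self, mask: MaskVolume) -> None:
        if self.values.shape != mask.labels.shape:
            raise ValueError(
                f"shape mismatch: map {self.values.shape} vs mask {mask.labels.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _to_nifti_order(array: np.ndarray) -> np.ndarray:
    # internal (slice, row, col) -> on-disk (col, row, slice)
    return np.transpose(array, (2, 1, 0))


def _from_nifti_order(array: np.ndarray) -> np.ndarray:
    return np.transpose(array, (2, 1, 0))


def write_mask_volume(mask: MaskVolume, path: str | Path) -> Path:
    """Write a MaskVolume as NIfTI; the label map is not embedded (YAML sidecar)."""
    path = Path(path)
    sx, sy, sz = mask.spacing
    affine = np.diag([sy, sx, sz, 1.0])
    img = nib.Nifti1Image(_to_nifti_order(mask.labels).astype(np.int16), affine)
    img.header.set_zooms((sy, sx, sz))
    nib.save(img, str(path))
    return path


def write_label_map(label_map: Mapping[int, tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    payload = {int(k): {"name": v[0], "tissue": v[1]} for k, v in label_map.items()}
    path.write_text(yaml.safe_dump(payload))
    return path


def read_label_map(path: str | Path) -> dict[int, tuple[str, str]]:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"label map {path} must be a mapping of label id -> entry")
    out: dict[int, tuple[str, str]] = {}
    for key, entry in raw.items():
        if isinstance(entry, dict):
            out[int(key)] = (str(entry["name"]), str(entry.get("tissue", "unknown")))
        else:  # allow shorthand {1: femur}
            out[int(key)] = (str(entry), "unknown")
    return out


def read_mask_volume(path: str | Path, label_map_path: str | Path | None = None,
                     label_map: Mapping[int, tuple[str, str]] | None = None) -> MaskVolume:
    """Read a 3D integer NIfTI label volume plus its YAML/JSON label map."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim} in {path}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"volume {path} has non-integer label values")
        data = rounded.astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[1]), float(zooms[0]), float(zooms[2]))  # (sx=row, sy=col, sz)
    if label_map is None:
        if label_map_path is None:
            raise ValueError("a label map (path or mapping) is required")
        label_map = read_label_map(label_map_path)
    return MaskVolume(
        labels=_from_nifti_order(data).astype(np.int32),
        spacing=spacing,
        label_map=dict(label_map),
        affine=np.asarray(img.affine),
    )


def write_parametric_map(pmap: ParametricMap, path: str | Path) -> Path:
    path = Path(path)
    sx, sy, sz = pmap.spacing
    img = nib.Nifti1Image(_to_nifti_order(pmap.values).astype(np.float32),
                          np.diag([sy, sx, sz, 1.0]))
    img.header.set_zooms((sy, sx, sz))
    nib.save(img, str(path))
    return path


def read_parametric_map(path: str | Path, modality: str = "T2") -> ParametricMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D map, got ndim={data.ndim} in {path}")
    zooms = img.header.get_zooms()[:3]
    return ParametricMap(
        values=_from_nifti_order(data),
        spacing=(float(zooms[1]), float(zooms[0]), float(zooms[2])),
        modality=modality,
    )


# ---------------------------------------------------------------------------
# Biomarker tables
# ---------------------------------------------------------------------------

def validate_biomarker_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BIOMARKER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"biomarker table missing columns: {missing}")
    bad_units = set(table["units"]) - VALID_UNITS
    if bad_units:
        raise ValueError(f"unknown units: {sorted(bad_units)}; allowed {sorted(VALID_UNITS)}")
    key = ["subject_id", "visit_month", "compartment", "biomarker"]
    if table.duplicated(subset=key).any():
        dupes = table[table.duplicated(subset=key, keep=False)]
        raise ValueError(f"duplicate (subject, visit, compartment, biomarker) rows:\n{dupes[key]}")
    per_marker = table.groupby("biomarker")["units"].nunique()
    mixed = per_marker[per_marker > 1]
    if len(mixed):
        raise ValueError(f"inconsistent units within biomarker(s): {list(mixed.index)}")
    return table


def write_biomarker_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_biomarker_table(table)
    path = Path(path)
    table.to_csv(path, index=False)  # str(float) round-trips exactly in py3
    return path


def read_biomarker_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_biomarker_table(table)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "io": {
        "cranio_caudal_axis": "row",  # axis carrying superior->inferior in sagittal slices
    },
    "biomarkers": {
        "thickness_mode": "full_width",
        "mode_2d": True,
        "min_skeleton_pixels": 5,
        "relaxometry_clip": [0.0, 100.0],
    },
    "triage": {
        "n_splits": 5,
        "specificity_targets": {"A": 0.90, "B85": 0.85, "B90": 0.90},
        "minutes_per_exam": 2.0,
        "n_boot": 2000,
    },
    "landmark": {
        "landmark_month": 48,
        "horizon_months": 48,
        "n_splits": 5,
        "n_boot_auc": 1000,
        "n_boot_dca": 2000,
        "rf_trees": 400,
        "rf_min_samples_leaf": 10,
    },
    "seeds": {
        "global": 0,
        "cv": 0,
        "learners": 0,
        "bootstrap": 0,
    },
}


def _merge_config(defaults: dict, override: dict, path: str = "") -> dict:
    merged = dict(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {here} must be a mapping")
            merged[key] = _merge_config(defaults[key], value, here)
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate YAML run configuration against the default schema.

    Unknown keys (at any depth) are rejected with their key path; missing
    sections take defaults. Defaulted seeds are logged so runs are auditable.
    """
    override: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("run configuration must be a YAML mapping")
        override = raw
    config = _merge_config(DEFAULT_CONFIG, override)
    if "seeds" not in override:
        logger.info("config: no seeds section; defaults applied: %s", config["seeds"])
    return config


def write_json_summary(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    return path
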