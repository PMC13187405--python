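"""Mask-to-biomarker measurements and reference z-scoring.

The measurement interface: labeled mask volumes (plus optional co-registered
relaxometry maps) become physical-unit biomarkers — medial-axis cartilage
thickness (mm), intervertebral disc heights (mm), tissue volumes (cm^3) and
clipped relaxometry means (ms) — and features are z-scored against a frozen
reference cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .volume_io import MaskVolume, ParametricMap, logger

AXIS_NAMES = {"slice": 0, "row": 1, "col": 2}


# ---------------------------------------------------------------------------
# Cartilage / meniscus thickness via the 2D medial axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThicknessResult:
    compartment: str
    mean_thickness_mm: float
    mode: str  # half_width | full_width
    n_skeleton_samples: int
    samples_per_slice: Mapping[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples_per_slice", dict(self.samples_per_slice))


def compartment_thickness(mask: MaskVolume, label_id: int,
                          mode: str = "full_width",
                          min_skeleton_pixels: int = 5) -> ThicknessResult:
    """Medial-axis thickness of a compartment, pooled over slices.

    Per slice, the binary compartment mask is skeletonized with the 2D medial
    axis; at each skeleton pixel the spacing-aware Euclidean distance to the
    nearest boundary is sampled. ``half_width`` reports the mean boundary
    distance, ``full_width`` twice it (laminar thickness). All skeleton
    samples are pooled across slices, then averaged. Empty or tiny
    compartments yield NaN with a warning.
    """
    if mode not in {"half_width", "full_width"}:
        raise ValueError("mode must be 'half_width' or 'full_width'")
    if label_id not in mask.label_map:
        raise ValueError(f"label {label_id} not in label_map")
    name = mask.label_map[label_id][0]
    binary = mask.labels == label_id
    sx, sy = mask.in_plane_spacing

    samples: list[np.ndarray] = []
    per_slice: dict[int, int] = {}
    for k in range(binary.shape[0]):
        plane = binary[k]
        if not plane.any():
            continue
        skeleton = morphology.medial_axis(plane)
        dist = ndimage.distance_transform_edt(plane, sampling=(sx, sy))
        d = dist[skeleton]
        per_slice[k] = int(d.size)
        samples.append(d)

    total = int(sum(per_slice.values()))
    if total == 0:
        logger.warning("thickness: compartment %r (label %d) is empty", name, label_id)
        return ThicknessResult(name, float("nan"), mode, 0, {})
    if total < min_skeleton_pixels:
        logger.warning(
            "thickness: compartment %r has only %d skeleton pixels (< %d); returning NaN",
            name, total, min_skeleton_pixels,
        )
        return ThicknessResult(name, float("nan"), mode, total, per_slice)

    half = float(np.mean(np.concatenate(samples)))
    value = half if mode == "half_width" else 2.0 * half
    return ThicknessResult(name, value, mode, total, per_slice)


# ---------------------------------------------------------------------------
# Intervertebral disc heights
# ---------------------------------------------------------------------------

def disc_heights(mask: MaskVolume, disc_label: int,
                 cranio_caudal_axis: str = "row") -> list[float]:
    """Per-level disc heights (mm), cranio-caudally ordered.

    Per slice, connected components are disc instances; each instance's
    axis-aligned bounding-box extent along the declared cranio-caudal axis
    times the spacing on that axis is its slice-level height. Instances are
    associated into levels by centroid ordering along the cranio-caudal axis
    (nearest reference centroid), and the level height is the maximum across
    slices. Returns [] when the label is absent.
    """
    if cranio_caudal_axis not in ("row", "col"):
        raise ValueError("cranio_caudal_axis must be 'row' or 'col' within slices")
    cc = 0 if cranio_caudal_axis == "row" else 1
    spacing_cc = mask.in_plane_spacing[cc]
    binary = mask.labels == disc_label

    instances: list[tuple[float, float]] = []  # (centroid along cc, height mm)
    per_slice_counts: list[tuple[int, list[tuple[float, float]]]] = []
    for k in range(binary.shape[0]):
        plane = binary[k]
        if not plane.any():
            continue
        lab = measure.label(plane, connectivity=2)
        here = []
        for region in measure.regionprops(lab):
            lo, hi = region.bbox[cc], region.bbox[cc + 2]
            height = (hi - lo) * spacing_cc
            here.append((float(region.centroid[cc]) * spacing_cc, height))
        per_slice_counts.append((len(here), here))
        instances.extend(here)

    if not instances:
        return []

    n_levels = max(count for count, _ in per_slice_counts)
    ref_slices = [inst for count, inst in per_slice_counts if count == n_levels]
    refs = np.sort(np.mean([sorted(c for c, _ in inst) for inst in ref_slices], axis=0))

    # flag ambiguity: reference centroids closer than the largest instance height
    max_h = max(h for _, h in instances)
    if n_levels > 1 and np.min(np.diff(refs)) < max_h:
        logger.warning("disc levels have overlapping centroid ranges; "
                       "using nearest-centroid assignment")

    heights = [0.0] * n_levels
    for centroid, height in instances:
        level = int(np.argmin(np.abs(refs - centroid)))
        heights[level] = max(heights[level], height)
    return heights


# ---------------------------------------------------------------------------
# Tissue volume and relaxometry
# ---------------------------------------------------------------------------

def tissue_volume(mask: MaskVolume, label_id: int) -> float:
    """Voxel count x voxel volume, in cm^3. Empty compartments give 0.0."""
    if label_id not in mask.label_map:
        raise ValueError(f"label {label_id} not in label_map")
    count = int(np.count_nonzero(mask.labels == label_id))
    return count * mask.voxel_volume_mm3 / 1000.0


def relaxometry_mean(pmap: ParametricMap, mask: MaskVolume, label_id: int,
                     clip: tuple[float, float] = (0.0, 100.0)) -> float:
    """Mean relaxation time (ms) over a compartment after clipping.

    Voxels inside the compartment are clipped to ``clip`` ms and pooled
    across all slices (whole-compartment voxel mean).
    """
    pmap.check_paired(mask)
    inside = mask.labels == label_id
    if not inside.any():
        logger.warning("relaxometry: compartment label %d is empty", label_id)
        return float("nan")
    values = np.clip(pmap.values[inside], clip[0], clip[1])
    return float(values.mean())


# ---------------------------------------------------------------------------
# Reference statistics and z-scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceStats:
    """Per-feature mean/SD frozen from a designated reference cohort.

    Computed once globally (never per CV fold) so every downstream model sees
    the same standardization.
    """

    stats: Mapping[str, tuple[float, float, int]]  # feature -> (mean, sd, n)
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stats", MappingProxyType(dict(self.stats)))

    @property
    def features(self) -> list[str]:
        return list(self.stats)


def fit_reference(table: pd.DataFrame, features: Sequence[str],
                  reference_mask: np.ndarray | pd.Series,
                  provenance: str = "") -> ReferenceStats:
    """Freeze per-feature mean and sample SD over the reference subset."""
    ref = table.loc[np.asarray(reference_mask, dtype=bool), list(features)]
    if len(ref) < 3:
        raise ValueError(f"reference subset too small: {len(ref)} rows (< 3)")
    stats: dict[str, tuple[float, float, int]] = {}
    for feat in features:
        x = ref[feat].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValueError(f"reference SD is zero for feature {feat!r}")
        stats[feat] = (mu, sd, len(x))
    return ReferenceStats(stats=stats, provenance=provenance)


def zscore(table: pd.DataFrame, reference: ReferenceStats) -> pd.DataFrame:
    """z = (x - mu_ref) / sd_ref for every reference feature (copy returned)."""
    out = table.copy()
    for feat, (mu, sd, _) in reference.stats.items():
        out[feat] = (out[feat] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# Longitudinal annual change
# ---------------------------------------------------------------------------

def annual_changes(visits: pd.DataFrame, value_col: str = "thickness_mm",
                   id_cols: Sequence[str] = ("knee_id", "compartment")) -> pd.DataFrame:
    """Annualized change between consecutive available visits.

    For each series (default: knee x compartment), change over each
    consecutive-visit interval is ``(v_t - v_{t-1}) / dt_years``, reported at
    the interval's end month.
    """
    frames = []
    for keys, grp in visits.groupby(list(id_cols)):
        grp = grp.sort_values("visit_month")
        months = grp["visit_month"].to_numpy(dtype=float)
        vals = grp[value_col].to_numpy(dtype=float)
        if len(grp) < 2:
            continue
        dt_years = np.diff(months) / 12.0
        rate = np.diff(vals) / dt_years
        frame = pd.DataFrame({
            "visit_month": months[1:].astype(int),
            "annual_change": rate,
        })
        for col, key in zip(id_cols, keys if isinstance(keys, tuple) else (keys,)):
            frame[col] = key
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=[*id_cols, "visit_month", "annual_change"])
    return pd.concat(frames, ignore_index=True)[[*id_cols, "visit_month", "annual_change"]]
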