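"""Standardized refinement of predicted masks before measurement.

Pipeline: logits -> sigmoid threshold -> small-component removal -> one
morphological closing pass -> optional light (3x3 median) boundary smoothing.
Refinement runs per slice by default, matching slice-wise prediction; a 3D
mode operates on the whole volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit
from skimage import morphology


@dataclass(frozen=True)
class RefineConfig:
    threshold: float = 0.5
    min_component_voxels: int = 10
    closing_radius_px: int = 1
    smoothing: str = "none"  # none | median3
    connectivity_2d: int = 8  # 4 or 8
    connectivity_3d: int = 26  # 6 or 26
    mode_2d: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.min_component_voxels < 0 or self.closing_radius_px < 0:
            raise ValueError("component size and closing radius must be >= 0")
        if self.smoothing not in {"none", "median3"}:
            raise ValueError("smoothing must be 'none' or 'median3'")
        if self.connectivity_2d not in (4, 8) or self.connectivity_3d not in (6, 26):
            raise ValueError("connectivity must be 4/8 (2D) or 6/26 (3D)")


def binarize_logits(logits: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """``sigmoid(logit) >= threshold``; logit 0 at threshold 0.5 is included."""
    logits = np.asarray(logits, dtype=float)
    if np.isnan(logits).any():
        raise ValueError("logits contain NaN")
    return expit(logits) >= threshold


def _skimage_connectivity(conn: int) -> int:
    # map 4/8 (2D) and 6/26 (3D) neighbourhoods to skimage's rank convention
    return {4: 1, 8: 2, 6: 1, 26: 3}[conn]


def _refine_plane(mask: np.ndarray, config: RefineConfig, selem) -> np.ndarray:
    conn = _skimage_connectivity(config.connectivity_2d if mask.ndim == 2
                                 else config.connectivity_3d)
    out = mask.astype(bool)
    if config.min_component_voxels > 0:
        # components strictly below the size floor are removed
        out = morphology.remove_small_objects(
            out, max_size=config.min_component_voxels - 1, connectivity=conn
        )
    if config.closing_radius_px > 0:
        out = morphology.closing(out, selem)
    if config.smoothing == "median3":
        out = ndimage.median_filter(out.astype(np.uint8), size=3).astype(bool)
    return out


def refine_prediction(mask: np.ndarray, config: RefineConfig | None = None) -> np.ndarray:
    """Refine a binary mask (2D slice or 3D volume). Empty in -> empty out.

    With ``min_component_voxels=0``, ``closing_radius_px=0`` and
    ``smoothing='none'`` this is the identity.
    """
    config = config or RefineConfig()
    mask = np.asarray(mask).astype(bool)
    if mask.ndim == 2:
        selem = morphology.disk(config.closing_radius_px) if config.closing_radius_px else None
        return _refine_plane(mask, config, selem)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 2D or 3D, got ndim={mask.ndim}")
    if config.mode_2d:
        selem = morphology.disk(config.closing_radius_px) if config.closing_radius_px else None
        return np.stack([_refine_plane(sl, config, selem) for sl in mask])
    selem = morphology.ball(config.closing_radius_px) if config.closing_radius_px else None
    return _refine_plane(mask, config, selem)
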