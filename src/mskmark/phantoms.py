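"""Synthetic phantoms and cohorts with analytically known ground truth.

Three generators cover the downstream measurement, triage and landmark layers:

* geometric label phantoms (slab, annulus, ellipsoid, disc stack) rasterized
  by center-of-voxel inclusion, with analytic thickness / height / volume;
* a cross-sectional knee cohort with six z-scorable biomarkers (cartilage
  thickness and bone volume for femur, tibia, patella), sex/age/weight and
  hierarchical normal/abnormal labels;
* a longitudinal knee cohort with visits at 0/12/24/36/48 months, linear
  thickness trajectories and event times drawn from a piecewise-constant
  hazard whose log intensity rises with cumulative thickness loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import MaskVolume, logger

TRIAGE_BIOMARKERS = (
    "femur_cartilage_thickness",
    "tibia_cartilage_thickness",
    "patella_cartilage_thickness",
    "femur_bone_volume",
    "tibia_bone_volume",
    "patella_bone_volume",
)

TRIAGE_CLASSES = ("normal", "cart_only", "bone_only", "both")

JOINTS = ("femur", "tibia", "patella")

LANDMARK_COMPARTMENTS = ("femur", "tibia_lat", "tibia_med", "patella")

VISIT_MONTHS = (0, 12, 24, 36, 48)


# ---------------------------------------------------------------------------
# Geometric phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic label phantom. All lengths in mm."""

    shape_kind: str  # slab | annulus | ellipsoid | disc_stack
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    label_id: int = 1
    rng_seed: int = 0
    # slab
    slab_width: float | None = None
    slab_length: float | None = None
    # annulus
    inner_radius: float | None = None
    outer_radius: float | None = None
    # ellipsoid
    semi_axes: tuple[float, float, float] | None = None
    # disc stack
    disc_height: float | None = None
    disc_width: float | None = None
    disc_count: int | None = None
    disc_gap: float | None = None
    n_slices: int = 5

    def __post_init__(self) -> None:
        if self.shape_kind not in {"slab", "annulus", "ellipsoid", "disc_stack"}:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")
        params = {
            "slab": [self.slab_width],
            "annulus": [self.inner_radius, self.outer_radius],
            "ellipsoid": list(self.semi_axes or [None]),
            "disc_stack": [self.disc_height, self.disc_width, self.disc_count],
        }[self.shape_kind]
        if any(p is None for p in params):
            raise ValueError(f"missing geometry parameters for {self.shape_kind}")
        if any(float(p) <= 0 for p in params):
            raise ValueError("geometry parameters must be strictly positive")
        if self.shape_kind == "annulus" and self.outer_radius <= self.inner_radius:
            raise ValueError("outer_radius must exceed inner_radius")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic measurements carried alongside a rasterized phantom."""

    thickness_mm: float | None = None
    volume_cm3: float | None = None
    heights_mm: tuple[float, ...] | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _centers(extent_mm: float, spacing: float, margin_vox: int = 2) -> np.ndarray:
    """Voxel-center coordinates covering [0, extent) plus a background margin."""
    n = int(math.ceil(extent_mm / spacing)) + 2 * margin_vox
    return (np.arange(n) + 0.5) * spacing - margin_vox * spacing


def make_phantom(spec: PhantomSpec) -> tuple[MaskVolume, GroundTruth]:
    """Rasterize a phantom by center-of-voxel inclusion against its implicit surface.

    Raises ``ValueError("degenerate phantom: ...")`` when the geometry is
    smaller than one voxel along a defining direction.
    """
    sx, sy, sz = spec.spacing
    kind = spec.shape_kind
    lid = spec.label_id

    if kind == "slab":
        w = float(spec.slab_width)
        if w < sx:
            raise ValueError("degenerate phantom: slab thinner than one voxel")
        # the analytic slab is unbounded along its length: the raster spans
        # the full array there, so the skeleton has no end-branches
        length = float(spec.slab_length or max(4 * w, 20 * sy))
        n_cols = max(int(round(length / sy)), 4)
        rows = _centers(w, sx)
        inside2d = np.repeat(((rows >= 0) & (rows < w))[:, None], n_cols, axis=1)
        mask = np.repeat(inside2d[None, :, :], spec.n_slices, axis=0)
        truth = GroundTruth(thickness_mm=w,
                            volume_cm3=w * n_cols * sy * spec.n_slices * sz / 1000.0)

    elif kind == "annulus":
        rin, rout = float(spec.inner_radius), float(spec.outer_radius)
        if rout - rin < min(sx, sy):
            raise ValueError("degenerate phantom: annulus thinner than one voxel")
        rows = _centers(2 * rout, sx) - rout
        cols = _centers(2 * rout, sy) - rout
        rho = np.hypot(rows[:, None], cols[None, :])
        inside2d = (rho >= rin) & (rho < rout)
        mask = np.repeat(inside2d[None, :, :], spec.n_slices, axis=0)
        truth = GroundTruth(
            thickness_mm=rout - rin,
            volume_cm3=math.pi * (rout**2 - rin**2) * spec.n_slices * sz / 1000.0,
        )

    elif kind == "ellipsoid":
        a, b, c = (float(v) for v in spec.semi_axes)
        if 2 * min(a, b, c) < min(spec.spacing):
            raise ValueError("degenerate phantom: ellipsoid smaller than one voxel")
        # semi-axes a,b,c along (row, col, slice)
        rows = _centers(2 * a, sx) - a
        cols = _centers(2 * b, sy) - b
        slcs = _centers(2 * c, sz) - c
        q = (
            (slcs[:, None, None] / c) ** 2
            + (rows[None, :, None] / a) ** 2
            + (cols[None, None, :] / b) ** 2
        )
        mask = q <= 1.0
        truth = GroundTruth(volume_cm3=4.0 / 3.0 * math.pi * a * b * c / 1000.0)

    else:  # disc_stack
        h, w = float(spec.disc_height), float(spec.disc_width)
        count = int(spec.disc_count)
        gap = float(spec.disc_gap if spec.disc_gap is not None else h)
        if h < sx or w < sy:
            raise ValueError("degenerate phantom: disc smaller than one voxel")
        total = count * h + (count - 1) * gap
        rows = _centers(total, sx)
        cols = _centers(w, sy)
        inside2d = np.zeros((rows.size, cols.size), dtype=bool)
        col_in = (cols >= 0) & (cols < w)
        for k in range(count):
            r0 = k * (h + gap)
            row_in = (rows >= r0) & (rows < r0 + h)
            inside2d |= row_in[:, None] & col_in[None, :]
        mask = np.repeat(inside2d[None, :, :], spec.n_slices, axis=0)
        truth = GroundTruth(heights_mm=tuple([h] * count))

    if not mask.any():
        raise ValueError("degenerate phantom: rasterization is empty")

    volume = MaskVolume(
        labels=mask.astype(np.int32) * lid,
        spacing=spec.spacing,
        label_map={lid: (f"{kind} phantom", "phantom")},
    )
    return volume, truth


def make_parametric_phantom(mask: MaskVolume, value_ms: float = 42.0):
    """Constant relaxometry map over the phantom grid (ms)."""
    from .volume_io import ParametricMap

    values = np.full(mask.labels.shape, value_ms, dtype=float)
    return ParametricMap(values=values, spacing=mask.spacing, modality="T2")


# ---------------------------------------------------------------------------
# Cross-sectional triage cohort
# ---------------------------------------------------------------------------

def default_class_shifts() -> dict[str, dict[str, float]]:
    """Mean shifts (reference-SD units) per abnormality class.

    Cartilage classes thin cartilage (negative thickness shift); bone classes
    inflate bone volume (positive shift), emulating osteophytic change.
    """
    cart = {f"{j}_cartilage_thickness": -1.5 for j in JOINTS}
    bone = {f"{j}_bone_volume": 1.2 for j in JOINTS}
    return {
        "normal": {},
        "cart_only": dict(cart),
        "bone_only": dict(bone),
        "both": {**cart, **bone},
    }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cross-sectional knee cohort: six biomarkers + demographics + labels."""

    n_subjects: int = 930
    class_prevalences: tuple[float, float, float, float] = (0.55, 0.20, 0.10, 0.15)
    class_shifts: dict = field(default_factory=default_class_shifts)
    noise_sd: float = 1.0
    sex_p_female: float = 0.5
    age_mean: float = 51.0
    age_sd: float = 17.0
    weight_mean: float = 78.0
    weight_sd: float = 18.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_prevalences) - 1.0) > 1e-9:
            raise ValueError("class prevalences must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be > 0")
        unknown = set(self.class_shifts) - set(TRIAGE_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_shifts: {sorted(unknown)}")


def make_triage_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Generate a knee cohort with hierarchical normal/abnormal labels.

    Biomarkers are drawn on an arbitrary raw scale (unit SD around per-class
    means); the six shifted means are exactly the spec's shifts in SD units,
    so class-conditional sample means recover them up to Monte-Carlo error.
    A joint is labelled abnormal for a tissue when its biomarker for that
    tissue is mean-shifted in the subject's class, so any abnormal joint
    implies an abnormal knee.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_subjects
    prev = np.asarray(spec.class_prevalences, dtype=float)
    expected = prev * n
    for cls, cnt in zip(TRIAGE_CLASSES, expected):
        if 0 < cnt < 2:
            logger.warning("triage cohort: expected count %.1f < 2 for class %s", cnt, cls)

    classes = rng.choice(len(TRIAGE_CLASSES), size=n, p=prev)
    data = {
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "class": [TRIAGE_CLASSES[c] for c in classes],
        "sex": rng.binomial(1, spec.sex_p_female, size=n),
        "age": rng.normal(spec.age_mean, spec.age_sd, size=n),
        "weight": rng.normal(spec.weight_mean, spec.weight_sd, size=n),
    }

    shift_matrix = np.zeros((n, len(TRIAGE_BIOMARKERS)))
    for i, c in enumerate(classes):
        for marker, shift in spec.class_shifts.get(TRIAGE_CLASSES[c], {}).items():
            shift_matrix[i, TRIAGE_BIOMARKERS.index(marker)] = shift
    values = shift_matrix + rng.normal(0.0, spec.noise_sd, size=shift_matrix.shape)
    for j, marker in enumerate(TRIAGE_BIOMARKERS):
        data[marker] = values[:, j]

    df = pd.DataFrame(data)
    for joint in JOINTS:
        cart_shifted = np.array([
            spec.class_shifts.get(cls, {}).get(f"{joint}_cartilage_thickness", 0.0) != 0
            for cls in df["class"]
        ])
        bone_shifted = np.array([
            spec.class_shifts.get(cls, {}).get(f"{joint}_bone_volume", 0.0) != 0
            for cls in df["class"]
        ])
        df[f"{joint}_cart_label"] = cart_shifted.astype(int)
        df[f"{joint}_bone_label"] = bone_shifted.astype(int)
        df[f"{joint}_abnormal"] = (cart_shifted | bone_shifted).astype(int)
    df["knee_abnormal"] = df[[f"{j}_abnormal" for j in JOINTS]].max(axis=1)
    return df


# ---------------------------------------------------------------------------
# Longitudinal landmark cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LongitudinalCohortSpec:
    """Longitudinal knee cohort: thickness trajectories plus event times.

    The hazard of the endpoint (e.g. joint replacement) is piecewise constant
    between visits: on each interval it equals
    ``baseline_hazard * exp(hazard_coef * cumulative_loss_mm)`` where
    cumulative loss is the total thickness lost across compartments since
    baseline, extrapolated linearly past the last visit. ``hazard_coef = 0``
    decouples events from trajectories.
    """

    n_knees: int = 1000
    knees_per_participant: int = 1  # 1 or 2
    baseline_mean_mm: float = 2.2
    baseline_sd_mm: float = 0.25
    slope_mean_mm_per_yr: float = -0.06
    slope_sd_mm_per_yr: float = 0.12
    baseline_hazard_per_month: float = 0.0005
    hazard_coef_per_mm_lost: float = 1.5
    censor_month: float = 96.0
    missing_visit_prob: float = 0.0
    kl_probs: tuple[float, ...] = (0.40, 0.25, 0.20, 0.10, 0.05)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.knees_per_participant not in (1, 2):
            raise ValueError("knees_per_participant must be 1 or 2")
        if self.baseline_hazard_per_month <= 0:
            raise ValueError("baseline hazard must be > 0")
        if not 0 <= self.missing_visit_prob < 1:
            raise ValueError("missing_visit_prob must be in [0, 1)")
        if abs(sum(self.kl_probs) - 1.0) > 1e-9:
            raise ValueError("KL grade probabilities must sum to 1")


@dataclass(frozen=True)
class LandmarkCohortData:
    """Long visit table plus per-knee event/demographic table."""

    visits: pd.DataFrame  # knee_id, participant_id, visit_month, compartment, thickness_mm
    knees: pd.DataFrame   # knee_id, participant_id, event_time, event, censor_time, kl, age, sex, bmi


def _event_time_piecewise(breaks: np.ndarray, hazards: np.ndarray, u: float) -> float:
    """Inverse-transform sample from a piecewise-constant hazard.

    ``breaks`` are interval starts (last interval open-ended); ``hazards``
    the per-month rate on each interval.
    """
    target = -math.log(u)
    cum = 0.0
    for i, start in enumerate(breaks):
        end = breaks[i + 1] if i + 1 < len(breaks) else math.inf
        lam = hazards[i]
        seg = lam * (end - start)
        if cum + seg >= target:
            return start + (target - cum) / lam
        cum += seg
    return math.inf


def make_landmark_cohort(spec: LongitudinalCohortSpec) -> LandmarkCohortData:
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_knees
    kpp = spec.knees_per_participant
    participant_ids = np.repeat(np.arange(math.ceil(n / kpp)), kpp)[:n]

    comps = LANDMARK_COMPARTMENTS
    baselines = rng.normal(spec.baseline_mean_mm, spec.baseline_sd_mm, size=(n, len(comps)))
    slopes = rng.normal(spec.slope_mean_mm_per_yr, spec.slope_sd_mm_per_yr, size=(n, len(comps)))

    months = np.asarray(VISIT_MONTHS, dtype=float)
    # thickness trajectories, floored at zero (cartilage cannot be negative)
    traj = np.clip(
        baselines[:, :, None] + slopes[:, :, None] * (months[None, None, :] / 12.0), 0.0, None
    )

    # per-knee piecewise-constant hazard: intervals between visits, then open-ended
    breaks = months
    event_times = np.empty(n)
    u = rng.uniform(size=n)
    for i in range(n):
        loss_at_break = np.maximum(baselines[i][:, None] - traj[i], 0.0).sum(axis=0)
        hazards = spec.baseline_hazard_per_month * np.exp(
            spec.hazard_coef_per_mm_lost * loss_at_break
        )
        event_times[i] = _event_time_piecewise(breaks, hazards, u[i])

    event = event_times <= spec.censor_month
    obs_time = np.where(event, event_times, spec.censor_month)

    n_participants = participant_ids.max() + 1
    age_p = rng.normal(61.0, 9.0, size=n_participants)
    sex_p = rng.binomial(1, 0.58, size=n_participants)
    bmi_p = rng.normal(28.5, 4.8, size=n_participants)
    kl = rng.choice(len(spec.kl_probs), size=n, p=np.asarray(spec.kl_probs))

    knees = pd.DataFrame({
        "knee_id": [f"K{i:05d}" for i in range(n)],
        "participant_id": [f"P{p:05d}" for p in participant_ids],
        "event_time": obs_time,
        "event": event.astype(int),
        "censor_time": spec.censor_month,
        "kl": kl,
        "age": age_p[participant_ids],
        "sex": sex_p[participant_ids],
        "bmi": bmi_p[participant_ids],
    })

    rows = []
    for i in range(n):
        for vj, month in enumerate(VISIT_MONTHS):
            if month != 0 and rng.uniform() < spec.missing_visit_prob:
                continue
            for cj, comp in enumerate(comps):
                rows.append((f"K{i:05d}", f"P{participant_ids[i]:05d}",
                             month, comp, traj[i, cj, vj]))
    visits = pd.DataFrame(
        rows, columns=["knee_id", "participant_id", "visit_month", "compartment", "thickness_mm"]
    )
    return LandmarkCohortData(visits=visits, knees=knees)
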