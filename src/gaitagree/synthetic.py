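"""Synthetic sagittal-plane gait cohorts with a controlled error structure.

Generates marker trajectories, vertical ground-reaction-force signals and
long-format joint-angle tables for a reliability study design: ``n`` subjects
each recorded in two sessions (markers re-placed between sessions), five
repetitions per session, two observers digitising the same videos, and two
measurement systems (a lateral 2D video system and an emulated 3D reference).

The generator is built so that every downstream quantity has a known ground
truth:

* Each subject draws true initial-contact (IC) angles for hip, knee and ankle
  from the population distribution; smooth two-harmonic gait curves are
  anchored to pass *exactly* through those targets at the IC phase.
* A planar three-segment linkage (pelvis-thigh-shank-foot) converts the
  curves into 3D marker positions in the sagittal plane, which the angle
  constructions in :mod:`gaitagree.kinematics` invert exactly in the
  noise-free, orthographic case.
* Measurement error enters mechanistically: marker re-placement offsets
  (metres, redrawn per session, frozen within a session), observer
  frame-selection error (integer frames), observer digitisation jitter
  (pixels), stride-to-stride variation of the true angles (degrees), and a
  per-joint systematic offset of the video system relative to the 3D
  reference (degrees).

With every standard deviation and bias set to zero, measurements equal the
ground truth bit-for-bit under orthographic projection; perspective
projection additionally reproduces the small view-angle distortion of a real
elevated lateral camera.

Coordinates: ``x`` = direction of progression, ``y`` = up, the sagittal plane
is ``z = 0``. Angle sign conventions match :mod:`gaitagree.kinematics`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinematics import (
    MARKER_NAMES,
    ForceSignal,
    MarkerFrame,
    ankle_angle,
    hip_angle,
    knee_angle,
)

__all__ = [
    "JOINTS",
    "POPULATION_IC_MEANS",
    "POPULATION_IC_SDS",
    "SegmentModel",
    "GaitAngleProfile",
    "CameraModel",
    "ErrorModel",
    "CohortConfig",
    "Subject",
    "TrialDataset",
    "substream",
    "sample_subject",
    "mean_subject",
    "pose_leg",
    "sagittal_view",
    "project_markers",
    "synth_grf",
    "simulate_trial",
    "simulate_cohort",
    "aggregate_repetitions",
    "implied_error_variances",
    "implied_icc",
]

logger = logging.getLogger(__name__)

JOINTS = ("hip", "knee", "ankle")

#: Population means / SDs of the IC angles (degrees) the generator draws from,
#: matching the magnitudes observed with 2D video goniometry in healthy adults
#: (hip flexed ~33 deg, knee slightly flexed, ankle slightly plantar flexed).
POPULATION_IC_MEANS = {"hip": 33.06, "knee": 4.55, "ankle": -7.77}
POPULATION_IC_SDS = {"hip": 5.7, "knee": 3.8, "ankle": 3.7}

#: Cohort anthropometry (healthy young adults): mean +/- SD, and the
#: plausibility range outside which a draw is rejected and resampled.
HEIGHT_MEAN_M, HEIGHT_SD_M = 1.6749, 0.2557
HEIGHT_RANGE_M = (1.40, 2.05)
MASS_MEAN_KG, MASS_SD_KG = 65.74, 12.94
MASS_RANGE_KG = (40.0, 120.0)

GRAVITY = 9.81

# Segment lengths as fractions of stature (standard anthropometric tables).
_THIGH_FRAC = 0.245
_SHANK_FRAC = 0.246
_FOOT_FRAC = 0.152
_PELVIS_DEPTH_FRAC = 0.100

_SEGMENT_OF_MARKER = {
    "ASIS": "pelvis", "PSIS": "pelvis", "GT": "pelvis",
    "THI": "thigh", "LFC": "thigh",
    "TIB": "shank", "LM": "shank",
    "CAL": "foot", "MT2": "foot",
}


class GaitSimulationError(ValueError):
    """Raised for invalid generator configuration or non-physiological poses."""


def _rot(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s], [s, c]])


def _rot90_ccw(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic child RNG for a hierarchical key path.

    Streams are independent across key paths and do not shift when the cohort
    grows (adding subjects never perturbs existing subjects' draws).
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in keys)))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentModel:
    """Planar segment lengths (m) and marker placements for one subject.

    ``heel_offset``/``toe_offset`` are the calcaneus / second-metatarsal-head
    positions in the foot's local frame relative to the ankle joint (local x
    points along the foot line, so both offsets share the same local y).
    ``marker_offsets`` are nominal per-marker placement deviations from the
    anatomical landmark, expressed in the carrying segment's local frame.
    """

    pelvis_depth: float = 0.1675
    thigh_length: float = 0.4104
    shank_length: float = 0.4120
    heel_offset: tuple[float, float] = (-0.0637, -0.060)
    toe_offset: tuple[float, float] = (0.1910, -0.060)
    pelvis_drop: float = 0.080  # GT below the mid ASIS-PSIS point
    marker_offsets: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pelvis_depth", "thigh_length", "shank_length", "pelvis_drop"):
            if getattr(self, name) <= 0:
                raise GaitSimulationError(f"{name} must be positive")
        if not math.isclose(self.heel_offset[1], self.toe_offset[1], abs_tol=1e-12):
            raise GaitSimulationError("heel and toe offsets must share the same local height (foot line = local x axis)")
        if self.toe_offset[0] <= self.heel_offset[0]:
            raise GaitSimulationError("toe marker must lie anterior to the heel marker")
        for m, off in self.marker_offsets.items():
            if np.hypot(*off) >= 0.05:
                raise GaitSimulationError(f"marker offset for {m!r} exceeds the 0.05 m bound")

    @property
    def foot_length(self) -> float:
        return self.toe_offset[0] - self.heel_offset[0]


# Two-harmonic base shapes (a1, b1, a2, b2) in degrees for
# a1*cos(2 pi t) + b1*sin(2 pi t) + a2*cos(4 pi t) + b2*sin(4 pi t),
# least-squares fitted to textbook normal sagittal gait curves (hip near peak
# flexion at IC, knee extending into IC then flexing through swing, ankle
# moving briefly into plantar flexion after heel strike). Only the shape
# matters: the constant term is re-anchored to each subject's IC targets.
_BASE_HARMONICS = {
    "hip": (20.356, -3.666, -2.020, -1.901),
    "knee": (-2.197, -18.540, -15.645, 7.640),
    "ankle": (-0.843, 6.907, 1.197, -7.860),
    "pelvic_tilt": (1.0, 0.8, 0.5, 0.3),
}


def _harmonic(coeffs: tuple[float, float, float, float], t) -> np.ndarray | float:
    a1, b1, a2, b2 = coeffs
    w = 2.0 * np.pi * np.asarray(t, dtype=float)
    return a1 * np.cos(w) + b1 * np.sin(w) + a2 * np.cos(2 * w) + b2 * np.sin(2 * w)


def _harmonic_slope(coeffs: tuple[float, float, float, float], t) -> np.ndarray | float:
    a1, b1, a2, b2 = coeffs
    w = 2.0 * np.pi * np.asarray(t, dtype=float)
    return 2 * np.pi * (-a1 * np.sin(w) + b1 * np.cos(w)) + 4 * np.pi * (-a2 * np.sin(2 * w) + b2 * np.cos(2 * w))


@dataclass(frozen=True)
class GaitAngleProfile:
    """Smooth periodic joint-angle curves anchored to the subject's IC targets.

    Each curve is the sum of two harmonics plus a constant chosen so that the
    curve passes exactly through the drawn IC target at phase ``t_ic``; curves
    are therefore continuous, periodic and analytically differentiable (used
    for the frame-shift sensitivity bookkeeping).
    """

    ic_targets: Mapping[str, float]
    pelvic_tilt_ic: float = 5.0
    t_ic: float = 0.0
    cycle_duration_s: float = 1.1
    stride_length_m: float = 1.30
    heel_clearance_max_m: float = 0.20
    ground_clearance_m: float = 0.02
    harmonics: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_BASE_HARMONICS)
    )

    def __post_init__(self) -> None:
        missing = [j for j in JOINTS if j not in self.ic_targets]
        if missing:
            raise GaitSimulationError(f"ic_targets missing joints: {missing}")
        if not 0.0 <= self.t_ic < 1.0:
            raise GaitSimulationError("t_ic must lie in [0, 1)")
        if self.cycle_duration_s <= 0:
            raise GaitSimulationError("cycle duration must be positive")

    def angle(self, joint: str, t) -> np.ndarray | float:
        """Joint angle (deg) at normalised gait-cycle phase ``t`` (periodic)."""
        coeffs = self.harmonics[joint]
        target = self.pelvic_tilt_ic if joint == "pelvic_tilt" else self.ic_targets[joint]
        return target + _harmonic(coeffs, t) - _harmonic(coeffs, self.t_ic)

    def slope(self, joint: str, t) -> np.ndarray | float:
        """d(angle)/d(phase) in degrees per gait cycle."""
        return _harmonic_slope(self.harmonics[joint], t)

    def slope_deg_per_s(self, joint: str, t) -> float:
        return float(self.slope(joint, t)) / self.cycle_duration_s

    def heel_clearance(self, t) -> np.ndarray | float:
        """Height of the heel marker above its ground clearance, metres.

        A smooth periodic bump with its minimum (zero) exactly at the
        initial-contact phase: the heel is on the ground at heel strike and
        rises through swing. The pelvis height is derived from this ground
        constraint, so heel-strike is by construction the local minimum of
        the heel track, as in real gait.
        """
        w = 2.0 * np.pi * (np.asarray(t, dtype=float) - self.t_ic)
        return self.heel_clearance_max_m * 0.5 * (1.0 - np.cos(w))

    def hip(self, t):
        return self.angle("hip", t)

    def knee(self, t):
        return self.angle("knee", t)

    def ankle(self, t):
        return self.angle("ankle", t)

    def pelvic_tilt(self, t):
        return self.angle("pelvic_tilt", t)


@dataclass(frozen=True)
class CameraModel:
    """Lateral video camera: pinhole perspective or orthographic projection.

    The optical axis is horizontal and perpendicular to the sagittal plane
    (``z = 0``); the camera sits at ``(x_position, height, lateral_distance)``
    looking in -z. Pixel coordinates use y-up with the principal point at the
    image centre. In ``orthographic`` mode points are scaled by
    ``focal_length_px / lateral_distance`` so the two modes agree on the
    sagittal plane and perspective converges to orthographic as the camera
    recedes.
    """

    lateral_distance: float = 2.5
    height: float = 1.0
    fps: float = 50.0
    resolution: tuple[int, int] = (1280, 720)
    focal_length_px: float = 1000.0
    projection_mode: str = "perspective"
    x_position: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise GaitSimulationError("fps must be positive")
        if self.lateral_distance <= 0:
            raise GaitSimulationError("lateral_distance must be positive")
        if self.projection_mode not in ("perspective", "orthographic"):
            raise GaitSimulationError("projection_mode must be 'perspective' or 'orthographic'")

    @property
    def principal_point(self) -> tuple[float, float]:
        return (self.resolution[0] / 2.0, self.resolution[1] / 2.0)

    @property
    def scale_px_per_m(self) -> float:
        """In-plane pixel scale at the sagittal plane."""
        return self.focal_length_px / self.lateral_distance


def project_markers(points3d, cam: CameraModel):
    """Project 3D world points to 2D pixel coordinates (y-up).

    Accepts an ``(N, 3)`` array or a mapping of marker name to ``(3,)`` point
    and returns the matching ``(N, 2)`` array or mapping. Perspective mode
    applies the pinhole division by depth; points at or behind the camera
    plane raise an error.
    """
    if isinstance(points3d, Mapping):
        names = list(points3d)
        arr = np.asarray([points3d[n] for n in names], dtype=float)
        out = project_markers(arr, cam)
        return {n: out[i] for i, n in enumerate(names)}
    pts = np.atleast_2d(np.asarray(points3d, dtype=float))
    if pts.shape[1] != 3:
        raise GaitSimulationError("points must have shape (N, 3)")
    u0, v0 = cam.principal_point
    x = pts[:, 0] - cam.x_position
    y = pts[:, 1] - cam.height
    if cam.projection_mode == "orthographic":
        s = cam.scale_px_per_m
        uv = np.column_stack([u0 + s * x, v0 + s * y])
    else:
        depth = cam.lateral_distance - pts[:, 2]
        if np.any(depth <= 1e-9):
            raise GaitSimulationError("point at or behind the camera plane")
        uv = np.column_stack([u0 + cam.focal_length_px * x / depth,
                              v0 + cam.focal_length_px * y / depth])
    return uv if np.asarray(points3d).ndim == 2 else uv[0]


def _broadcast_per_joint(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {j: float(value.get(j, 0.0)) for j in JOINTS}
    else:
        out = {j: float(value) for j in JOINTS}
    return out


@dataclass(frozen=True)
class ErrorModel:
    """Variance components and biases of the simulated measurement chain.

    All SDs are non-negative; with every SD and bias at zero (``zero()``)
    measurements reproduce the ground truth exactly (under orthographic
    projection, which has no view-angle distortion).

    Defaults are calibrated so that a default cohort yields intra-rater ICCs
    around the high 0.8s, inter-rater ICCs above 0.95, and video-vs-reference
    biases of about +0.8 deg (hip), +2.0 deg (knee) and -1.3 deg (ankle).
    """

    #: Between-subject SD of true IC angles, degrees (per joint or scalar).
    sd_subject: Mapping[str, float] | float = field(default_factory=lambda: dict(POPULATION_IC_SDS))
    #: Marker re-placement SD, metres; redrawn each session, frozen within it.
    sd_session_m: float = 0.003
    #: Observer frame-selection SD, frames (rounded to integers).
    sd_observer_frame: float = 1.0
    #: Observer marker-click jitter SD, pixels, per coordinate.
    sd_digitize_px: float = 1.2
    #: Additive offset of the video system relative to the 3D reference, deg.
    #: Under the default elevated perspective camera the video chain itself
    #: contributes a further systematic view-angle distortion (about +0.5 deg
    #: on the knee), so these defaults are calibrated so that the *total*
    #: video-minus-reference bias of a default cohort is about +0.8 (hip),
    #: +2.0 (knee) and -1.3 (ankle) degrees.
    system_bias_deg: Mapping[str, float] | float = field(
        default_factory=lambda: {"hip": 0.87, "knee": 1.54, "ankle": -1.18}
    )
    #: Stride-to-stride SD of the true IC angles, degrees (per trial).
    sd_residual_deg: float = 1.5
    #: Measurement noise of the emulated 3D reference system, degrees.
    sd_reference_deg: float = 0.5
    #: Force-plate noise, Newtons.
    sd_force_n: float = 2.0

    def __post_init__(self) -> None:
        subj = _broadcast_per_joint(self.sd_subject, "sd_subject")
        bias = _broadcast_per_joint(self.system_bias_deg, "system_bias_deg")
        object.__setattr__(self, "sd_subject", subj)
        object.__setattr__(self, "system_bias_deg", bias)
        for name in ("sd_session_m", "sd_observer_frame", "sd_digitize_px",
                     "sd_residual_deg", "sd_reference_deg", "sd_force_n"):
            if getattr(self, name) < 0:
                raise GaitSimulationError(f"{name} must be >= 0")
        if any(v < 0 for v in subj.values()):
            raise GaitSimulationError("sd_subject must be >= 0")

    @classmethod
    def zero(cls) -> "ErrorModel":
        """Error model with every SD and bias set to zero (ground truth only)."""
        return cls(sd_subject=0.0, sd_session_m=0.0, sd_observer_frame=0.0,
                   sd_digitize_px=0.0, system_bias_deg=0.0, sd_residual_deg=0.0,
                   sd_reference_deg=0.0, sd_force_n=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study design: who is measured, how often, by whom."""

    n_subjects: int = 50
    n_sessions: int = 2
    n_repetitions: int = 5
    n_observers: int = 2
    systems: tuple[str, ...] = ("video", "reference")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_repetitions", "n_observers"):
            if getattr(self, name) < 1:
                raise GaitSimulationError(f"{name} must be >= 1")
        if not 0 <= int(self.rng_seed) < 2**31:
            raise GaitSimulationError("rng_seed must be in [0, 2^31)")


@dataclass(frozen=True)
class Subject:
    """One simulated participant: anthropometry plus true gait profile."""

    index: int
    segments: SegmentModel
    profile: GaitAngleProfile
    height_m: float
    mass_kg: float


@dataclass
class TrialDataset:
    """One recorded walk with full ground truth attached."""

    tracks_3d: dict[str, np.ndarray]       # marker -> (n_frames, 3)
    times_s: np.ndarray
    fps: float
    true_ic_frame: int
    true_angles: dict[str, float]          # trial ground truth at IC, deg
    force: ForceSignal
    true_ic_force_sample: int
    observer_frames: list[int]
    observer_markers_px: list[dict[str, np.ndarray]]
    video_angles: list[dict[str, float]]   # one dict per observer
    reference_angles: dict[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.times_s.size


# --------------------------------------------------------------------------
# subject sampling and forward kinematics
# --------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, what: str) -> float:
    """Draw with rejection; degenerate draws are resampled with a warning."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = float(rng.normal(mean, sd))
        if lo <= x <= hi:
            return x
        logger.warning("rejected degenerate %s draw %.3f outside [%.2f, %.2f]; resampling", what, x, lo, hi)
    raise GaitSimulationError(f"could not draw a plausible {what} in 1000 attempts")


def sample_subject(config: CohortConfig, err: ErrorModel, rng: np.random.Generator,
                   index: int = 0) -> Subject:
    """Draw one subject: anthropometry-scaled segments plus IC angle targets.

    Segment lengths scale with the drawn stature; IC targets are drawn around
    the population means with the configured between-subject SDs.
    """
    height = _truncated_normal(rng, HEIGHT_MEAN_M, HEIGHT_SD_M, *HEIGHT_RANGE_M, what="height")
    mass = _truncated_normal(rng, MASS_MEAN_KG, MASS_SD_KG, *MASS_RANGE_KG, what="body mass")
    # small individual variation of segment proportions
    prop = 1.0 + rng.normal(0.0, 0.015, size=4)
    thigh = _THIGH_FRAC * height * prop[0]
    shank = _SHANK_FRAC * height * prop[1]
    foot = _FOOT_FRAC * height * prop[2]
    pelvis_depth = _PELVIS_DEPTH_FRAC * height * prop[3]
    foot_drop = 0.060 * height / HEIGHT_MEAN_M
    seg = SegmentModel(
        pelvis_depth=pelvis_depth,
        thigh_length=thigh,
        shank_length=shank,
        heel_offset=(-0.25 * foot, -foot_drop),
        toe_offset=(0.75 * foot, -foot_drop),
    )
    targets = {}
    for j in JOINTS:  # fixed draw order for determinism
        targets[j] = POPULATION_IC_MEANS[j] + err.sd_subject[j] * float(rng.standard_normal())
    tilt = 5.0 + 1.5 * float(rng.standard_normal())
    profile = GaitAngleProfile(
        ic_targets=targets,
        pelvic_tilt_ic=tilt,
        stride_length_m=0.78 * height,
        heel_clearance_max_m=0.12 * height,
    )
    return Subject(index=index, segments=seg, profile=profile, height_m=height, mass_kg=mass)


def mean_subject() -> Subject:
    """The deterministic population-mean subject (useful for sensitivity work)."""
    seg = SegmentModel()
    profile = GaitAngleProfile(
        ic_targets=dict(POPULATION_IC_MEANS),
        stride_length_m=0.78 * HEIGHT_MEAN_M,
        heel_clearance_max_m=0.12 * HEIGHT_MEAN_M,
    )
    return Subject(index=-1, segments=seg, profile=profile,
                   height_m=HEIGHT_MEAN_M, mass_kg=MASS_MEAN_KG)


_GUARD_RANGES = {"hip": (-40.0, 70.0), "knee": (-20.0, 95.0), "ankle": (-50.0, 50.0)}


def pose_leg(
    profile: GaitAngleProfile,
    seg: SegmentModel,
    t: float,
    pelvis_x: float | None = None,
    marker_offsets: Mapping[str, np.ndarray] | None = None,
    guard: bool = True,
) -> dict[str, np.ndarray]:
    """Forward kinematics: 3D marker positions at gait-cycle phase ``t``.

    The left leg is posed as a planar linkage in the sagittal plane (z = 0)
    realising the profile's hip, knee, ankle and pelvic-tilt angles, so that
    re-extracting those angles from the returned markers reproduces the
    profile exactly. ``marker_offsets`` (metres, in each marker's carrying
    segment frame) model placement error and are added on top of the
    segment model's nominal offsets.
    """
    tp = float(t) % 1.0
    if not 0.0 <= tp < 1.0:  # pragma: no cover - arithmetic guard
        raise GaitSimulationError("phase must be finite")
    hip = float(profile.angle("hip", tp))
    knee = float(profile.angle("knee", tp))
    ankle = float(profile.angle("ankle", tp))
    tilt = float(profile.angle("pelvic_tilt", tp))
    if guard:
        for j, val in (("hip", hip), ("knee", knee), ("ankle", ankle)):
            lo, hi = _GUARD_RANGES[j]
            if not lo <= val <= hi:
                raise GaitSimulationError(f"{j} angle {val:.1f} deg outside guard range [{lo}, {hi}]")

    if pelvis_x is None:
        pelvis_x = profile.stride_length_m * (float(t) - profile.t_ic)
    centre = np.array([pelvis_x, 0.0])

    # pelvic tilt positive = anterior tilt = clockwise rotation in the
    # (x anterior, y up) plane
    pelvis_dir = _rot(-tilt) @ np.array([1.0, 0.0])
    caudal = _rot(-tilt) @ np.array([0.0, -1.0])
    thigh_dir = _rot(hip) @ caudal            # CCW from the caudal ray = anterior
    shank_dir = _rot(-knee) @ thigh_dir       # flexion carries the shank posterior
    foot_dir = _rot(ankle) @ _rot90_ccw(shank_dir)  # dorsiflexion lifts the toes

    gt = centre + seg.pelvis_drop * caudal
    lfc = gt + seg.thigh_length * thigh_dir
    lm = lfc + seg.shank_length * shank_dir

    frames2d = {
        "pelvis": np.column_stack([pelvis_dir, _rot90_ccw(pelvis_dir)]),
        "thigh": np.column_stack([thigh_dir, _rot90_ccw(thigh_dir)]),
        "shank": np.column_stack([shank_dir, _rot90_ccw(shank_dir)]),
        "foot": np.column_stack([foot_dir, _rot90_ccw(foot_dir)]),
    }
    base = {
        "ASIS": centre + 0.5 * seg.pelvis_depth * pelvis_dir,
        "PSIS": centre - 0.5 * seg.pelvis_depth * pelvis_dir,
        "GT": gt,
        "THI": gt + 0.5 * seg.thigh_length * thigh_dir,
        "LFC": lfc,
        "TIB": lfc + 0.5 * seg.shank_length * shank_dir,
        "LM": lm,
        "CAL": lm + frames2d["foot"] @ np.asarray(seg.heel_offset),
        "MT2": lm + frames2d["foot"] @ np.asarray(seg.toe_offset),
    }
    # ground-contact constraint: the pelvis height is whatever puts the
    # (nominal, offset-free) heel marker on its designed clearance curve
    lift = float(profile.heel_clearance(tp)) + profile.ground_clearance_m - base["CAL"][1]

    out: dict[str, np.ndarray] = {}
    for name, p in base.items():
        off = np.zeros(2)
        if seg.marker_offsets and name in seg.marker_offsets:
            off = off + frames2d[_SEGMENT_OF_MARKER[name]] @ np.asarray(seg.marker_offsets[name], dtype=float)
        if marker_offsets and name in marker_offsets:
            off = off + frames2d[_SEGMENT_OF_MARKER[name]] @ np.asarray(marker_offsets[name], dtype=float)
        q = p + off
        out[name] = np.array([q[0], q[1] + lift, 0.0])
    return out


def sagittal_view(markers3d: Mapping[str, np.ndarray], frame_index: int = 0,
                  time_s: float = 0.0) -> MarkerFrame:
    """Drop the mediolateral coordinate: metric 2D frame in the sagittal plane."""
    return MarkerFrame(points={n: np.asarray(p)[:2] for n, p in markers3d.items()},
                       frame_index=frame_index, time_s=time_s)


# --------------------------------------------------------------------------
# ground-reaction force
# --------------------------------------------------------------------------

def synth_grf(
    contact_time_s: float,
    duration_s: float,
    rate_hz: float = 1000.0,
    mass_kg: float = MASS_MEAN_KG,
    stance_duration_s: float = 0.68,
    sd_noise_n: float = 0.0,
    rng: np.random.Generator | None = None,
    threshold_n: float = 20.0,
) -> tuple[ForceSignal, int]:
    """Synthesise a vertical GRF for one foot contact.

    The signal is zero during swing and follows the classic double-bump
    stance shape ``W * (sin(pi u) + 0.28 sin(3 pi u))`` after contact, rising
    monotonically through the detection threshold. Returns the signal and the
    ground-truth sample index at which the *noise-free* force first reaches
    ``threshold_n`` (recorded at construction, before any noise is added).
    """
    if rate_hz <= 0:
        raise GaitSimulationError("rate must be positive")
    if not 0 <= contact_time_s < duration_s:
        raise GaitSimulationError("contact time must fall inside the recording")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    u = (t - contact_time_s) / stance_duration_s
    shape = np.where((u >= 0) & (u <= 1), np.sin(np.pi * u) + 0.28 * np.sin(3 * np.pi * u), 0.0)
    clean = mass_kg * GRAVITY * np.clip(shape, 0.0, None)
    above = np.flatnonzero(clean >= threshold_n)
    if above.size == 0:
        raise GaitSimulationError("stance too short: force never reaches the threshold")
    true_ic = int(above[0])
    samples = clean
    if sd_noise_n > 0:
        if rng is None:
            raise GaitSimulationError("rng is required when sd_noise_n > 0")
        samples = clean + rng.normal(0.0, sd_noise_n, size=n)
    return ForceSignal(samples=samples, rate_hz=rate_hz, threshold_n=threshold_n), true_ic


# --------------------------------------------------------------------------
# trials and cohorts
# --------------------------------------------------------------------------

def _draw_session_offsets(err: ErrorModel, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Marker re-placement offsets for one session (frozen across repetitions)."""
    if err.sd_session_m == 0:
        return {}
    return {m: rng.normal(0.0, err.sd_session_m, size=2) for m in MARKER_NAMES}


def _draw_trial_targets(subject: Subject, err: ErrorModel, rng: np.random.Generator) -> dict[str, float]:
    return {j: subject.profile.ic_targets[j] + (err.sd_residual_deg * float(rng.standard_normal())
                                                if err.sd_residual_deg > 0 else 0.0)
            for j in JOINTS}


def _measure_video(
    trial_profile: GaitAngleProfile,
    seg: SegmentModel,
    session_offsets: Mapping[str, np.ndarray],
    err: ErrorModel,
    cam: CameraModel,
    rng: np.random.Generator,
) -> tuple[dict[str, float], int, dict[str, np.ndarray]]:
    """One observer's digitisation of one trial: frame pick + clicks + angles."""
    shift = 0
    if err.sd_observer_frame > 0:
        shift = int(round(rng.normal(0.0, err.sd_observer_frame)))
    phase = trial_profile.t_ic + shift / (cam.fps * trial_profile.cycle_duration_s)
    markers3d = pose_leg(trial_profile, seg, phase, pelvis_x=cam.x_position,
                         marker_offsets=session_offsets)
    px = project_markers(markers3d, cam)
    if err.sd_digitize_px > 0:
        px = {m: p + rng.normal(0.0, err.sd_digitize_px, size=2) for m, p in px.items()}
    frame = MarkerFrame(points=px).normalized()
    angles = {"hip": hip_angle(frame), "knee": knee_angle(frame), "ankle": ankle_angle(frame)}
    return angles, shift, px


def _measure_reference(true_angles: Mapping[str, float], err: ErrorModel,
                       rng: np.random.Generator) -> dict[str, float]:
    """Emulated 3D reference system: truth minus the video-vs-reference bias.

    The per-joint ``system_bias_deg`` is defined as video minus reference, so
    the reference reads ``truth - bias`` (plus its own measurement noise); the
    video system, which measures the truth through the camera chain, then
    sits ``bias`` degrees above it on average.
    """
    out = {}
    for j in JOINTS:
        noise = err.sd_reference_deg * float(rng.standard_normal()) if err.sd_reference_deg > 0 else 0.0
        out[j] = float(true_angles[j]) - err.system_bias_deg[j] + noise
    return out


def simulate_trial(
    subject: Subject,
    session_offsets: Mapping[str, np.ndarray],
    err: ErrorModel,
    cam: CameraModel,
    rng: np.random.Generator,
    n_frames: int = 80,
    n_observers: int = 2,
    force_rate_hz: float = 1000.0,
    meta: dict | None = None,
) -> TrialDataset:
    """Simulate one recorded walk: full marker tracks, GRF, observer readings.

    The recording spans ``n_frames`` video frames with the true initial
    contact at the middle frame. Session-level marker offsets are applied to
    every frame (they are frozen within a session); each observer then picks
    an IC frame with independent frame error and digitises the markers with
    independent pixel jitter. The reference-system angles are the trial's
    ground truth plus the configured system bias/noise.
    """
    profile = subject.profile
    trial_targets = _draw_trial_targets(subject, err, rng)
    trial_profile = replace(profile, ic_targets=trial_targets)

    ic_frame = n_frames // 2
    cycle_frames = cam.fps * profile.cycle_duration_s
    frame_idx = np.arange(n_frames)
    phases = profile.t_ic + (frame_idx - ic_frame) / cycle_frames
    times = frame_idx / cam.fps

    tracks: dict[str, list[np.ndarray]] = {m: [] for m in MARKER_NAMES}
    for ph in phases:
        x = cam.x_position + profile.stride_length_m * (ph - profile.t_ic)
        pose = pose_leg(trial_profile, subject.segments, ph, pelvis_x=x,
                        marker_offsets=session_offsets)
        for m in MARKER_NAMES:
            tracks[m].append(pose[m])
    tracks3d = {m: np.vstack(v) for m, v in tracks.items()}

    force, true_ic_sample = synth_grf(
        contact_time_s=ic_frame / cam.fps,
        duration_s=n_frames / cam.fps,
        rate_hz=force_rate_hz,
        mass_kg=subject.mass_kg,
        sd_noise_n=err.sd_force_n,
        rng=rng if err.sd_force_n > 0 else None,
    )

    observer_frames: list[int] = []
    observer_px: list[dict[str, np.ndarray]] = []
    video_angles: list[dict[str, float]] = []
    for _ in range(n_observers):
        angles, shift, px = _measure_video(trial_profile, subject.segments,
                                           session_offsets, err, cam, rng)
        observer_frames.append(int(np.clip(ic_frame + shift, 0, n_frames - 1)))
        observer_px.append(px)
        video_angles.append(angles)

    reference = _measure_reference(trial_targets, err, rng)

    return TrialDataset(
        tracks_3d=tracks3d,
        times_s=times,
        fps=cam.fps,
        true_ic_frame=ic_frame,
        true_angles=trial_targets,
        force=force,
        true_ic_force_sample=true_ic_sample,
        observer_frames=observer_frames,
        observer_markers_px=observer_px,
        video_angles=video_angles,
        reference_angles=reference,
        meta=meta or {},
    )


# fixed substream namespaces so adding subjects/sessions never shifts draws
_NS_SUBJECT, _NS_SESSION, _NS_TRIAL, _NS_OBSERVER = 1, 2, 3, 4

_COHORT_COLUMNS = ["subject", "session", "observer", "system", "repetition", "joint", "angle_deg"]


def simulate_cohort(
    config: CohortConfig,
    err: ErrorModel | None = None,
    cam: CameraModel | None = None,
) -> pd.DataFrame:
    """Simulate the full study and return the long-format angle table.

    One row per (subject, session, observer, system, repetition, joint).
    Video rows come from the full camera/digitisation chain; reference rows
    are observer-independent (the 3D system does not involve the video
    observers) and are duplicated across the observer column so the table
    schema is uniform. Identical config + error model + seed reproduce the
    table bit-for-bit.
    """
    err = err if err is not None else ErrorModel()
    cam = cam if cam is not None else CameraModel()
    seed = config.rng_seed
    rows: list[tuple] = []
    for s in range(1, config.n_subjects + 1):
        subject = sample_subject(config, err, substream(seed, _NS_SUBJECT, s), index=s)
        for c in range(1, config.n_sessions + 1):
            offsets = _draw_session_offsets(err, substream(seed, _NS_SESSION, s, c))
            for r in range(1, config.n_repetitions + 1):
                rng_trial = substream(seed, _NS_TRIAL, s, c, r)
                trial_targets = _draw_trial_targets(subject, err, rng_trial)
                trial_profile = replace(subject.profile, ic_targets=trial_targets)
                reference = _measure_reference(trial_targets, err, rng_trial)
                for o in range(1, config.n_observers + 1):
                    rng_obs = substream(seed, _NS_OBSERVER, s, c, r, o)
                    if "video" in config.systems:
                        angles, _, _ = _measure_video(trial_profile, subject.segments,
                                                      offsets, err, cam, rng_obs)
                        for j in JOINTS:
                            rows.append((s, c, o, "video", r, j, angles[j]))
                    if "reference" in config.systems:
                        for j in JOINTS:
                            rows.append((s, c, o, "reference", r, j, reference[j]))
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def aggregate_repetitions(df: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Collapse repetitions to one value per (subject, session, observer, system, joint).

    ``how`` is 'mean' (default, the least-variance choice), 'median', or
    'first' (a single selected repetition).
    """
    keys = ["subject", "session", "observer", "system", "joint"]
    g = df.groupby(keys, sort=True)["angle_deg"]
    if how == "mean":
        out = g.mean()
    elif how == "median":
        out = g.median()
    elif how == "first":
        out = g.first()
    else:
        raise GaitSimulationError(f"unknown aggregation {how!r}")
    return out.reset_index()


# --------------------------------------------------------------------------
# variance bookkeeping: delta-method angle-space error components
# --------------------------------------------------------------------------

def _video_angle_of_offsets(subject: Subject, cam: CameraModel,
                            offsets: Mapping[str, np.ndarray],
                            px_jitter: Mapping[str, np.ndarray] | None = None) -> dict[str, float]:
    pose = pose_leg(subject.profile, subject.segments, subject.profile.t_ic,
                    pelvis_x=cam.x_position, marker_offsets=offsets)
    px = project_markers(pose, cam)
    if px_jitter:
        px = {m: p + px_jitter.get(m, 0.0) for m, p in px.items()}
    frame = MarkerFrame(points=px).normalized()
    return {"hip": hip_angle(frame), "knee": knee_angle(frame), "ankle": ankle_angle(frame)}


def _sensitivity_variances(subject: Subject, cam: CameraModel, err: ErrorModel) -> tuple[dict, dict]:
    """Per-joint session (m) and digitisation (px) variances for one subject."""
    h = 1e-5
    sess_var = {j: 0.0 for j in JOINTS}
    for m in MARKER_NAMES:
        for axis in range(2):
            dv = np.zeros(2)
            dv[axis] = h
            plus = _video_angle_of_offsets(subject, cam, {m: dv})
            minus = _video_angle_of_offsets(subject, cam, {m: -dv})
            for j in JOINTS:
                grad = (plus[j] - minus[j]) / (2 * h)
                sess_var[j] += (grad * err.sd_session_m) ** 2
    hp = 1e-3
    dig_var = {j: 0.0 for j in JOINTS}
    for m in MARKER_NAMES:
        for axis in range(2):
            dv = np.zeros(2)
            dv[axis] = hp
            plus = _video_angle_of_offsets(subject, cam, {}, px_jitter={m: dv})
            minus = _video_angle_of_offsets(subject, cam, {}, px_jitter={m: -dv})
            for j in JOINTS:
                grad = (plus[j] - minus[j]) / (2 * hp)
                dig_var[j] += (grad * err.sd_digitize_px) ** 2
    return sess_var, dig_var


def implied_error_variances(err: ErrorModel, cam: CameraModel | None = None,
                            subject: Subject | None = None,
                            n_subjects_avg: int = 16) -> dict[str, dict[str, float]]:
    """Angle-space (deg^2) error variances implied by the mechanistic model.

    Uses the delta method: numerical Jacobians of each joint angle with
    respect to marker placement offsets (metres) and digitisation clicks
    (pixels) at the initial-contact pose, plus the analytic curve slope for
    frame-selection error (with the integer rounding of the frame pick
    accounted for exactly). Because the Jacobians depend on segment lengths,
    they are averaged over a fixed panel of ``n_subjects_avg`` sampled
    subjects unless a specific ``subject`` is given. Returns, per joint, the
    variance contributed per single measurement by ``session``, ``digitize``,
    ``frame``, ``residual`` and ``reference`` sources.
    """
    cam = cam if cam is not None else CameraModel()
    if subject is not None:
        panel = [subject]
    else:
        cfg = CohortConfig(n_subjects=n_subjects_avg, rng_seed=12345)
        panel = [sample_subject(cfg, err, substream(12345, _NS_SUBJECT, s), index=s)
                 for s in range(1, n_subjects_avg + 1)]
    sess_var = {j: 0.0 for j in JOINTS}
    dig_var = {j: 0.0 for j in JOINTS}
    for subj in panel:
        sv, dv = _sensitivity_variances(subj, cam, err)
        for j in JOINTS:
            sess_var[j] += sv[j] / len(panel)
            dig_var[j] += dv[j] / len(panel)

    # variance of round(N(0, sd)) computed exactly from the normal CDF
    from scipy.stats import norm
    sd_f = err.sd_observer_frame
    if sd_f > 0:
        ks = np.arange(-int(6 * sd_f + 2), int(6 * sd_f + 3))
        pk = norm.cdf((ks + 0.5) / sd_f) - norm.cdf((ks - 0.5) / sd_f)
        frame_var_frames = float(np.sum(pk * ks**2))
    else:
        frame_var_frames = 0.0
    ref = panel[0].profile
    cycle_frames = cam.fps * ref.cycle_duration_s
    frame_var = {}
    for j in JOINTS:
        slope = float(ref.slope(j, ref.t_ic)) / cycle_frames  # deg/frame
        frame_var[j] = slope**2 * frame_var_frames

    return {
        j: {
            "session": sess_var[j],
            "digitize": dig_var[j],
            "frame": frame_var[j],
            "residual": err.sd_residual_deg**2,
            "reference": err.sd_reference_deg**2,
        }
        for j in JOINTS
    }


def implied_icc(err: ErrorModel, config: CohortConfig | None = None,
                cam: CameraModel | None = None, contrast: str = "intra_rater",
                subject: Subject | None = None) -> dict[str, float]:
    """Closed-form single-measures ICC implied by the configured components.

    Computes ``sigma^2_subject / (sigma^2_subject + sigma^2_error)`` per joint
    for the requested contrast, after averaging the per-trial error sources
    over the repetitions:

    * ``intra_rater`` (one observer, session vs session): error = session
      re-placement + (frame + digitise + stride residual) / n_rep.
    * ``inter_rater`` (two observers, same session): session and stride
      effects are shared (they move both observers identically, adding to the
      between-subject spread); error = (frame + digitise) / n_rep.
    """
    config = config if config is not None else CohortConfig()
    comps = implied_error_variances(err, cam, subject)
    nrep = config.n_repetitions
    out = {}
    for j in JOINTS:
        c = comps[j]
        var_subj = err.sd_subject[j] ** 2
        if contrast == "intra_rater":
            var_err = c["session"] + (c["frame"] + c["digitize"] + c["residual"]) / nrep
        elif contrast == "inter_rater":
            var_subj = var_subj + c["session"] + c["residual"] / nrep
            var_err = (c["frame"] + c["digitize"]) / nrep
        else:
            raise GaitSimulationError(f"unknown contrast {contrast!r}")
        out[j] = var_subj / (var_subj + var_err) if (var_subj + var_err) > 0 else float("nan")
    return out
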