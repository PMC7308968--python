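"""Sagittal-plane joint angles at initial contact, and gait-event detection.

Implements the 2D video-goniometry constructions used in clinical gait
screening from a lateral camera view: the hip angle measured against the
pelvic (ASIS-PSIS) line, the knee angle as the deviation of the shank from
the extended thigh line, the ankle angle as the deviation of the foot line
from perpendicular to the shank, plus initial-contact detection either from
a vertical ground-reaction-force threshold or from heel-marker height.

Conventions
-----------
* Coordinates: ``x`` is the direction of progression, ``y`` is up. Frames
  recorded while walking towards ``-x`` are mirrored before any signed angle
  is computed (:meth:`MarkerFrame.normalized`), so flexion/dorsiflexion signs
  do not depend on walking direction.
* Hip: signed angle between the caudal (downward) perpendicular to the pelvic
  line, drawn through the greater trochanter, and the thigh line GT->LFC.
  Flexion (thigh anterior of the perpendicular) is positive.
* Knee: 180 deg minus the inner angle at the lateral femoral condyle between
  the GT and LM rays. Flexion (shank posterior of the extended thigh line) is
  positive; hyperextension is negative.
* Ankle: 90 deg minus the inner angle between the foot line CAL->MT2 and the
  shank line. Dorsiflexion positive, plantar flexion negative.

All angle constructions are invariant under translation, scaling and in-plane
rotation of the marker set, so they can be evaluated on metric coordinates or
directly on pixel coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "REQUIRED_MARKERS",
    "OPTIONAL_MARKERS",
    "MARKER_NAMES",
    "MarkerFrame",
    "JointAnglesIC",
    "ForceSignal",
    "angle_at_vertex",
    "signed_angle_from",
    "hip_angle",
    "knee_angle",
    "ankle_angle",
    "angles_at_ic",
    "detect_ic_force",
    "detect_ic_kinematic",
    "smooth_track",
]

#: Markers required by the three angle constructions.
REQUIRED_MARKERS = ("ASIS", "PSIS", "GT", "LFC", "LM", "CAL", "MT2")
#: Markers carried through the pipeline but unused in the angle math.
OPTIONAL_MARKERS = ("THI", "TIB")
MARKER_NAMES = REQUIRED_MARKERS[:3] + ("THI", "LFC", "TIB") + REQUIRED_MARKERS[4:]

_COINCIDENT_TOL = 1e-12


class GaitKinematicsError(ValueError):
    """Raised for degenerate marker geometry or undetectable events."""


@dataclass(frozen=True)
class MarkerFrame:
    """Named 2D marker coordinates for one video frame.

    Units may be metres or pixels but must be consistent within the frame;
    the angle constructions are scale-invariant so either works.
    """

    points: Mapping[str, np.ndarray]
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        pts = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (2,):
                raise GaitKinematicsError(f"marker {name!r} must be a 2D point, got shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise GaitKinematicsError(f"marker {name!r} has non-finite coordinates")
            pts[name] = arr
        missing = [m for m in REQUIRED_MARKERS if m not in pts]
        if missing:
            raise GaitKinematicsError(f"missing required markers: {missing}")
        object.__setattr__(self, "points", pts)

    def point(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise GaitKinematicsError(f"marker {name!r} not present in frame") from None

    def normalized(self) -> "MarkerFrame":
        """Mirror the frame so the subject walks towards +x.

        The anterior pelvic marker (ASIS) must be ahead of the posterior one
        (PSIS) in the direction of progression; if it is not, every x
        coordinate is negated.
        """
        if self.points["ASIS"][0] >= self.points["PSIS"][0]:
            return self
        flipped = {n: np.array([-p[0], p[1]]) for n, p in self.points.items()}
        return replace(self, points=flipped)


@dataclass(frozen=True)
class JointAnglesIC:
    """Sagittal joint angles (degrees) at the initial-contact frame.

    Signs: hip and knee flexion positive (knee extension negative), ankle
    dorsiflexion positive / plantar flexion negative.
    """

    hip_deg: float
    knee_deg: float
    ankle_deg: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        for name in ("hip_deg", "knee_deg", "ankle_deg"):
            v = getattr(self, name)
            if abs(v) >= 90.0:
                warnings.warn(
                    f"{name}={v:.1f} exceeds the plausible +/-90 deg range at initial contact",
                    stacklevel=2,
                )

    def as_dict(self) -> dict[str, float]:
        return {"hip": self.hip_deg, "knee": self.knee_deg, "ankle": self.ankle_deg}


@dataclass(frozen=True)
class ForceSignal:
    """Vertical ground-reaction-force samples in Newtons at a fixed rate."""

    samples: np.ndarray
    rate_hz: float
    threshold_n: float = 20.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(arr)):
            raise GaitKinematicsError("force signal contains non-finite samples")
        if self.rate_hz <= 0:
            raise GaitKinematicsError("force sampling rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz


def _as_vec(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (2,):
        raise GaitKinematicsError(f"expected a 2D point/vector, got shape {arr.shape}")
    return arr


def angle_at_vertex(a, v, b) -> float:
    """Inner angle in degrees, in [0, 180], between rays v->a and v->b.

    This is the unsigned protractor angle a video digitising tool reports.
    Computed with a two-argument arctangent of the cross and dot products,
    which is numerically stable for nearly collinear rays.
    """
    a, v, b = _as_vec(a), _as_vec(v), _as_vec(b)
    u = a - v
    w = b - v
    nu, nw = np.hypot(*u), np.hypot(*w)
    if nu < _COINCIDENT_TOL or nw < _COINCIDENT_TOL:
        raise GaitKinematicsError("vertex coincides with an endpoint; angle undefined")
    cross = u[0] * w[1] - u[1] * w[0]
    dot = u[0] * w[0] + u[1] * w[1]
    return math.degrees(math.atan2(abs(cross), dot))


def signed_angle_from(reference_dir, target_dir) -> float:
    """Signed angle in degrees, in (-180, 180], from ``reference_dir`` to ``target_dir``.

    Positive is counter-clockwise in the (x right, y up) plane. For the
    caudally directed (downward) reference rays used by the hip construction,
    counter-clockwise rotation carries the target towards +x, i.e. anteriorly,
    so flexion comes out positive once the walking direction is normalised
    to +x.
    """
    r = _as_vec(reference_dir)
    t = _as_vec(target_dir)
    if np.hypot(*r) < _COINCIDENT_TOL or np.hypot(*t) < _COINCIDENT_TOL:
        raise GaitKinematicsError("zero-length direction vector")
    cross = r[0] * t[1] - r[1] * t[0]
    dot = r[0] * t[0] + r[1] * t[1]
    ang = math.degrees(math.atan2(cross, dot))
    return 180.0 if ang == -180.0 else ang


def _rot90_ccw(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def _rot90_cw(v: np.ndarray) -> np.ndarray:
    return np.array([v[1], -v[0]])


def hip_angle(frame: MarkerFrame) -> float:
    """Hip flexion angle (deg) relative to the pelvis.

    A line through ASIS and PSIS defines the pelvis; its caudal perpendicular,
    drawn through the greater trochanter, is the reference against which the
    thigh line GT->LFC is measured. Positive when the femoral condyle lies
    anterior to the perpendicular (hip flexion). Assumes the frame is
    normalised so progression is towards +x.
    """
    asis, psis = frame.point("ASIS"), frame.point("PSIS")
    gt, lfc = frame.point("GT"), frame.point("LFC")
    pelvis = asis - psis
    if np.hypot(*pelvis) < _COINCIDENT_TOL:
        raise GaitKinematicsError("ASIS and PSIS coincide; pelvic line undefined")
    caudal_perp = _rot90_cw(pelvis)  # anterior pelvic dir rotated to point down
    thigh = lfc - gt
    return signed_angle_from(caudal_perp, thigh)


def knee_angle(frame: MarkerFrame) -> float:
    """Knee angle (deg): 180 minus the inner angle at the femoral condyle.

    The magnitude equals ``180 - angle(GT, LFC, LM)``; the sign comes from the
    orientation of the shank relative to the extended thigh line, so flexion
    (shank posterior) is positive and hyperextension negative. A perfectly
    straight leg returns exactly 0.
    """
    gt, lfc, lm = frame.point("GT"), frame.point("LFC"), frame.point("LM")
    thigh = lfc - gt
    shank = lm - lfc
    if np.hypot(*thigh) < _COINCIDENT_TOL or np.hypot(*shank) < _COINCIDENT_TOL:
        raise GaitKinematicsError("degenerate knee geometry: coincident markers")
    # CCW rotation of the shank away from the extended thigh line is anterior
    # (hyperextension); flexion is the clockwise side, hence the minus sign.
    return -signed_angle_from(thigh, shank)


def ankle_angle(frame: MarkerFrame) -> float:
    """Ankle angle (deg): 90 minus the inner angle between foot and shank lines.

    The foot line runs from the calcaneus to the second metatarsal head; the
    shank line from the femoral condyle to the malleolus. The inner angle is
    taken on the dorsal side (against the proximally directed shank ray), the
    convention under which heel-strike plantar flexion is negative, matching
    clinical usage. Dorsiflexion positive.
    """
    lfc, lm = frame.point("LFC"), frame.point("LM")
    cal, mt2 = frame.point("CAL"), frame.point("MT2")
    foot = mt2 - cal
    shank_down = lm - lfc
    if np.hypot(*foot) < _COINCIDENT_TOL:
        raise GaitKinematicsError("CAL and MT2 coincide; foot line undefined")
    if np.hypot(*shank_down) < _COINCIDENT_TOL:
        raise GaitKinematicsError("LFC and LM coincide; shank line undefined")
    # Neutral foot direction is the anterior perpendicular of the shank; the
    # signed deviation from it is the dorsi(+)/plantar(-) flexion angle and
    # equals 90 - (inner angle between foot line and proximal shank ray).
    neutral_foot = _rot90_ccw(shank_down)
    return signed_angle_from(neutral_foot, foot)


def angles_at_ic(frames: Sequence[MarkerFrame] | MarkerFrame, ic_frame: int | None = None) -> JointAnglesIC:
    """Apply the three constructions to the initial-contact frame.

    Parameters
    ----------
    frames
        Either a single :class:`MarkerFrame` or a sequence of frames.
    ic_frame
        Index of the initial-contact frame within ``frames`` (0-based).
        Ignored when a single frame is given.
    """
    if isinstance(frames, MarkerFrame):
        frame = frames
        idx = frames.frame_index
    else:
        if ic_frame is None:
            raise GaitKinematicsError("ic_frame is required when passing a sequence of frames")
        if not 0 <= ic_frame < len(frames):
            raise GaitKinematicsError(f"ic_frame {ic_frame} outside recording of {len(frames)} frames")
        frame = frames[ic_frame]
        idx = ic_frame
    frame = frame.normalized()
    return JointAnglesIC(
        hip_deg=hip_angle(frame),
        knee_deg=knee_angle(frame),
        ankle_deg=ankle_angle(frame),
        frame_index=idx,
    )


def detect_ic_force(
    sig: ForceSignal,
    threshold_n: float | None = None,
    min_above: int = 10,
) -> int:
    """Initial contact from the vertical ground-reaction force.

    Returns the first sample at or above ``threshold_n`` (default: the
    signal's own threshold, normally 20 N) that stays at or above it for
    ``min_above`` consecutive samples. The persistence requirement rejects
    isolated noise spikes before true foot contact; 10 samples at 1000 Hz
    is 10 ms.
    """
    thr = sig.threshold_n if threshold_n is None else float(threshold_n)
    if min_above < 1:
        raise GaitKinematicsError("min_above must be >= 1")
    x = sig.samples
    above = x >= thr
    for i in np.flatnonzero(above):
        j = int(i)
        if j + min_above <= x.size and bool(np.all(above[j : j + min_above])):
            return j
    raise GaitKinematicsError(
        f"no contact: force never stays >= {thr:g} N for {min_above} consecutive samples"
    )


def detect_ic_kinematic(
    cal_y: np.ndarray,
    window: tuple[int, int] | None = None,
) -> int:
    """Initial contact as the first local minimum of heel (CAL) height.

    An automated surrogate for an observer scrubbing video for the heel-strike
    frame. ``window`` restricts the search to ``[start, stop)`` frame indices.
    """
    y = np.asarray(cal_y, dtype=float).ravel()
    if y.size < 5:
        raise GaitKinematicsError("need at least 5 frames to detect a heel-height minimum")
    lo, hi = (0, y.size) if window is None else window
    lo = max(lo, 0)
    hi = min(hi, y.size)
    for i in range(max(lo, 1), min(hi, y.size - 1)):
        if y[i] < y[i - 1] and y[i] <= y[i + 1]:
            return i
    raise GaitKinematicsError("no local minimum of heel height in the search window")


def smooth_track(y: np.ndarray, width: int = 1) -> np.ndarray:
    """Optional centred moving average of a marker track (off by default).

    ``width`` is the full window in frames; ``width <= 1`` returns the input
    unchanged. Edges use a shrinking window so the track length is preserved.
    """
    y = np.asarray(y, dtype=float)
    if width <= 1:
        return y.copy()
    half = width // 2
    out = np.empty_like(y)
    for i in range(y.shape[0]):
        lo, hi = max(0, i - half), min(y.shape[0], i + half + 1)
        out[i] = y[lo:hi].mean(axis=0)
    return out
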