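"""Frontal-plane kinematics from 2D pose landmarks.

Three angles describe single-leg-squat movement quality as seen from a
frontal camera:

* **trunk lateral tilt** — unsigned angle between the vertical axis and the
  segment joining the shoulder midpoint and the hip midpoint (upper-body lean);
* **pelvic lateral tilt** — unsigned angle between the inter-hip segment and
  the horizontal axis (pelvic obliquity / contralateral pelvic drop);
* **knee valgus** — 180° minus the interior hip–knee–ankle angle, signed so
  that medial deviation of the knee (valgus) is positive and lateral
  deviation (varus) is negative.

All coordinates use a mathematical y-up convention (the io module converts
image coordinates on read). Angles are reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateGeometryError, SchemaError, SequenceQualityError

#: The eight landmarks every frame must carry.
REQUIRED_LANDMARKS: Tuple[str, ...] = (
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: Default visibility below which a frame's angle is interpolated from neighbors.
DEFAULT_VISIBILITY_THRESHOLD = 0.5

#: Longest run of low-visibility frames that may be bridged by interpolation.
DEFAULT_MAX_GAP = 5


@dataclass
class LandmarkFrame:
    """A single time-stamped pose frame.

    ``coordinates`` maps landmark name -> (x, y) in the internal y-up frame;
    ``visibility`` maps landmark name -> confidence in [0, 1] (defaults to 1).
    """

    timestamp: float
    coordinates: Dict[str, Tuple[float, float]]
    visibility: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in REQUIRED_LANDMARKS:
            if name not in self.coordinates:
                raise SchemaError(f"required landmark {name!r} missing from frame")
            x, y = self.coordinates[name]
            if not (math.isfinite(x) and math.isfinite(y)):
                raise SchemaError(f"non-finite coordinates for landmark {name!r}")

    def vis(self, name: str) -> float:
        return float(self.visibility.get(name, 1.0))

    def point(self, name: str) -> np.ndarray:
        return np.asarray(self.coordinates[name], dtype=float)


@dataclass
class LandmarkSequence:
    """An ordered sequence of frames for one single-leg-squat repetition."""

    frames: List[LandmarkFrame]
    frame_rate: float
    weight_bearing_side: str  # "left" | "right"

    def __post_init__(self) -> None:
        if len(self.frames) < 5:
            raise SchemaError("a landmark sequence needs at least 5 frames")
        if self.weight_bearing_side not in ("left", "right"):
            raise SchemaError(
                f"weight_bearing_side must be 'left' or 'right', got {self.weight_bearing_side!r}"
            )
        ts = np.array([f.timestamp for f in self.frames], dtype=float)
        if not np.all(np.diff(ts) > 0):
            raise SchemaError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def coords_array(self, names: Sequence[str]) -> np.ndarray:
        """Stack coordinates into an (n_frames, len(names), 2) array."""
        return np.array(
            [[f.coordinates[n] for n in names] for f in self.frames], dtype=float
        )

    def visibility_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([[f.vis(n) for n in names] for f in self.frames], dtype=float)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)


@dataclass
class AngleSeries:
    """Frame-wise trunk / pelvic / knee angles for one repetition (degrees)."""

    trunk: np.ndarray
    pelvis: np.ndarray
    knee: np.ndarray

    def __post_init__(self) -> None:
        self.trunk = np.asarray(self.trunk, dtype=float)
        self.pelvis = np.asarray(self.pelvis, dtype=float)
        self.knee = np.asarray(self.knee, dtype=float)
        n = len(self.trunk)
        if len(self.pelvis) != n or len(self.knee) != n:
            raise SchemaError("angle series must share one length")
        for arr, name in ((self.trunk, "trunk"), (self.pelvis, "pelvis"), (self.knee, "knee")):
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"non-finite values in {name} angle series")

    def __len__(self) -> int:
        return len(self.trunk)


@dataclass(frozen=True)
class PeakAngles:
    """Per-repetition peak frontal-plane deviations (degrees).

    ``trunk`` and ``pelvis`` are magnitudes (>= 0); ``knee`` is signed
    (positive = valgus, negative = varus).
    """

    trunk: float
    pelvis: float
    knee: float

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.trunk, self.pelvis, self.knee)


# ---------------------------------------------------------------------------
# frame-level angle operations
# ---------------------------------------------------------------------------

def _midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 0.5 * (a + b)


def trunk_tilt_frame(frame: LandmarkFrame) -> float:
    """Unsigned angle (deg, in [0, 90]) between the vertical and the
    shoulder-midpoint -> hip-midpoint segment."""
    s_mid = _midpoint(frame.point("left_shoulder"), frame.point("right_shoulder"))
    h_mid = _midpoint(frame.point("left_hip"), frame.point("right_hip"))
    d = s_mid - h_mid
    if np.allclose(d, 0.0):
        raise DegenerateGeometryError("shoulder and hip midpoints coincide")
    return math.degrees(math.atan2(abs(d[0]), abs(d[1])))


def pelvic_tilt_frame(frame: LandmarkFrame) -> float:
    """Unsigned angle (deg, in [0, 90]) between the inter-hip segment and the
    horizontal axis."""
    d = frame.point("left_hip") - frame.point("right_hip")
    if np.allclose(d, 0.0):
        raise DegenerateGeometryError("left and right hip landmarks coincide")
    return math.degrees(math.atan2(abs(d[1]), abs(d[0])))


def knee_valgus_frame(frame: LandmarkFrame, side: str) -> float:
    """Signed frontal-plane knee deviation (deg) for the given limb.

    Magnitude is 180° minus the interior angle of the hip–knee–ankle chain at
    the knee. Sign is resolved from the side: positive when the knee lies
    medial to the hip->ankle line (valgus), negative when lateral (varus).
    """
    if side not in ("left", "right"):
        raise SchemaError(f"side must be 'left' or 'right', got {side!r}")
    hip = frame.point(f"{side}_hip")
    knee = frame.point(f"{side}_knee")
    ankle = frame.point(f"{side}_ankle")
    return _knee_valgus(hip, knee, ankle, side)


def _knee_valgus(hip: np.ndarray, knee: np.ndarray, ankle: np.ndarray, side: str) -> float:
    v1 = hip - knee
    v2 = ankle - knee
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0 or np.linalg.norm(hip - ankle) == 0.0:
        raise DegenerateGeometryError("hip, knee and ankle must be pairwise distinct")
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    interior = math.degrees(math.acos(cosang))
    magnitude = 180.0 - interior
    # Perpendicular offset of the knee relative to the hip->ankle line; with the
    # subject facing the camera, +x is the subject's left, so the medial
    # direction of the right limb is +x and of the left limb is -x.
    cross = (ankle[0] - hip[0]) * (knee[1] - hip[1]) - (ankle[1] - hip[1]) * (knee[0] - hip[0])
    medial = 1.0 if side == "right" else -1.0
    sign = medial * math.copysign(1.0, cross) if cross != 0.0 else 0.0
    return magnitude * sign if sign != 0.0 else 0.0


# ---------------------------------------------------------------------------
# sequence-level operations
# ---------------------------------------------------------------------------

def _interpolate_gaps(values: np.ndarray, valid: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate entries where ``valid`` is False.

    Gaps longer than ``max_gap`` frames fail the trial; gaps at either edge are
    held at the nearest valid value.
    """
    if valid.all():
        return values
    idx = np.arange(len(values))
    # locate contiguous invalid runs
    invalid = ~valid
    run_start = None
    for i in range(len(values) + 1):
        if i < len(values) and invalid[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > max_gap:
                raise SequenceQualityError(
                    f"low-visibility gap of {i - run_start} frames exceeds the "
                    f"maximum bridgeable gap of {max_gap}"
                )
            run_start = None
    out = values.copy()
    out[invalid] = np.interp(idx[invalid], idx[valid], values[valid])
    return out


def angle_series(
    sequence: LandmarkSequence,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
    smooth_window: Optional[int] = None,
) -> AngleSeries:
    """Compute the three frontal-plane angles for every frame.

    Frames in which any required landmark falls below ``visibility_threshold``
    are linearly interpolated from neighboring valid frames. More than 50%
    low-visibility frames, or a gap longer than ``max_gap``, raises
    :class:`SequenceQualityError`. An optional centered moving average of odd
    width ``smooth_window`` may be applied afterwards (off by default).
    """
    side = sequence.weight_bearing_side
    coords = sequence.coords_array(REQUIRED_LANDMARKS)
    name_ix = {n: i for i, n in enumerate(REQUIRED_LANDMARKS)}

    s_mid = 0.5 * (coords[:, name_ix["left_shoulder"]] + coords[:, name_ix["right_shoulder"]])
    h_mid = 0.5 * (coords[:, name_ix["left_hip"]] + coords[:, name_ix["right_hip"]])
    d_trunk = s_mid - h_mid
    if np.any(np.all(np.isclose(d_trunk, 0.0), axis=1)):
        raise DegenerateGeometryError("shoulder and hip midpoints coincide in a frame")
    trunk = np.degrees(np.arctan2(np.abs(d_trunk[:, 0]), np.abs(d_trunk[:, 1])))

    d_hip = coords[:, name_ix["left_hip"]] - coords[:, name_ix["right_hip"]]
    if np.any(np.all(np.isclose(d_hip, 0.0), axis=1)):
        raise DegenerateGeometryError("hip landmarks coincide in a frame")
    pelvis = np.degrees(np.arctan2(np.abs(d_hip[:, 1]), np.abs(d_hip[:, 0])))

    hip = coords[:, name_ix[f"{side}_hip"]]
    kne = coords[:, name_ix[f"{side}_knee"]]
    ank = coords[:, name_ix[f"{side}_ankle"]]
    v1 = hip - kne
    v2 = ank - kne
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0) or np.any(np.linalg.norm(hip - ank, axis=1) == 0):
        raise DegenerateGeometryError("coincident hip/knee/ankle landmarks in a frame")
    cosang = np.clip(np.einsum("ij,ij->i", v1, v2) / (n1 * n2), -1.0, 1.0)
    magnitude = 180.0 - np.degrees(np.arccos(cosang))
    cross = (ank[:, 0] - hip[:, 0]) * (kne[:, 1] - hip[:, 1]) - (
        ank[:, 1] - hip[:, 1]
    ) * (kne[:, 0] - hip[:, 0])
    medial = 1.0 if side == "right" else -1.0
    knee = magnitude * medial * np.sign(cross)

    vis = sequence.visibility_array(REQUIRED_LANDMARKS).min(axis=1)
    valid = vis >= visibility_threshold
    if valid.sum() < 0.5 * len(valid):
        raise SequenceQualityError(
            f"{(~valid).sum()} of {len(valid)} frames fall below the visibility "
            f"threshold {visibility_threshold}"
        )
    trunk = _interpolate_gaps(trunk, valid, max_gap)
    pelvis = _interpolate_gaps(pelvis, valid, max_gap)
    knee = _interpolate_gaps(knee, valid, max_gap)

    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise SchemaError("smooth_window must be a positive odd integer")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        for arr in (trunk, pelvis, knee):
            padded = np.pad(arr, pad, mode="edge")
            arr[:] = np.convolve(padded, kernel, mode="valid")

    return AngleSeries(trunk=trunk, pelvis=pelvis, knee=knee)


def extract_peaks(series: AngleSeries) -> PeakAngles:
    """Reduce an angle series to per-repetition peak deviations.

    Trunk and pelvic peaks are the maxima of the unsigned series. The knee peak
    is the *signed* value at the frame of maximum absolute knee deviation, so a
    repetition dominated by varus yields a negative peak.
    """
    if len(series) == 0:
        raise SchemaError("cannot extract peaks from an empty angle series")
    knee_ix = int(np.argmax(np.abs(series.knee)))
    return PeakAngles(
        trunk=float(np.max(series.trunk)),
        pelvis=float(np.max(series.pelvis)),
        knee=float(series.knee[knee_ix]),
    )


def peaks_from_sequence(sequence: LandmarkSequence, **kwargs) -> PeakAngles:
    """Convenience composition of :func:`angle_series` and :func:`extract_peaks`."""
    return extract_peaks(angle_series(sequence, **kwargs))
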