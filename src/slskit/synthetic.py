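"""Seeded synthesis of single-leg-squat landmark cohorts.

The generator emulates a screening cohort graded into three ordinal movement
quality classes (0 = good, 1 = moderate, 2 = poor). Per-class peak trunk
lateral tilt, pelvic lateral tilt and knee valgus are drawn from a correlated
trivariate normal whose default means and SDs are the published per-class
cohort statistics; a forward kinematic model then realizes each draw as a 2D
landmark trajectory whose *extracted* kinematics reproduce the drawn peaks
exactly in the noise-free case.

Geometry: y-up coordinates with the weight-bearing ankle at the origin. The
squat is a half-cosine deviation profile: every angle ramps from 0 at stance
to its peak at maximal depth (mid-sequence) and back. With an odd frame count
the mid frame attains the peak exactly, which is what makes the noise-free
generator/extractor round trip exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigError
from .kinematics import LandmarkFrame, LandmarkSequence, PeakAngles

CLASS_NAMES = {0: "good", 1: "moderate", 2: "poor"}

#: Published per-class peak-angle statistics, degrees: (mean, sd) for
#: trunk lateral tilt, pelvic lateral tilt, signed knee valgus.
DEFAULT_CLASS_ANGLE_PARAMS: Dict[int, Dict[str, Tuple[float, float]]] = {
    0: {"trunk": (6.00, 2.47), "pelvis": (6.31, 1.93), "knee": (-2.63, 2.55)},
    1: {"trunk": (7.24, 3.23), "pelvis": (8.50, 2.76), "knee": (3.67, 3.75)},
    2: {"trunk": (10.24, 6.34), "pelvis": (10.38, 4.94), "knee": (13.24, 9.71)},
}

ANGLE_ORDER = ("trunk", "pelvis", "knee")


@dataclass(frozen=True)
class SegmentLengths:
    """Body segment lengths in pixels, scaled for a ~3 m frontal 1080p view."""

    torso: float = 450.0
    pelvis_width: float = 160.0
    thigh: float = 400.0
    shank: float = 380.0
    shoulder_width: float = 300.0

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if not (v > 0 and math.isfinite(v)):
                raise ConfigError(f"segment length {name} must be positive, got {v}")


@dataclass
class GeneratorConfig:
    """Cohort-level configuration for the synthetic landmark generator."""

    n_per_class: Tuple[int, int, int] = (28, 41, 36)
    reps_per_participant: int = 3
    class_angle_params: Dict[int, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_ANGLE_PARAMS.items()}
    )
    #: Either a scalar common pairwise correlation or a full 3x3 matrix over
    #: (trunk, pelvis, knee). Default: moderate positive coupling.
    angle_correlation: Union[float, Sequence[Sequence[float]]] = 0.3
    #: Isotropic Gaussian landmark jitter (pixels). Default 0: the class SDs
    #: already subsume tracking noise observed through the pose estimator.
    landmark_noise_sd: float = 0.0
    frame_rate: float = 30.0
    n_frames: int = 61
    segment_lengths: SegmentLengths = field(default_factory=SegmentLengths)
    weight_bearing_side: str = "right"
    seed: int = 0

    # ------------------------------------------------------------------
    def correlation_matrix(self) -> np.ndarray:
        if np.isscalar(self.angle_correlation):
            r = float(self.angle_correlation)
            mat = np.full((3, 3), r)
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(self.angle_correlation, dtype=float)
        return mat

    def validate(self) -> None:
        if len(self.n_per_class) != 3 or any(n < 0 for n in self.n_per_class):
            raise ConfigError("n_per_class must be three nonnegative counts")
        if sum(self.n_per_class) < 1:
            raise ConfigError("cohort must contain at least one participant")
        if self.reps_per_participant < 1:
            raise ConfigError("reps_per_participant must be >= 1")
        if self.n_frames < 5:
            raise ConfigError("n_frames must be >= 5")
        if self.landmark_noise_sd < 0:
            raise ConfigError("landmark_noise_sd must be >= 0")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.weight_bearing_side not in ("left", "right"):
            raise ConfigError("weight_bearing_side must be 'left' or 'right'")
        self.segment_lengths.validate()
        for c in (0, 1, 2):
            if c not in self.class_angle_params:
                raise ConfigError(f"class_angle_params missing class {c}")
            for angle in ANGLE_ORDER:
                mean, sd = self.class_angle_params[c][angle]
                if sd < 0:
                    raise ConfigError(f"SD for class {c} {angle} must be >= 0")
        mat = self.correlation_matrix()
        if mat.shape != (3, 3) or not np.allclose(mat, mat.T):
            raise ConfigError("angle_correlation must be a symmetric 3x3 structure")
        if np.min(np.linalg.eigvalsh(mat)) < -1e-9:
            raise ConfigError("angle_correlation must be positive semidefinite")


@dataclass
class SyntheticTrial:
    """One synthesized repetition with its generating targets."""

    participant_id: str
    repetition_index: int  # 1-based
    sequence: LandmarkSequence
    true_peaks: PeakAngles
    true_class: int


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sqrt_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix (handles singular structures)."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


def sample_peak_targets(
    config: GeneratorConfig, class_id: int, rng: np.random.Generator
) -> PeakAngles:
    """Draw one (trunk, pelvis, knee) peak-angle target for the given class.

    Draws come from the class-conditional correlated normal. Trunk and pelvic
    tilts are magnitudes: the rare negative draw is clamped to 0 (for the
    published class parameters this touches at most ~5% of draws and keeps
    the class-conditional means within a small, analytically bounded offset
    of the configured means; resampling instead would bias all three angles
    through the correlation). Knee valgus is unbounded below (negative =
    varus).
    """
    if class_id not in (0, 1, 2):
        raise ConfigError(f"unknown class id {class_id!r}; expected 0, 1 or 2")
    params = config.class_angle_params[class_id]
    mean = np.array([params[a][0] for a in ANGLE_ORDER])
    sd = np.array([params[a][1] for a in ANGLE_ORDER])
    transform = np.diag(sd) @ _sqrt_psd(config.correlation_matrix())
    draw = mean + transform @ rng.standard_normal(3)
    return PeakAngles(
        trunk=float(max(draw[0], 0.0)),
        pelvis=float(max(draw[1], 0.0)),
        knee=float(draw[2]),
    )


# ---------------------------------------------------------------------------
# forward kinematic landmark model
# ---------------------------------------------------------------------------

def _pose_landmarks(
    trunk_deg: float,
    pelvis_deg: float,
    knee_deg: float,
    side: str,
    seg: SegmentLengths,
) -> Dict[str, Tuple[float, float]]:
    """Place the eight landmarks realizing the requested frontal-plane angles.

    The weight-bearing ankle sits at the origin with the hip of that side on
    the vertical through it, so the knee's medial offset alone encodes valgus.
    """
    m = 1.0 if side == "right" else -1.0  # medial direction of the WB limb
    other = "left" if side == "right" else "right"

    # weight-bearing leg: hip-knee-ankle triangle with the prescribed exterior
    # angle at the knee; the hip-ankle distance follows from the law of cosines
    phi = math.radians(180.0 - abs(knee_deg))  # interior knee angle
    ls, lt = seg.shank, seg.thigh
    d = math.sqrt(ls * ls + lt * lt - 2.0 * ls * lt * math.cos(phi))
    beta = math.asin(min(1.0, lt * math.sin(phi) / d))  # angle at the ankle
    ankle_wb = np.array([0.0, 0.0])
    hip_wb = np.array([0.0, d])
    offset_dir = m * math.copysign(1.0, knee_deg) if knee_deg != 0.0 else 0.0
    knee_wb = np.array([ls * math.sin(beta) * offset_dir, ls * math.cos(beta)])

    # pelvis: contralateral hip drops by the pelvic tilt angle
    p = math.radians(pelvis_deg)
    hip_other = hip_wb + seg.pelvis_width * np.array([m * math.cos(p), -math.sin(p)])

    # trunk: shoulder midpoint leans over the stance limb by the trunk tilt
    t = math.radians(trunk_deg)
    hip_mid = 0.5 * (hip_wb + hip_other)
    s_mid = hip_mid + seg.torso * np.array([-m * math.sin(t), math.cos(t)])
    half_sw = 0.5 * seg.shoulder_width
    shoulder_left = s_mid + np.array([half_sw, 0.0])
    shoulder_right = s_mid - np.array([half_sw, 0.0])

    # non-weight-bearing leg: held flexed behind; placement is schematic
    knee_other = hip_other + np.array([m * 0.15 * seg.thigh, -0.6 * seg.thigh])
    ankle_other = knee_other + np.array([m * 0.05 * seg.shank, -0.35 * seg.shank])

    out = {
        "left_shoulder": tuple(shoulder_left),
        "right_shoulder": tuple(shoulder_right),
        f"{side}_hip": tuple(hip_wb),
        f"{other}_hip": tuple(hip_other),
        f"{side}_knee": tuple(knee_wb),
        f"{other}_knee": tuple(knee_other),
        f"{side}_ankle": tuple(ankle_wb),
        f"{other}_ankle": tuple(ankle_other),
    }
    return out


def depth_profile(n_frames: int) -> np.ndarray:
    """Half-cosine descend/ascend scaling in [0, 1] with its peak mid-sequence."""
    t = np.arange(n_frames)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / (n_frames - 1)))


def synthesize_trial(
    peaks: PeakAngles,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "P000",
    repetition_index: int = 1,
    true_class: int = 0,
) -> SyntheticTrial:
    """Realize one repetition whose extracted peak angles equal ``peaks``.

    With ``landmark_noise_sd`` 0 the kinematics module recovers the targets to
    well under 1e-6 degrees; with noise, isotropic Gaussian jitter is added to
    every landmark in every frame.
    """
    for name, v in zip(ANGLE_ORDER, peaks.as_tuple()):
        if not math.isfinite(v):
            raise ConfigError(f"peak {name} is not finite")
        if abs(v) > 90.0:
            raise ConfigError(f"peak {name}={v} deg is geometrically infeasible (>90)")
    if peaks.trunk < 0 or peaks.pelvis < 0:
        raise ConfigError("trunk and pelvic peaks are magnitudes and must be >= 0")
    config.segment_lengths.validate()

    scale = depth_profile(config.n_frames)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noise_sd = config.landmark_noise_sd
    frames: List[LandmarkFrame] = []
    for i, s in enumerate(scale):
        coords = _pose_landmarks(
            s * peaks.trunk,
            s * peaks.pelvis,
            s * peaks.knee,
            config.weight_bearing_side,
            config.segment_lengths,
        )
        if noise_sd > 0:
            coords = {
                k: (x + rng.normal(0.0, noise_sd), y + rng.normal(0.0, noise_sd))
                for k, (x, y) in coords.items()
            }
        frames.append(
            LandmarkFrame(
                timestamp=i / config.frame_rate,
                coordinates=coords,
                visibility={},
            )
        )
    seq = LandmarkSequence(
        frames=frames,
        frame_rate=config.frame_rate,
        weight_bearing_side=config.weight_bearing_side,
    )
    return SyntheticTrial(
        participant_id=participant_id,
        repetition_index=repetition_index,
        sequence=seq,
        true_peaks=peaks,
        true_class=true_class,
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort(config: GeneratorConfig) -> List[SyntheticTrial]:
    """Generate a full cohort of repetitions, grouped by participant.

    Each participant is assigned a class; repetition-level classes are drawn
    from classes <= the assigned class with one repetition pinned at the
    assigned class, so the participant's *worst* repetition always matches the
    assigned label (the poorest-repetition labeling rule).
    Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials: List[SyntheticTrial] = []
    pid = 0
    for class_id, n in enumerate(config.n_per_class):
        for _ in range(n):
            pid += 1
            participant = f"P{pid:03d}"
            reps = config.reps_per_participant
            worst = int(rng.integers(reps))
            rep_classes = [
                class_id if r == worst else int(rng.integers(0, class_id + 1))
                for r in range(reps)
            ]
            for r, rep_class in enumerate(rep_classes):
                peaks = sample_peak_targets(config, rep_class, rng)
                trials.append(
                    synthesize_trial(
                        peaks,
                        config,
                        rng=rng,
                        participant_id=participant,
                        repetition_index=r + 1,
                        true_class=rep_class,
                    )
                )
    return trials


def group_by_participant(trials: Sequence[SyntheticTrial]) -> Dict[str, List[SyntheticTrial]]:
    groups: Dict[str, List[SyntheticTrial]] = {}
    for t in trials:
        groups.setdefault(t.participant_id, []).append(t)
    for reps in groups.values():
        reps.sort(key=lambda t: t.repetition_index)
    return groups
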