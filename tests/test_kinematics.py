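"""Frame-level angle geometry, series extraction and their invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slskit import (
    DegenerateGeometryError,
    LandmarkFrame,
    LandmarkSequence,
    PeakAngles,
    SequenceQualityError,
    angle_series,
    extract_peaks,
    knee_valgus_frame,
    pelvic_tilt_frame,
    trunk_tilt_frame,
)
from slskit.kinematics import AngleSeries, REQUIRED_LANDMARKS

from conftest import oracle_angle_between, oracle_axis_angle


def frame_with(**overrides) -> LandmarkFrame:
    """A neutral upright frame with selected landmarks overridden."""
    coords = {
        "left_shoulder": (0.6, 2.0),
        "right_shoulder": (-0.6, 2.0),
        "left_hip": (0.3, 1.0),
        "right_hip": (-0.3, 1.0),
        "left_knee": (0.3, 0.5),
        "right_knee": (-0.3, 0.5),
        "left_ankle": (0.3, 0.0),
        "right_ankle": (-0.3, 0.0),
    }
    coords.update(overrides)
    return LandmarkFrame(timestamp=0.0, coordinates=coords)


def shoulders_at(mid, width=1.0):
    return {
        "left_shoulder": (mid[0] + width / 2, mid[1]),
        "right_shoulder": (mid[0] - width / 2, mid[1]),
    }


def hips_at(mid, width=0.6):
    return {
        "left_hip": (mid[0] + width / 2, mid[1]),
        "right_hip": (mid[0] - width / 2, mid[1]),
    }


class TestTrunkTilt:
    @pytest.mark.parametrize(
        "s_mid,h_mid,expected",
        [
            ((0.0, 2.0), (0.0, 1.0), 0.0),  # vertical torso
            ((1.0, 2.0), (0.0, 1.0), 45.0),  # arctan(1/1)
            ((0.1045, 1.9945), (0.0, 1.0), 6.00),  # good-group scale
        ],
    )
    def test_examples(self, s_mid, h_mid, expected):
        frame = frame_with(**shoulders_at(s_mid), **hips_at(h_mid))
        assert trunk_tilt_frame(frame) == pytest.approx(expected, abs=5e-3)

    def test_degenerate_midpoints_raise(self):
        frame = frame_with(**shoulders_at((0.0, 1.0)), **hips_at((0.0, 1.0)))
        with pytest.raises(DegenerateGeometryError):
            trunk_tilt_frame(frame)


class TestPelvicTilt:
    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ((1.0, 1.0), (-1.0, 1.0), 0.0),  # level pelvis
            ((1.0, 1.0 + 2.0 * math.tan(math.radians(10.0))), (-1.0, 1.0), 10.0),
            ((0.0, 1.0), (0.0, 0.0), 90.0),  # vertical limit
        ],
    )
    def test_examples(self, left, right, expected):
        frame = frame_with(left_hip=left, right_hip=right)
        assert pelvic_tilt_frame(frame) == pytest.approx(expected, abs=1e-9)

    def test_coincident_hips_raise(self):
        frame = frame_with(left_hip=(0.0, 1.0), right_hip=(0.0, 1.0))
        with pytest.raises(DegenerateGeometryError):
            pelvic_tilt_frame(frame)


class TestKneeValgus:
    def test_collinear_chain_is_zero(self):
        frame = frame_with(
            right_hip=(0.0, 2.0), right_knee=(0.0, 1.0), right_ankle=(0.0, 0.0)
        )
        assert knee_valgus_frame(frame, "right") == 0.0

    @pytest.mark.parametrize("valgus", [13.24, 5.0, 45.0])
    def test_constructed_valgus_and_mirror(self, valgus):
        """Rotate the shank so the interior angle is 180 - valgus; the mirror
        configuration across the hip->ankle line flips only the sign."""
        hip = np.array([0.0, 2.0])
        knee = np.array([0.0, 1.0])
        # medial direction of the right limb is +x
        ang = math.radians(180.0 - valgus)
        thigh_dir = (hip - knee) / np.linalg.norm(hip - knee)
        rot = np.array(
            [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
        )
        ankle = knee + rot @ thigh_dir  # interior angle at knee = 180 - valgus
        if ankle[0] - knee[0] > 0:  # ensure the knee sits medial (valgus)
            rot = rot.T
            ankle = knee + rot @ thigh_dir
        frame = frame_with(right_hip=tuple(hip), right_knee=tuple(knee), right_ankle=tuple(ankle))
        got = knee_valgus_frame(frame, "right")
        assert got == pytest.approx(valgus, abs=1e-9)
        mirror = frame_with(
            right_hip=(-hip[0], hip[1]),
            right_knee=(-knee[0], knee[1]),
            right_ankle=(-ankle[0], ankle[1]),
        )
        assert knee_valgus_frame(mirror, "right") == pytest.approx(-valgus, abs=1e-9)

    def test_coincident_landmarks_raise(self):
        frame = frame_with(right_knee=(-0.3, 0.0), right_ankle=(-0.3, 0.0))
        with pytest.raises(DegenerateGeometryError):
            knee_valgus_frame(frame, "right")


class TestOracleEquivalence:
    def test_matches_arccos_oracle_on_random_placements(self, rng):
        """All three frame angles agree with a brute-force arccos oracle."""
        for _ in range(2000):
            pts = rng.normal(0.0, 1.0, size=(8, 2))
            names = list(REQUIRED_LANDMARKS)
            coords = {n: tuple(p) for n, p in zip(names, pts)}
            frame = LandmarkFrame(timestamp=0.0, coordinates=coords)
            s_mid = 0.5 * (pts[0] + pts[1])
            h_mid = 0.5 * (pts[2] + pts[3])
            if np.allclose(s_mid, h_mid):
                continue
            exp_trunk = oracle_axis_angle(s_mid - h_mid, (0.0, 1.0))
            assert trunk_tilt_frame(frame) == pytest.approx(exp_trunk, abs=1e-9)
            exp_pelvis = oracle_axis_angle(pts[2] - pts[3], (1.0, 0.0))
            assert pelvic_tilt_frame(frame) == pytest.approx(exp_pelvis, abs=1e-9)
            hip, knee, ankle = pts[3], pts[5], pts[7]  # right side
            exp_mag = 180.0 - oracle_angle_between(hip - knee, ankle - knee)
            assert abs(knee_valgus_frame(frame, "right")) == pytest.approx(
                exp_mag, abs=1e-9
            )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    tx=st.floats(-50, 50),
    ty=st.floats(-50, 50),
    scale=st.floats(0.1, 20),
)
def test_similarity_invariance(tx, ty, scale):
    """Uniform translation and scaling leave all three angles unchanged."""
    frame = frame_with(
        **shoulders_at((0.4, 2.1)),
        **hips_at((0.1, 1.0)),
        right_knee=(-0.45, 0.52),
    )
    moved = LandmarkFrame(
        timestamp=0.0,
        coordinates={
            n: (scale * (x + tx), scale * (y + ty))
            for n, (x, y) in frame.coordinates.items()
        },
    )
    assert trunk_tilt_frame(moved) == pytest.approx(trunk_tilt_frame(frame), abs=1e-8)
    assert pelvic_tilt_frame(moved) == pytest.approx(pelvic_tilt_frame(frame), abs=1e-8)
    assert knee_valgus_frame(moved, "right") == pytest.approx(
        knee_valgus_frame(frame, "right"), abs=1e-8
    )


def test_mirror_flips_knee_sign_only():
    frame = frame_with(
        **shoulders_at((0.4, 2.1)),
        **hips_at((0.1, 1.0)),
        right_knee=(-0.45, 0.52),
    )
    mirrored = LandmarkFrame(
        timestamp=0.0,
        coordinates={n: (-x, y) for n, (x, y) in frame.coordinates.items()},
    )
    assert trunk_tilt_frame(mirrored) == pytest.approx(trunk_tilt_frame(frame), abs=1e-9)
    assert pelvic_tilt_frame(mirrored) == pytest.approx(pelvic_tilt_frame(frame), abs=1e-9)
    assert knee_valgus_frame(mirrored, "right") == pytest.approx(
        -knee_valgus_frame(frame, "right"), abs=1e-9
    )


class TestAngleSeries:
    def make_sequence(self, n=10, visibility=None):
        frames = []
        for i in range(n):
            f = frame_with()
            vis = {} if visibility is None else {k: visibility[i] for k in REQUIRED_LANDMARKS}
            frames.append(
                LandmarkFrame(timestamp=i / 30.0, coordinates=f.coordinates, visibility=vis)
            )
        return LandmarkSequence(frames=frames, frame_rate=30.0, weight_bearing_side="right")

    def test_neutral_sequence_is_all_zero(self):
        series = angle_series(self.make_sequence())
        assert np.allclose(series.trunk, 0.0)
        assert np.allclose(series.pelvis, 0.0)
        assert np.allclose(series.knee, 0.0)

    def test_low_visibility_frame_interpolated(self):
        n = 9
        frames = []
        for i in range(n):
            # pelvis tilts linearly over the sequence
            tilt = i * 1.0
            dy = 0.6 * math.tan(math.radians(tilt))
            f = frame_with(left_hip=(0.3, 1.0 + dy), right_hip=(-0.3, 1.0))
            vis = {k: (0.1 if i == 4 else 1.0) for k in REQUIRED_LANDMARKS}
            frames.append(
                LandmarkFrame(timestamp=i / 30.0, coordinates=f.coordinates, visibility=vis)
            )
        seq = LandmarkSequence(frames=frames, frame_rate=30.0, weight_bearing_side="right")
        series = angle_series(seq)
        expected = 0.5 * (series.pelvis[3] + series.pelvis[5])
        assert series.pelvis[4] == pytest.approx(expected, abs=1e-9)

    def test_majority_low_visibility_fails(self):
        vis = [0.1] * 6 + [1.0] * 4
        with pytest.raises(SequenceQualityError):
            angle_series(self.make_sequence(10, visibility=vis))

    def test_long_gap_fails(self):
        vis = [1.0, 1.0] + [0.1] * 6 + [1.0] * 6
        with pytest.raises(SequenceQualityError):
            angle_series(self.make_sequence(14, visibility=vis))


class TestExtractPeaks:
    def test_all_zero_series(self):
        series = AngleSeries(np.zeros(5), np.zeros(5), np.zeros(5))
        assert extract_peaks(series) == PeakAngles(0.0, 0.0, 0.0)

    def test_knee_peak_keeps_sign_of_max_magnitude(self):
        series = AngleSeries(
            np.zeros(4), np.zeros(4), np.array([-3.0, -2.63, -1.0, 0.0])
        )
        assert extract_peaks(series).knee == -3.0

    def test_appending_sub_peak_frames_never_changes_output(self, rng):
        trunk = rng.uniform(0, 20, 12)
        pelvis = rng.uniform(0, 20, 12)
        knee = rng.uniform(-20, 20, 12)
        base = extract_peaks(AngleSeries(trunk, pelvis, knee))
        ext = extract_peaks(
            AngleSeries(
                np.append(trunk, trunk.max() - 1e-6),
                np.append(pelvis, pelvis.max() - 1e-6),
                np.append(knee, 0.0),
            )
        )
        assert ext == base
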