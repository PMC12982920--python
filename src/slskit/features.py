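"""Engineered kinematic feature set for movement-quality classification.

From the three per-repetition peak angles (trunk lateral tilt, pelvic lateral
tilt, signed knee valgus) a fixed 17-feature representation is built: the 3
primary angles, 7 ratio features, 3 interaction terms, 3 nonlinear (squared)
terms, and the composite summated angle (trunk + pelvis + knee). The ratio
and interaction terms encode inter-segment coordination (e.g. how much knee
deviation occurs per degree of trunk lean) that single-joint criteria miss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidTrialError, SchemaError
from .kinematics import PeakAngles

#: Fixed feature schema: 3 primary, 7 ratio, 3 interaction, 3 nonlinear, 1 composite.
FEATURE_NAMES: Tuple[str, ...] = (
    "trunk",
    "pelvis",
    "knee",
    "knee_over_trunk",
    "knee_sq_over_trunk",
    "knee_over_pelvis",
    "knee_sq_over_pelvis",
    "knee_over_trunk_plus_pelvis",
    "knee_sq_over_trunk_plus_pelvis",
    "trunk_over_pelvis",
    "trunk_x_knee",
    "trunk_x_pelvis",
    "pelvis_x_knee",
    "trunk_sq",
    "pelvis_sq",
    "knee_sq",
    "summated",
)

LABEL_COLUMN = "label"
ID_COLUMN = "participant_id"

#: Ratio denominators with magnitude below this are clamped (sign-preserving).
DENOMINATOR_GUARD = 1e-6


def _guard(d: float) -> float:
    if abs(d) >= DENOMINATOR_GUARD:
        return d
    return DENOMINATOR_GUARD if d >= 0 else -DENOMINATOR_GUARD


def engineer_features(peaks: PeakAngles) -> Dict[str, float]:
    """Compute the 17-feature vector from one repetition's peak angles.

    The signed knee peak enters the ratio and interaction terms directly
    (varus contributes negatively); squared terms discard the sign.
    """
    t, p, k = peaks.trunk, peaks.pelvis, peaks.knee
    for name, v in (("trunk", t), ("pelvis", p), ("knee", k)):
        if not math.isfinite(v):
            raise SchemaError(f"peak {name} is not finite")
    k2 = k * k
    tp = t + p
    vec = {
        "trunk": t,
        "pelvis": p,
        "knee": k,
        "knee_over_trunk": k / _guard(t),
        "knee_sq_over_trunk": k2 / _guard(t),
        "knee_over_pelvis": k / _guard(p),
        "knee_sq_over_pelvis": k2 / _guard(p),
        "knee_over_trunk_plus_pelvis": k / _guard(tp),
        "knee_sq_over_trunk_plus_pelvis": k2 / _guard(tp),
        "trunk_over_pelvis": t / _guard(p),
        "trunk_x_knee": t * k,
        "trunk_x_pelvis": t * p,
        "pelvis_x_knee": p * k,
        "trunk_sq": t * t,
        "pelvis_sq": p * p,
        "knee_sq": k2,
        "summated": t + p + k,
    }
    return vec


def aggregate_participant(
    rep_labels: Sequence[int],
    rep_peaks: Sequence[PeakAngles],
) -> Tuple[Dict[str, float], int, int]:
    """Reduce a participant's repetitions to one feature vector and label.

    The participant label is the worst (maximum) repetition label; features
    come from the poorest-rated repetition, and when several repetitions tie
    at the worst label the earliest one is used. Returns
    ``(features, label, chosen_repetition_index)`` (0-based index).
    """
    if len(rep_labels) == 0 or len(rep_labels) != len(rep_peaks):
        raise InvalidTrialError("participant has no valid repetitions to aggregate")
    labels = [int(l) for l in rep_labels]
    if any(l not in (0, 1, 2) for l in labels):
        raise SchemaError(f"repetition labels must be in {{0,1,2}}, got {labels}")
    worst = max(labels)
    chosen = labels.index(worst)  # earliest among ties
    return engineer_features(rep_peaks[chosen]), worst, chosen


def build_feature_table(
    records: Iterable[Tuple[str, Dict[str, float], int]]
) -> pd.DataFrame:
    """Assemble per-participant rows into a feature table.

    ``records`` yields (participant_id, feature dict, label). The resulting
    frame has the participant id, the 17 features in schema order, and the
    ordinal label.
    """
    rows = []
    for pid, feats, label in records:
        missing = [n for n in FEATURE_NAMES if n not in feats]
        if missing:
            raise SchemaError(f"feature vector for {pid} missing {missing}")
        row = {ID_COLUMN: pid, **{n: float(feats[n]) for n in FEATURE_NAMES}, LABEL_COLUMN: int(label)}
        rows.append(row)
    if not rows:
        raise SchemaError("no participant records supplied")
    table = pd.DataFrame(rows, columns=[ID_COLUMN, *FEATURE_NAMES, LABEL_COLUMN])
    validate_feature_table(table)
    return table


def validate_feature_table(table: pd.DataFrame) -> None:
    missing = [c for c in (ID_COLUMN, LABEL_COLUMN, *FEATURE_NAMES) if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns {missing}")
    if table[list(FEATURE_NAMES)].isna().any().any():
        raise SchemaError("feature table contains missing values")
    if not set(table[LABEL_COLUMN].unique()).issubset({0, 1, 2}):
        raise SchemaError("labels must be drawn from {0, 1, 2}")


def feature_matrix(table: pd.DataFrame, features: Optional[Sequence[str]] = None) -> np.ndarray:
    names = list(features) if features is not None else list(FEATURE_NAMES)
    return table[names].to_numpy(dtype=float)


def labels(table: pd.DataFrame) -> np.ndarray:
    return table[LABEL_COLUMN].to_numpy(dtype=int)
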