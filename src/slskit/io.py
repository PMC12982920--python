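"""Reading and writing landmark files, feature tables and reports.

Landmark files follow the layout of 33-landmark pose-estimator output (one
row per frame, ``<landmark>_x/_y/_v`` columns, or an equivalent JSON frame
list). Image coordinates are y-down and often normalized to [0, 1]; the
reader converts to the package's internal y-up pixel convention so the
geometry code never sees dialect details.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .features import FEATURE_NAMES, ID_COLUMN, LABEL_COLUMN, validate_feature_table
from .kinematics import REQUIRED_LANDMARKS, LandmarkFrame, LandmarkSequence
from .selection import SelectionResult
from .stability import InstabilityCurve

#: Index of each required landmark in the 33-point pose-estimator layout.
POSE33_INDICES: Dict[str, int] = {
    "left_shoulder": 11,
    "right_shoulder": 12,
    "left_hip": 23,
    "right_hip": 24,
    "left_knee": 25,
    "right_knee": 26,
    "left_ankle": 27,
    "right_ankle": 28,
}


@dataclass
class LandmarkDialect:
    """How a landmark file encodes coordinates.

    ``normalized``: coordinates lie in [0, 1] and are scaled by the image
    size on read. ``y_down``: the y axis points down (image convention) and
    is flipped on read. The defaults match common pose-estimator output.
    """

    normalized: bool = True
    y_down: bool = True
    image_width: float = 1080.0
    image_height: float = 1920.0

    def to_internal(self, x: np.ndarray, y: np.ndarray) -> tuple:
        if self.normalized:
            x = x * self.image_width
            y = y * self.image_height
        if self.y_down:
            y = self.image_height - y
        return x, y

    def from_internal(self, x: np.ndarray, y: np.ndarray) -> tuple:
        if self.y_down:
            y = self.image_height - y
        if self.normalized:
            x = x / self.image_width
            y = y / self.image_height
        return x, y


def read_landmarks(
    path: Union[str, Path],
    dialect: Optional[LandmarkDialect] = None,
    frame_rate: float = 30.0,
    weight_bearing_side: Optional[str] = None,
) -> LandmarkSequence:
    """Read a landmark CSV or JSON file into a :class:`LandmarkSequence`.

    CSV: one row per frame, columns ``<landmark>_x``, ``<landmark>_y`` and
    optionally ``<landmark>_v`` (visibility) for at least the eight required
    landmarks; an optional ``timestamp`` column, else timestamps derive from
    ``frame_rate``. JSON: an object with ``frame_rate``,
    ``weight_bearing_side`` and a ``frames`` list. Extra (pass-through)
    landmark columns are ignored.
    """
    path = Path(path)
    dialect = dialect or LandmarkDialect()
    if path.suffix.lower() == ".json":
        return _read_landmarks_json(path, dialect, frame_rate, weight_bearing_side)
    return _read_landmarks_csv(path, dialect, frame_rate, weight_bearing_side)


def _read_landmarks_csv(path, dialect, frame_rate, weight_bearing_side):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface the offending file
        raise SchemaError(f"could not parse landmark file {path}: {exc}") from exc
    for name in REQUIRED_LANDMARKS:
        for ax in ("x", "y"):
            if f"{name}_{ax}" not in df.columns:
                raise SchemaError(f"landmark file {path} missing column {name}_{ax}")
    if "timestamp" in df.columns:
        ts = df["timestamp"].to_numpy(dtype=float)
        if not np.all(np.diff(ts) > 0):
            raise SchemaError(f"non-monotone timestamps in {path}")
    else:
        ts = np.arange(len(df)) / frame_rate
    side = weight_bearing_side
    if side is None:
        if "weight_bearing_side" in df.columns:
            side = str(df["weight_bearing_side"].iloc[0])
        else:
            raise SchemaError(
                f"weight-bearing side for {path} must be given as an argument or column"
            )
    frames = []
    for i in range(len(df)):
        coords = {}
        vis = {}
        for name in REQUIRED_LANDMARKS:
            x, y = dialect.to_internal(
                np.float64(df[f"{name}_x"].iloc[i]), np.float64(df[f"{name}_y"].iloc[i])
            )
            coords[name] = (float(x), float(y))
            vcol = f"{name}_v"
            if vcol in df.columns:
                vis[name] = float(df[vcol].iloc[i])
        frames.append(LandmarkFrame(timestamp=float(ts[i]), coordinates=coords, visibility=vis))
    return LandmarkSequence(frames=frames, frame_rate=frame_rate, weight_bearing_side=side)


def _read_landmarks_json(path, dialect, frame_rate, weight_bearing_side):
    with open(path) as fh:
        doc = json.load(fh)
    fr = float(doc.get("frame_rate", frame_rate))
    side = weight_bearing_side or doc.get("weight_bearing_side")
    if side is None:
        raise SchemaError(f"weight-bearing side missing for {path}")
    frames = []
    for i, entry in enumerate(doc.get("frames", [])):
        coords = {}
        vis = {}
        lms = entry.get("landmarks", {})
        for name in REQUIRED_LANDMARKS:
            if name not in lms:
                raise SchemaError(f"landmark file {path} missing landmark {name}")
            x, y = dialect.to_internal(
                np.float64(lms[name]["x"]), np.float64(lms[name]["y"])
            )
            coords[name] = (float(x), float(y))
            if "visibility" in lms[name]:
                vis[name] = float(lms[name]["visibility"])
        frames.append(
            LandmarkFrame(
                timestamp=float(entry.get("timestamp", i / fr)),
                coordinates=coords,
                visibility=vis,
            )
        )
    return LandmarkSequence(frames=frames, frame_rate=fr, weight_bearing_side=side)


def write_landmarks(
    sequence: LandmarkSequence,
    path: Union[str, Path],
    dialect: Optional[LandmarkDialect] = None,
) -> Path:
    """Write a sequence as a wide CSV in the given dialect (round-trip safe)."""
    path = Path(path)
    dialect = dialect or LandmarkDialect()
    rows = []
    for f in sequence.frames:
        row: Dict[str, float] = {"timestamp": f.timestamp}
        for name in REQUIRED_LANDMARKS:
            x, y = f.coordinates[name]
            ox, oy = dialect.from_internal(np.float64(x), np.float64(y))
            row[f"{name}_x"] = float(ox)
            row[f"{name}_y"] = float(oy)
            row[f"{name}_v"] = f.vis(name)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["weight_bearing_side"] = sequence.weight_bearing_side
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# tables and reports
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    validate_feature_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_feature_table(table)
    return table


def write_selection_report(result: SelectionResult, csv_path, json_path=None) -> Path:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    result.stats.to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "filter_set": result.filter_set,
            "wrapper_set": result.wrapper_set,
            "final_set": result.final_set,
            "fallback_used": result.fallback_used,
            "cv_curve": result.cv_curve.to_dict(orient="records"),
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))
    return csv_path


def write_metrics(reports, csv_path, json_path=None) -> Path:
    from .modeling import reports_table

    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    reports_table(reports).to_csv(csv_path, index=False)
    if json_path is not None:
        bundle = [
            {
                **r.to_row(),
                "confusion_matrix": np.asarray(r.confusion_matrix).tolist(),
                "per_class_f1": {str(k): v for k, v in r.per_class_f1.items()},
                "best_params": {k: repr(v) for k, v in r.best_params.items()},
            }
            for r in reports
        ]
        Path(json_path).write_text(json.dumps(bundle, indent=2))
    return csv_path


def write_instability_curve(curve: InstabilityCurve, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    curve.table.to_csv(path, index=False)
    return path


def load_config_file(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return doc
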