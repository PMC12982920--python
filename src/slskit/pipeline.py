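"""End-to-end orchestration: simulate/ingest -> extract -> engineer -> split
-> select -> train -> evaluate -> stability -> explain.

Every run writes its artifacts plus a manifest recording seeds, a config
hash and package versions; rerunning with an identical config reproduces the
deterministic outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .errors import ConfigError, SchemaError
from .features import (
    FEATURE_NAMES,
    aggregate_participant,
    build_feature_table,
)
from .io import (
    LandmarkDialect,
    read_landmarks,
    write_feature_table,
    write_instability_curve,
    write_metrics,
    write_selection_report,
)
from .kinematics import peaks_from_sequence
from .modeling import (
    CLASSIFIER_NAMES,
    SplitSpec,
    evaluate_all,
    stratified_split,
    train_all,
)
from .selection import hybrid_select
from .stability import DEFAULT_FRACTIONS, instability_curve
from .explain import global_attributions, local_explanation
from .synthetic import GeneratorConfig, SyntheticTrial, group_by_participant, sample_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    out_dir: Union[str, Path] = "slskit_run"
    landmark_dir: Optional[Union[str, Path]] = None  # None -> simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    alpha: float = 0.05
    folds: int = 5
    test_fraction: float = 0.30
    stability_fractions: Sequence[float] = DEFAULT_FRACTIONS
    n_boot: int = 100
    stability_classifiers: Sequence[str] = CLASSIFIER_NAMES
    n_perturb: int = 5000
    classifiers: Sequence[str] = CLASSIFIER_NAMES
    grids: Optional[Dict[str, Dict[str, list]]] = None
    run_stability: bool = True
    run_explain: bool = True
    dialect: LandmarkDialect = field(default_factory=LandmarkDialect)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def cohort_feature_table(trials: Sequence[SyntheticTrial]) -> pd.DataFrame:
    """Extract kinematics from synthesized trials and aggregate to the
    participant level (poorest-repetition rule)."""
    records = []
    for pid, reps in group_by_participant(trials).items():
        peaks = [peaks_from_sequence(t.sequence) for t in reps]
        rep_labels = [t.true_class for t in reps]
        feats, label, _ = aggregate_participant(rep_labels, peaks)
        records.append((pid, feats, label))
    return build_feature_table(records)


def simulate_feature_table(config: GeneratorConfig) -> pd.DataFrame:
    """Sample a cohort and run it through extraction + aggregation."""
    return cohort_feature_table(sample_cohort(config))


def ingest_feature_table(
    landmark_dir: Union[str, Path],
    manifest_csv: Union[str, Path],
    dialect: Optional[LandmarkDialect] = None,
) -> pd.DataFrame:
    """Build a participant feature table from a directory of landmark files.

    ``manifest_csv`` must list one row per repetition with columns
    ``participant_id``, ``repetition``, ``label``, ``file`` and optionally
    ``weight_bearing_side``. A file that fails to parse names itself in the
    raised error.
    """
    manifest = pd.read_csv(manifest_csv)
    for col in ("participant_id", "repetition", "label", "file"):
        if col not in manifest.columns:
            raise SchemaError(f"ingest manifest missing column {col!r}")
    landmark_dir = Path(landmark_dir)
    records = []
    for pid, group in manifest.groupby("participant_id", sort=True):
        group = group.sort_values("repetition")
        peaks, rep_labels = [], []
        for _, row in group.iterrows():
            fpath = landmark_dir / str(row["file"])
            side = row.get("weight_bearing_side")
            try:
                seq = read_landmarks(
                    fpath,
                    dialect=dialect,
                    weight_bearing_side=None if pd.isna(side) else str(side),
                )
                peaks.append(peaks_from_sequence(seq))
            except SchemaError as exc:
                raise SchemaError(f"ingest failed for {fpath}: {exc}") from exc
            rep_labels.append(int(row["label"]))
        feats, label, _ = aggregate_participant(rep_labels, peaks)
        records.append((str(pid), feats, label))
    return build_feature_table(records)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full workflow and write all artifacts under ``out_dir``.

    Returns a dict of in-memory artifacts (feature table, selection result,
    reports, curve, attributions, manifest path). A stage failure halts the
    run with the failing stage named; artifacts written so far remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "package_version": _version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "generator_seed": config.generator.seed,
        "stages": {},
        "warnings": [],
    }
    artifacts: Dict[str, object] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if config.landmark_dir is None:
            table = simulate_feature_table(config.generator)
        else:
            stage = "ingest"
            table = ingest_feature_table(
                config.landmark_dir,
                Path(config.landmark_dir) / "manifest.csv",
                dialect=config.dialect,
            )
        write_feature_table(table, out / "features.csv")
        artifacts["features"] = table
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        logger.info("%s: %d participants", stage, len(table))

        stage = "split"
        t0 = time.perf_counter()
        train, test = stratified_split(
            table, SplitSpec(test_fraction=config.test_fraction, seed=config.seed)
        )
        artifacts["train"], artifacts["test"] = train, test
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_train": len(train),
            "n_test": len(test),
        }

        stage = "select"
        t0 = time.perf_counter()
        selection = hybrid_select(
            train, alpha=config.alpha, folds=config.folds, seed=config.seed
        )
        write_selection_report(
            selection, out / "selection.csv", out / "selection.json"
        )
        artifacts["selection"] = selection
        if selection.fallback_used:
            manifest["warnings"].append("selection fell back to the wrapper set")
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "final_set": selection.final_set,
        }

        stage = "train"
        t0 = time.perf_counter()
        fitted = train_all(
            train,
            selection.final_set,
            grids=config.grids,
            folds=config.folds,
            seed=config.seed,
            classifiers=config.classifiers,
        )
        artifacts["models"] = fitted
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        stage = "evaluate"
        t0 = time.perf_counter()
        reports = evaluate_all(fitted, test, selection.final_set)
        write_metrics(reports, out / "metrics.csv", out / "metrics.json")
        artifacts["reports"] = reports
        best = max(reports, key=lambda r: (r.auc_ovr_macro, r.accuracy))
        artifacts["best_classifier"] = best.classifier
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "best_classifier": best.classifier,
        }

        if config.run_stability:
            stage = "stability"
            t0 = time.perf_counter()
            curve = instability_curve(
                table,
                classifiers=config.stability_classifiers,
                fractions=config.stability_fractions,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            write_instability_curve(curve, out / "instability.csv")
            artifacts["instability"] = curve
            manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        if config.run_explain:
            stage = "explain"
            t0 = time.perf_counter()
            best_model = fitted[best.classifier]
            attribution = global_attributions(
                best_model, test, selection.final_set, background=train, seed=config.seed
            )
            attribution.per_class.to_csv(out / "global_attributions.csv")
            (out / "global_ranking.json").write_text(
                json.dumps(attribution.ranking, indent=2)
            )
            locals_ = []
            for cls in sorted(test["label"].unique()):
                row = test[test["label"] == cls].iloc[0]
                expl = local_explanation(
                    best_model,
                    row,
                    train,
                    selection.final_set,
                    n_perturb=config.n_perturb,
                    seed=config.seed,
                    instance_id=str(row.get("participant_id", f"class{cls}")),
                )
                locals_.append(expl)
            pd.concat(
                [
                    e.contributions.assign(
                        instance_id=e.instance_id, predicted_class=e.predicted_class
                    )
                    for e in locals_
                ],
                ignore_index=True,
            ).to_csv(out / "local_explanations.csv", index=False)
            artifacts["global_attribution"] = attribution
            artifacts["local_explanations"] = locals_
            manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
        from .errors import SLSKitError

        raise SLSKitError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2))
    artifacts["manifest_path"] = manifest_path
    return artifacts
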