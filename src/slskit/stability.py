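"""Bootstrap prediction-instability analysis for sample-size adequacy.

For each dataset fraction (default 10%, 30%, 50%, 70%, 90%) and classifier,
many stratified subsamples of that fraction are drawn, a model is fitted on
each, and the variability (standard deviation) of its evaluation accuracy
across replicates is reported as the *prediction instability* at that sample
size. A declining curve indicates that the dataset is large enough for
stable model behavior.

Evaluation set: by default every replicate is scored on the full fixed
dataset, so the evaluation-noise floor is identical across fractions and the
curve isolates the effect of training-set size. Scoring on the complement of
the subsample is available via ``eval_mode="complement"``, but note its
evaluation set shrinks as the fraction grows, which inflates instability at
large fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import ConfigError
from .features import feature_matrix, labels
from .modeling import CLASSIFIER_NAMES, make_classifier

DEFAULT_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class InstabilityCurve:
    """Instability per classifier x fraction."""

    table: pd.DataFrame  # columns: classifier, fraction, instability, n_boot
    metric: str = "accuracy"
    eval_mode: str = "full"

    def mean_over_classifiers(self) -> pd.Series:
        return self.table.groupby("fraction")["instability"].mean()


def _accuracy(model, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(model.predict(X) == y))


def instability_curve(
    table: pd.DataFrame,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    features: Optional[Sequence[str]] = None,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_boot: int = 100,
    seed: int = 0,
    eval_mode: str = "full",
) -> InstabilityCurve:
    """Compute the bootstrap instability curve.

    Subsamples are stratified draws *without* replacement of the given
    fraction of the dataset. ``instability`` is the SD of replicate accuracy.
    Deterministic for a fixed seed. Fractions too small to contain at least
    2 members of every class are skipped with a warning; ``n_boot`` of 1
    yields a degenerate instability of 0 with a warning.
    """
    if eval_mode not in ("full", "complement"):
        raise ConfigError("eval_mode must be 'full' or 'complement'")
    fr = list(fractions)
    if any(not 0 < f <= 1 for f in fr) or sorted(fr) != fr or len(set(fr)) != len(fr):
        raise ConfigError("fractions must be strictly increasing values in (0, 1]")
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    if n_boot == 1:
        warnings.warn(
            "n_boot=1 gives a degenerate replicate set; instability reported as 0",
            UserWarning,
            stacklevel=2,
        )

    from .features import FEATURE_NAMES

    feats = list(features) if features is not None else [
        c for c in table.columns if c in FEATURE_NAMES
    ]
    X_all = feature_matrix(table, feats)
    y_all = labels(table)
    n = len(y_all)
    class_counts = np.bincount(y_all)
    rng = np.random.default_rng(seed)

    rows: List[Dict[str, object]] = []
    for f in fr:
        min_members = np.floor(f * class_counts[class_counts > 0]).min()
        if f < 1.0 and min_members < 2:
            warnings.warn(
                f"fraction {f} leaves fewer than 2 members of some class; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        # replicate subsample index sets, shared across classifiers
        replicate_ix = []
        for _ in range(n_boot):
            if f >= 1.0:
                replicate_ix.append(np.arange(n))
                continue
            sub_seed = int(rng.integers(2**31 - 1))
            sub, _rest = train_test_split(
                np.arange(n), train_size=f, stratify=y_all, random_state=sub_seed
            )
            replicate_ix.append(np.sort(sub))
        for name in classifiers:
            accs = []
            for ix in replicate_ix:
                model = make_classifier(name, seed=seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X_all[ix], y_all[ix])
                if eval_mode == "full":
                    accs.append(_accuracy(model, X_all, y_all))
                else:
                    comp = np.setdiff1d(np.arange(n), ix)
                    if comp.size == 0:
                        accs.append(_accuracy(model, X_all, y_all))
                    else:
                        accs.append(_accuracy(model, X_all[comp], y_all[comp]))
            instab = float(np.std(accs)) if len(accs) > 1 else 0.0
            rows.append(
                {"classifier": name, "fraction": f, "instability": instab, "n_boot": n_boot}
            )
    return InstabilityCurve(table=pd.DataFrame(rows), eval_mode=eval_mode)
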