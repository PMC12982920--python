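"""Model explanation: global Shapley attributions and local surrogate models.

Global attributions are interventional Shapley values: for each instance and
class, each feature's contribution to the model's class score relative to a
background expectation. With p features the 2^p feature coalitions are
enumerated exactly (the coalition value is the mean model score with absent
features replaced by background rows), so the efficiency axiom — base value
plus the sum of attributions equals the model's score — holds to machine
precision. For larger feature sets a seeded Monte-Carlo permutation
estimator is used. Class-wise mean |attribution| and a summed global ranking
are reported.

Local explanations follow the perturbation-surrogate recipe: the instance's
features are discretized into quartile bins of a background sample, several
thousand perturbed neighbors are drawn by randomly resetting features to
background values, and an exponentially distance-weighted ridge regression
on the "feature kept at its observed bin" indicators yields signed
per-feature contributions toward the predicted class, each tied to the bin
interval the instance occupies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .errors import ConfigError, SchemaError
from .features import feature_matrix

EXACT_ENUMERATION_LIMIT = 12  # beyond this, Monte-Carlo permutation sampling


@dataclass
class GlobalAttribution:
    """Class-wise mean |Shapley value| per feature plus a global ranking."""

    per_class: pd.DataFrame  # index = feature, columns = class labels
    ranking: List[str]  # features by descending summed mean |attribution|
    base_values: np.ndarray  # per-class background expectation of the score


@dataclass
class LocalExplanation:
    """Per-instance surrogate explanation."""

    instance_id: str
    predicted_class: int
    contributions: pd.DataFrame  # feature, contribution, bin_low, bin_high
    intercept: float
    skipped_features: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# score function
# ---------------------------------------------------------------------------

def _predict_scores(model, X: np.ndarray) -> np.ndarray:
    """(n, n_classes) class-membership scores (probabilities if available)."""
    if hasattr(model, "predict_proba"):
        try:
            return np.asarray(model.predict_proba(X), dtype=float)
        except AttributeError:
            pass
    s = np.asarray(model.decision_function(X), dtype=float)
    if s.ndim == 1:
        s = np.column_stack([-s, s])
    return s


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

def _coalition_values(model, x: np.ndarray, background: np.ndarray) -> Dict[int, np.ndarray]:
    """Mean class scores for every coalition (bitmask) of present features."""
    p = x.shape[0]
    B = background.shape[0]
    masks = np.arange(2**p)
    bits = ((masks[:, None] >> np.arange(p)) & 1).astype(bool)  # (2^p, p)
    # rows: for each mask, background copies with present features overwritten
    X = np.repeat(background[None, :, :], 2**p, axis=0)  # (2^p, B, p)
    X[bits[:, None, :].repeat(B, axis=1)] = np.broadcast_to(
        x, (2**p, B, p)
    )[bits[:, None, :].repeat(B, axis=1)]
    flat = X.reshape(-1, p)
    scores = _predict_scores(model, flat).reshape(2**p, B, -1).mean(axis=1)
    return {int(m): scores[m] for m in masks}


def _exact_shapley(model, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """(p, n_classes) exact interventional Shapley values for one instance."""
    p = x.shape[0]
    values = _coalition_values(model, x, background)
    n_classes = values[0].shape[0]
    phi = np.zeros((p, n_classes))
    weights = {s: factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)}
    others = list(range(p))
    for i in range(p):
        rest = [j for j in others if j != i]
        for size in range(p):
            w = weights[size]
            for S in combinations(rest, size):
                mask = sum(1 << j for j in S)
                phi[i] += w * (values[mask | (1 << i)] - values[mask])
    return phi


def _sampled_shapley(
    model, x: np.ndarray, background: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo permutation Shapley estimate for wide feature sets."""
    p = x.shape[0]
    B = background.shape[0]
    n_classes = _predict_scores(model, x[None, :]).shape[1]
    phi = np.zeros((p, n_classes))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        current = background.copy()
        prev = _predict_scores(model, current).mean(axis=0)
        for i in order:
            current[:, i] = x[i]
            nxt = _predict_scores(model, current).mean(axis=0)
            phi[i] += nxt - prev
            prev = nxt
    return phi / n_permutations


def shapley_values(
    model,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Shapley values for each row of ``X``.

    Returns ``(phi, base)`` where ``phi`` has shape
    (n_instances, n_features, n_classes) and ``base`` is the per-class mean
    model score over the background. Exact enumeration is used up to
    :data:`EXACT_ENUMERATION_LIMIT` features; beyond that, seeded permutation
    sampling with ``n_permutations`` draws.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if X.shape[1] != background.shape[1]:
        raise SchemaError("instance and background feature dimensions differ")
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    base = _predict_scores(model, background).mean(axis=0)
    out = []
    for x in X:
        if p <= EXACT_ENUMERATION_LIMIT:
            out.append(_exact_shapley(model, x, background))
        else:
            out.append(_sampled_shapley(model, x, background, n_permutations, rng))
    return np.stack(out), base


def global_attributions(
    model,
    data: pd.DataFrame,
    features: Sequence[str],
    background: Optional[pd.DataFrame] = None,
    max_background: int = 50,
    seed: int = 0,
) -> GlobalAttribution:
    """Aggregate per-instance Shapley values into class-wise global importance.

    ``background`` defaults to ``data`` itself (subsampled to
    ``max_background`` rows, seeded). The ranking orders features by the sum
    over classes of the mean absolute attribution.
    """
    feats = list(features)
    X = feature_matrix(data, feats)
    bg_frame = background if background is not None else data
    bg = feature_matrix(bg_frame, feats)
    if bg.shape[0] > max_background:
        rng = np.random.default_rng(seed)
        bg = bg[rng.choice(bg.shape[0], size=max_background, replace=False)]
    phi, base = shapley_values(model, X, bg, seed=seed)
    mean_abs = np.abs(phi).mean(axis=0)  # (p, n_classes)
    classes = list(getattr(model, "classes_", range(mean_abs.shape[1])))
    per_class = pd.DataFrame(mean_abs, index=feats, columns=classes)
    order = per_class.sum(axis=1).sort_values(ascending=False, kind="stable")
    return GlobalAttribution(per_class=per_class, ranking=list(order.index), base_values=base)


# ---------------------------------------------------------------------------
# local surrogate explanations
# ---------------------------------------------------------------------------

def _quartile_bins(values: np.ndarray) -> np.ndarray:
    return np.percentile(values, [25, 50, 75])


def _bin_interval(x: float, edges: np.ndarray) -> Tuple[float, float]:
    lo, hi = -np.inf, np.inf
    bounds = [-np.inf, *edges, np.inf]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a < x <= b or (a == -np.inf and x <= b):
            return (a, b)
    return (lo, hi)


def local_explanation(
    model,
    instance: pd.Series,
    background: pd.DataFrame,
    features: Sequence[str],
    n_perturb: int = 5000,
    seed: int = 0,
    kernel_width: Optional[float] = None,
    ridge_alpha: float = 1.0,
    instance_id: str = "instance",
) -> LocalExplanation:
    """Explain one prediction with a weighted sparse linear surrogate.

    ``n_perturb`` perturbations of the instance are drawn: each feature is
    independently either kept at the instance's value or reset to a random
    background value. The surrogate regresses the model's score for the
    predicted class on the keep/reset indicators, weighted by an exponential
    kernel over perturbation distance. The signed coefficient for each
    feature is its contribution toward the predicted class, conditioned on
    the quartile bin the instance occupies. Deterministic for a fixed seed.
    Features constant in the background are skipped with a warning.
    """
    feats = list(features)
    if n_perturb < 10:
        raise ConfigError("n_perturb must be at least 10")
    x = np.array([float(instance[f]) for f in feats])
    bg = feature_matrix(background, feats)
    p = len(feats)
    rng = np.random.default_rng(seed)

    constant = [feats[j] for j in range(p) if np.ptp(bg[:, j]) == 0.0]
    if constant:
        warnings.warn(
            f"background features {constant} are constant and are skipped",
            UserWarning,
            stacklevel=2,
        )
    active = [j for j in range(p) if feats[j] not in set(constant)]

    pred_class = int(np.asarray(model.predict(x[None, :]))[0])
    classes = list(getattr(model, "classes_", []))
    class_col = classes.index(pred_class) if pred_class in classes else pred_class

    # keep/reset design: z=1 keeps the instance's value, z=0 resets to a
    # random background row's value for that feature
    z = rng.integers(0, 2, size=(n_perturb, p)).astype(float)
    z[0, :] = 1.0  # the instance itself anchors the fit
    for j in range(p):
        if j not in active:
            z[:, j] = 1.0
    donor = rng.integers(0, bg.shape[0], size=(n_perturb, p))
    Xp = np.where(z.astype(bool), x[None, :], bg[donor, np.arange(p)[None, :]])
    target = _predict_scores(model, Xp)[:, class_col]

    kw = kernel_width if kernel_width is not None else 0.75 * np.sqrt(p)
    dist = np.sqrt((1.0 - z).sum(axis=1))
    sample_weight = np.exp(-(dist**2) / kw**2)

    reg = Ridge(alpha=ridge_alpha)
    reg.fit(z[:, active], target, sample_weight=sample_weight)

    bins = {j: _quartile_bins(bg[:, j]) for j in active}
    rows = []
    coef = dict(zip(active, reg.coef_))
    for j in range(p):
        if j in coef:
            lo, hi = _bin_interval(x[j], bins[j])
            rows.append(
                {
                    "feature": feats[j],
                    "contribution": float(coef[j]),
                    "bin_low": float(lo),
                    "bin_high": float(hi),
                }
            )
    contributions = pd.DataFrame(rows, columns=["feature", "contribution", "bin_low", "bin_high"])
    return LocalExplanation(
        instance_id=instance_id,
        predicted_class=pred_class,
        contributions=contributions,
        intercept=float(reg.intercept_),
        skipped_features=constant,
    )
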