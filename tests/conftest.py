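"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from slskit import (
    GeneratorConfig,
    PeakAngles,
    engineer_features,
    sample_peak_targets,
    simulate_feature_table,
)
from slskit.features import build_feature_table


# ---------------------------------------------------------------------------
# oracles (kept independent of the implementation under test)
# ---------------------------------------------------------------------------

def oracle_angle_between(u, v) -> float:
    """Brute-force arccos-of-normalized-dot angle between two vectors, deg."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def oracle_axis_angle(segment, axis) -> float:
    """Unsigned angle in [0, 90] between an undirected segment and an axis."""
    a = oracle_angle_between(segment, axis)
    return min(a, 180.0 - a)


def oracle_bh(pvals: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def oracle_anova_f(groups) -> tuple:
    """Two-pass between/within sums-of-squares one-way ANOVA F and p."""
    from scipy.stats import f as f_dist

    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n = len(all_vals)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, float(f_dist.sf(F, df_b, df_w))


def oracle_weighted_kappa(a, b, weighting="linear") -> float:
    """Weighted Cohen kappa from an explicitly built contingency table."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    k = 3
    obs = np.zeros((k, k))
    for i, j in zip(a, b):
        obs[i, j] += 1
    obs /= len(a)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    ii, jj = np.meshgrid(range(k), range(k), indexing="ij")
    d = np.abs(ii - jj) / (k - 1)
    w = d if weighting == "linear" else d**2
    return 1.0 - (w * obs).sum() / (w * exp).sum()


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_peak_table(n_per_class=(28, 41, 36), seed=0, config=None) -> pd.DataFrame:
    """Feature table built directly from class-conditional peak draws
    (bypasses landmark synthesis; used where geometry is not under test)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    records = []
    pid = 0
    for c, n in enumerate(n_per_class):
        for _ in range(n):
            pid += 1
            peaks = sample_peak_targets(cfg, c, rng)
            records.append((f"P{pid:03d}", engineer_features(peaks), c))
    return build_feature_table(records)


@pytest.fixture(scope="session")
def study_table() -> pd.DataFrame:
    """Participant table from a full study-matched landmark cohort."""
    return simulate_feature_table(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def peak_table() -> pd.DataFrame:
    """Fast study-sized table straight from peak draws."""
    return make_peak_table(seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
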