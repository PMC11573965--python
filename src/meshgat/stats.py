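"""Feature assessment: one-way ANOVA, MRMR ranking, class-pattern summaries.

These stages assess — but by default do not prune — the ten features: the
F-test measures each feature's marginal separation of the benign and
malignant groups, MRMR ranks features by relevance penalized by redundancy
with already-chosen features, and the pattern summary reports per-class means
over random subsets of increasing size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

P_SIGNIFICANT = 0.05  # group-difference significance threshold


def _split_classes(table: pd.DataFrame, features: list[str]):
    y = table["target"].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {list(classes)}")
    a = table.loc[y == classes[0], features].to_numpy(dtype=float)
    b = table.loc[y == classes[1], features].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 rows")
    return a, b


def anova_f(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Per-feature one-way F statistic and p-value for benign vs malignant.

    Zero within-group variance with differing group means yields F = inf,
    p = 0, flagged in the ``degenerate`` column.
    """
    features = features or FEATURE_NAMES
    a, b = _split_classes(table, features)
    rows = []
    for j, name in enumerate(features):
        x, z = a[:, j], b[:, j]
        sw = np.var(x, ddof=1) * (len(x) - 1) + np.var(z, ddof=1) * (len(z) - 1)
        degenerate = False
        if sw == 0.0:
            if np.mean(x) == np.mean(z):
                f, p = 0.0, 1.0
            else:
                f, p = np.inf, 0.0
            degenerate = True
        else:
            f, p = sps.f_oneway(x, z)
        rows.append({"feature": name, "F_value": float(f), "p_value": float(p),
                     "degenerate": degenerate})
    return pd.DataFrame(rows)


def mrmr_rank(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Greedy minimum-redundancy maximum-relevance feature ranking (FCQ).

    Relevance = ANOVA F against the class label; redundancy = mean absolute
    Pearson correlation with the already-selected set; each step picks the
    feature maximizing relevance / redundancy. Scores are min-max scaled to
    [0, 100] percent. Ties break lexicographically by feature name.
    """
    features = sorted(features or FEATURE_NAMES)
    if len(features) < 2:
        raise ValueError("MRMR needs at least 2 features")
    relevance = anova_f(table, features).set_index("feature")["F_value"]
    X = table[features].to_numpy(dtype=float)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        log.warning("constant feature columns (zero relevance): %s",
                    [f for f, c in zip(features, const) if c])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(np.abs(corr), nan=1.0)

    selected: list[int] = []
    remaining = list(range(len(features)))
    raw_scores: dict[int, float] = {}
    rel = np.nan_to_num(relevance[features].to_numpy(), posinf=np.finfo(float).max)
    rel = np.where(const, 0.0, rel)
    while remaining:
        if not selected:
            scores = {i: rel[i] for i in remaining}
        else:
            scores = {}
            for i in remaining:
                red = float(np.mean(corr[i, selected]))
                scores[i] = rel[i] / red if red > 0 else rel[i]
        best = min(remaining, key=lambda i: (-scores[i], features[i]))
        raw_scores[best] = scores[best]
        selected.append(best)
        remaining.remove(best)

    raw = np.array([raw_scores[i] for i in selected])
    span = raw.max() - raw.min()
    pct = 100.0 * (raw - raw.min()) / span if span > 0 else np.full_like(raw, 100.0)
    return pd.DataFrame({
        "rank": np.arange(1, len(selected) + 1),
        "feature": [features[i] for i in selected],
        "raw_score": raw,
        "score_pct": pct,
    })


def pattern_summary(
    table: pd.DataFrame,
    subset_sizes: list[int] = (70, 90, 110, 130, 150),
    seed: int = 0,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class feature means over random subsets plus the full-class means.

    For each class and each requested subset size, sample rows without
    replacement (size capped at the class size, with a warning) and report the
    ten feature means; the final ``all`` row is the exact class mean.
    """
    features = features or FEATURE_NAMES
    rng = np.random.default_rng(seed)
    rows = []
    for cls, grp in table.groupby("target"):
        X = grp[features].to_numpy(dtype=float)
        for size in subset_sizes:
            n = int(size)
            if n > len(X):
                log.warning("subset size %d > class size %d for %s; capped",
                            n, len(X), cls)
                n = len(X)
            idx = rng.choice(len(X), size=n, replace=False)
            rows.append({"target": cls, "subset_size": str(size),
                         **dict(zip(features, X[idx].mean(axis=0)))})
        rows.append({"target": cls, "subset_size": "all",
                     **dict(zip(features, X.mean(axis=0)))})
    return pd.DataFrame(rows)
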