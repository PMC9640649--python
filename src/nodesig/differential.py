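"""Two-group differential abundance with exclusivity rules.

Features observed at least ``min_obs_per_group`` times in both groups are
compared with an equal-variance two-sided Student's t-test; features
detected in only one group are handled by the exclusivity rule: at the
p-value level any exclusive detection counts, at the FDR level the
detection fraction in that group must reach ``exclusive_min_fraction``.
BH correction runs over tested features only.  The log2 ratio is the
difference of group means of the log2 values (positive minus negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NEGATIVE, POSITIVE

__all__ = [
    "DegenerateVarianceError",
    "DifferentialRecord",
    "student_t_two_sided",
    "bh_adjust",
    "differential_table",
    "pca_summary",
    "deregulation_chi2",
    "records_to_frame",
]


class DegenerateVarianceError(ValueError):
    """Pooled variance is zero; the t statistic is undefined."""


@dataclass(frozen=True)
class DifferentialRecord:
    feature_id: str
    n_obs_pos: int
    n_obs_neg: int
    mean_pos: float
    mean_neg: float
    ratio: float
    t_stat: float
    p: float
    q: float
    status: str  # up | down | not_significant | not_tested
    exclusivity: str  # none | exclusive_pos | exclusive_neg


def student_t_two_sided(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pooled-variance (equal-variance) two-sided Student's t-test.

    Raises :class:`DegenerateVarianceError` when the pooled variance is
    zero so callers can route the feature to an NA path instead of
    reporting p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two observations")
    df = nx + ny - 2
    pooled = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if pooled <= 0:
        raise DegenerateVarianceError("zero pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _split_groups(
    table: pd.DataFrame, labels: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    pos = [s for s in table.columns if labels.get(s) == POSITIVE]
    neg = [s for s in table.columns if labels.get(s) == NEGATIVE]
    if not pos or not neg:
        raise ValueError("both groups must be nonempty")
    return pos, neg


def differential_table(
    table: pd.DataFrame,
    labels: Mapping[str, str],
    use_fdr: bool = False,
    alpha: float = 0.05,
    min_obs_per_group: int = 2,
    exclusive_min_fraction: float = 0.5,
) -> list[DifferentialRecord]:
    """Per-feature two-group comparison on an un-imputed table.

    The observed-value mask drives the exclusivity logic, so the input
    must not be imputed.
    """
    pos_samples, neg_samples = _split_groups(table, labels)
    xs = table[pos_samples]
    ys = table[neg_samples]

    rows: list[dict] = []
    for fid in table.index:
        x = xs.loc[fid].dropna().to_numpy()
        y = ys.loc[fid].dropna().to_numpy()
        row = {
            "feature_id": fid,
            "n_obs_pos": len(x),
            "n_obs_neg": len(y),
            "mean_pos": float(x.mean()) if len(x) else math.nan,
            "mean_neg": float(y.mean()) if len(y) else math.nan,
            "t_stat": math.nan,
            "p": math.nan,
            "q": math.nan,
            "exclusivity": "none",
            "status": "not_tested",
        }
        row["ratio"] = (
            row["mean_pos"] - row["mean_neg"]
            if len(x) and len(y)
            else math.nan
        )
        if len(x) >= min_obs_per_group and len(y) >= min_obs_per_group:
            try:
                row["t_stat"], row["p"] = student_t_two_sided(x, y)
                row["status"] = "tested"
            except DegenerateVarianceError:
                pass  # undefined statistic -> stays not_tested
        elif len(x) > 0 and len(y) == 0:
            row["exclusivity"] = "exclusive_pos"
        elif len(y) > 0 and len(x) == 0:
            row["exclusivity"] = "exclusive_neg"
        rows.append(row)

    tested = [r for r in rows if r["status"] == "tested"]
    if use_fdr and tested:
        qvals = bh_adjust([r["p"] for r in tested])
        for r, q in zip(tested, qvals):
            r["q"] = float(q)

    n_pos, n_neg = len(pos_samples), len(neg_samples)
    for r in rows:
        if r["status"] == "tested":
            crit = r["q"] if use_fdr else r["p"]
            if crit <= alpha and r["ratio"] > 0:
                r["status"] = "up"
            elif crit <= alpha and r["ratio"] < 0:
                r["status"] = "down"
            else:
                r["status"] = "not_significant"
        elif r["exclusivity"] != "none":
            if r["exclusivity"] == "exclusive_pos":
                frac = r["n_obs_pos"] / n_pos
                direction = "up"
            else:
                frac = r["n_obs_neg"] / n_neg
                direction = "down"
            # the detection-fraction clause applies at FDR level only
            if use_fdr and frac < exclusive_min_fraction:
                r["status"] = "not_significant"
                r["exclusivity"] = "none"
            else:
                r["status"] = direction

    return [DifferentialRecord(**r) for r in rows]


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Records as a DataFrame with a fixed column order."""
    cols = [
        "feature_id",
        "n_obs_pos",
        "n_obs_neg",
        "mean_pos",
        "mean_neg",
        "ratio",
        "t_stat",
        "p",
        "q",
        "status",
        "exclusivity",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])[cols]


def pca_summary(
    table: pd.DataFrame, feature_subset: Sequence[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples on a complete (imputed) table.

    Returns per-sample component scores and explained-variance fractions
    (which sum to 1 over min(n_samples - 1, n_features) components).
    """
    sub = table.loc[list(feature_subset)] if feature_subset is not None else table
    if sub.shape[0] == 0:
        raise ValueError("feature subset is empty")
    if sub.isna().any().any():
        raise ValueError("table contains missing values; impute first")
    X = sub.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    if n_comp < 1:
        raise ValueError("need at least two samples")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    s, vt = s[:n_comp], vt[:n_comp]
    scores = X @ vt.T
    var = s**2
    fractions = var / var.sum() if var.sum() > 0 else np.full(n_comp, 1.0 / n_comp)
    score_df = pd.DataFrame(
        scores, index=sub.columns, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    return score_df, fractions


def deregulation_chi2(
    up_a: int, down_a: int, up_b: int, down_b: int
) -> tuple[float, float]:
    """Chi-square comparison of up/down frequencies between two datasets."""
    tab = np.array([[up_a, down_a], [up_b, down_b]])
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)
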