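"""Hierarchical clustering over a method x metric grid and cluster-covariate
association by Fisher's exact test.

Binary set metrics (dice, jaccard, ...) are computed on the detection mask
(observed = 1, missing = 0) rather than on continuous log2 values; pass
``force_continuous_binary=True`` to apply them to the raw matrix anyway.
Two metrics that newer SciPy releases dropped (kulsinski, sokalmichener)
are implemented locally so the full 22-metric grid stays available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "METHODS",
    "METRICS",
    "BINARY_METRICS",
    "LinkageSpec",
    "ClusterAssignment",
    "GridFailure",
    "linkage_result",
    "linkage_grid",
    "cut_groups",
    "fisher_exact_2x2",
    "associate_clusters",
    "to_newick",
]

METHODS = ("complete", "weighted", "ward")
METRICS = (
    "braycurtis",
    "canberra",
    "chebyshev",
    "cityblock",
    "correlation",
    "cosine",
    "dice",
    "euclidean",
    "hamming",
    "jaccard",
    "jensenshannon",
    "kulsinski",
    "mahalanobis",
    "yule",
    "matching",
    "minkowski",
    "rogerstanimoto",
    "russellrao",
    "seuclidean",
    "sokalmichener",
    "sokalsneath",
    "sqeuclidean",
)
BINARY_METRICS = frozenset(
    {
        "dice",
        "hamming",
        "jaccard",
        "kulsinski",
        "matching",
        "rogerstanimoto",
        "russellrao",
        "sokalmichener",
        "sokalsneath",
        "yule",
    }
)
# metrics whose distances are compatible with Ward's variance criterion
_WARD_COMPATIBLE = frozenset({"euclidean", "sqeuclidean", "seuclidean", "minkowski"})


def _kulsinski(u: np.ndarray, v: np.ndarray) -> float:
    u = u.astype(bool)
    v = v.astype(bool)
    ntt = int((u & v).sum())
    ntf = int((u & ~v).sum())
    nft = int((~u & v).sum())
    n = len(u)
    return (ntf + nft - ntt + n) / (ntf + nft + n)


def _sokalmichener(u: np.ndarray, v: np.ndarray) -> float:
    u = u.astype(bool)
    v = v.astype(bool)
    ntt = int((u & v).sum())
    nff = int((~u & ~v).sum())
    r = 2 * (int((u & ~v).sum()) + int((~u & v).sum()))
    return r / (r + ntt + nff) if (r + ntt + nff) else 0.0


_LOCAL_METRICS: dict[str, Callable] = {
    "kulsinski": _kulsinski,
    "sokalmichener": _sokalmichener,
}


@dataclass(frozen=True)
class LinkageSpec:
    method: str
    metric: str

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass(frozen=True)
class ClusterAssignment:
    item_ids: tuple[str, ...]
    labels: tuple[str, ...]
    linkage_spec: LinkageSpec | None
    linkage_matrix: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.item_ids), name="cluster")


@dataclass(frozen=True)
class GridFailure:
    linkage_spec: LinkageSpec
    reason: str


def _distance(X: np.ndarray, metric: str) -> np.ndarray:
    if metric in _LOCAL_METRICS:
        return pdist(X, metric=_LOCAL_METRICS[metric])
    return pdist(X, metric=metric)


def linkage_result(
    table: pd.DataFrame,
    spec: LinkageSpec,
    axis: str = "samples",
    k: int = 2,
    mask: pd.DataFrame | None = None,
    force_continuous_binary: bool = False,
) -> ClusterAssignment:
    """Cluster one grid cell and cut the tree into ``k`` flat groups.

    ``mask`` is the detection mask (True = observed) used for binary
    metrics; the continuous table itself is used for all others.
    """
    if axis not in ("samples", "features"):
        raise ValueError("axis must be 'samples' or 'features'")
    data = table if axis == "features" else table.T
    if data.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    if table.isna().any().any():
        raise ValueError("table contains missing values; impute first")

    if spec.metric in BINARY_METRICS and not force_continuous_binary:
        if mask is None:
            raise ValueError(
                f"metric {spec.metric!r} needs the detection mask "
                "(or force_continuous_binary=True)"
            )
        source = mask if axis == "features" else mask.T
        X = source.to_numpy(dtype=bool).astype(float)
    else:
        X = data.to_numpy(dtype=float)

    if spec.method == "ward" and spec.metric not in _WARD_COMPATIBLE:
        raise ValueError(f"ward linkage unsupported for metric {spec.metric!r}")

    dist = _distance(X, spec.metric)
    if not np.isfinite(dist).all():
        raise ValueError("non-finite distances")
    Z = hierarchy.linkage(dist, method=spec.method)
    item_ids = tuple(str(i) for i in data.index)
    labels = _cut_labels(Z, k, item_ids, prefix="C" if axis == "samples" else "PC")
    return ClusterAssignment(
        item_ids=item_ids, labels=labels, linkage_spec=spec, linkage_matrix=Z
    )


def _cut_labels(
    Z: np.ndarray, k: int, item_ids: tuple[str, ...], prefix: str = "C"
) -> tuple[str, ...]:
    n = len(item_ids)
    if k > n:
        raise ValueError(f"cannot cut {n} items into {k} groups")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # rank groups by size (desc); ties broken by first item position, so the
    # larger cluster is always C1
    groups: dict[int, list[int]] = {}
    for i, g in enumerate(flat):
        groups.setdefault(int(g), []).append(i)
    ordered = sorted(groups, key=lambda g: (-len(groups[g]), min(groups[g])))
    rename = {g: f"{prefix}{rank + 1}" for rank, g in enumerate(ordered)}
    return tuple(rename[int(g)] for g in flat)


def cut_groups(assignment: ClusterAssignment, k: int, prefix: str = "C") -> ClusterAssignment:
    """Re-cut an existing tree into ``k`` flat groups."""
    labels = _cut_labels(assignment.linkage_matrix, k, assignment.item_ids, prefix)
    return ClusterAssignment(
        item_ids=assignment.item_ids,
        labels=labels,
        linkage_spec=assignment.linkage_spec,
        linkage_matrix=assignment.linkage_matrix,
    )


def linkage_grid(
    table: pd.DataFrame,
    axis: str = "samples",
    methods: Sequence[str] = METHODS,
    metrics: Sequence[str] = METRICS,
    k: int = 2,
    mask: pd.DataFrame | None = None,
    force_continuous_binary: bool = False,
) -> dict[LinkageSpec, ClusterAssignment | GridFailure]:
    """Run every method x metric cell; failures are recorded, not fatal."""
    out: dict[LinkageSpec, ClusterAssignment | GridFailure] = {}
    for method in methods:
        for metric in metrics:
            spec = LinkageSpec(method, metric)
            try:
                out[spec] = linkage_result(
                    table,
                    spec,
                    axis=axis,
                    k=k,
                    mask=mask,
                    force_continuous_binary=force_continuous_binary,
                )
            except Exception as exc:  # isolate per-cell failures
                out[spec] = GridFailure(spec, f"{type(exc).__name__}: {exc}")
    return out


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, bool]:
    """Two-sided Fisher's exact p for a 2x2 table.

    Returns (p, degenerate); any zero margin yields p = 1 with the
    degeneracy flag set.
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return 1.0, True
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    return float(p), False


def associate_clusters(
    assignment: ClusterAssignment,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-exact association of 2-group cluster labels with covariates.

    Multi-level covariates are dichotomized against their modal level;
    single-level covariates are skipped with a note.
    """
    labels = assignment.as_series()
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError("association requires exactly two clusters")
    in_c1 = labels == uniq[0]

    records = []
    for cov in covariates.columns:
        values = covariates.loc[labels.index, cov].dropna()
        rec = {"covariate": cov, "p": np.nan, "significant": False, "note": ""}
        levels = values.unique()
        if len(levels) < 2:
            rec["note"] = "skipped: single level"
            records.append(rec)
            continue
        if len(levels) == 2:
            ref = levels[0]
        else:
            ref = values.mode().iloc[0]
            rec["note"] = f"dichotomized at modal level {ref!r}"
        is_ref = values == ref
        idx = values.index
        tab = [
            [int((in_c1[idx] & is_ref).sum()), int((in_c1[idx] & ~is_ref).sum())],
            [int((~in_c1[idx] & is_ref).sum()), int((~in_c1[idx] & ~is_ref).sum())],
        ]
        p, degenerate = fisher_exact_2x2(tab)
        rec["p"] = p
        rec["significant"] = (not degenerate) and p <= alpha
        rec["table"] = tab
        if degenerate:
            rec["note"] = (rec["note"] + "; " if rec["note"] else "") + "degenerate margin"
        records.append(rec)
    return pd.DataFrame(records)


def to_newick(assignment: ClusterAssignment) -> str:
    """Nested-parenthesis (Newick) text of the merge tree, with heights."""
    tree = hierarchy.to_tree(assignment.linkage_matrix)
    ids = assignment.item_ids

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
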