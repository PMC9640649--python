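"""Exhaustive signature x classifier search with cross-validated validation.

Every subset of panel variables up to ``max_size`` (a signature Si) is
paired with each classifier family (Cj) and evaluated by repeated
stratified K-fold cross-validation: within one repetition the held-out
continuous scores of all K folds are pooled into a single ROC AUC, giving
R AUC values per pair.  The pair with the highest mean AUC is top-1;
pairs whose AUC distribution is not distinguishable from top-1's
(two-sided equal-variance t-test, p >= 0.05) are selected alongside it.
Selected pairs are validated by a label-permutation test, and pairs with
mean AUC >= 0.85 and permutation p <= 0.05 are flagged high-performance.

Fold partitions are derived from (base_seed, repetition) and shared across
pairs, so AUC distributions are directly comparable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import config_context
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, Perceptron, RidgeClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import POSITIVE

__all__ = [
    "CLASSIFIER_FAMILIES",
    "ClassifierSpec",
    "CVConfig",
    "PanelData",
    "PairEvaluation",
    "prepare_panel",
    "enumerate_signatures",
    "count_signatures",
    "make_splits",
    "cv_auc_distribution",
    "evaluate_all_pairs",
    "select_equivalent_to_top1",
    "permutation_pvalue",
    "high_performance_filter",
    "marker_frequency",
    "run_search",
    "roc_points",
]

CLASSIFIER_FAMILIES = (
    "ridge",
    "linear_svm",
    "lasso",
    "linear_discriminant",
    "perceptron",
    "decision_tree",
    "naive_bayes",
    "gbm",
    "random_forest",
    "rbf_svm",
)

# fixed, documented defaults per family; immutable within a run
_DEFAULT_PARAMS: dict[str, dict] = {
    "ridge": {"alpha": 1.0},
    "linear_svm": {"C": 1.0},
    "lasso": {"C": 1.0},
    "linear_discriminant": {},
    "perceptron": {"max_iter": 1000, "tol": 1e-3},
    "decision_tree": {"max_depth": None},
    "naive_bayes": {},
    "gbm": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "random_forest": {"n_estimators": 100},
    "rbf_svm": {"C": 1.0, "gamma": "scale"},
}
_SEEDED_FAMILIES = frozenset(
    {"perceptron", "decision_tree", "gbm", "random_forest"}
)


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with a fixed hyperparameter record."""

    family: str
    overrides: tuple[tuple[str, object], ...] = ()

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    @property
    def params(self) -> dict:
        return {**_DEFAULT_PARAMS[self.family], **dict(self.overrides)}

    def make(self, random_state: int = 0):
        p = self.params
        if self.family == "ridge":
            return RidgeClassifier(**p)
        if self.family == "linear_svm":
            return SVC(kernel="linear", **p)
        if self.family == "lasso":
            return LogisticRegression(solver="liblinear", l1_ratio=1.0, **p)
        if self.family == "linear_discriminant":
            return LinearDiscriminantAnalysis(**p)
        if self.family == "perceptron":
            return Perceptron(random_state=random_state, **p)
        if self.family == "decision_tree":
            return DecisionTreeClassifier(random_state=random_state, **p)
        if self.family == "naive_bayes":
            return GaussianNB(**p)
        if self.family == "gbm":
            return GradientBoostingClassifier(random_state=random_state, **p)
        if self.family == "random_forest":
            return RandomForestClassifier(random_state=random_state, **p)
        if self.family == "rbf_svm":
            return SVC(kernel="rbf", **p)
        raise AssertionError(self.family)


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified K-fold settings.

    ``K=None`` means "smallest class size".  ``per_fold_auc`` switches the
    AUC granularity from one pooled AUC per repetition (default) to one
    AUC per fold.
    """

    R: int = 10
    K: int | None = None
    base_seed: int = 0
    n_permutations: int = 100
    standardize: bool = False
    per_fold_auc: bool = False

    def resolve_k(self, y: np.ndarray) -> int:
        smallest = int(min(np.bincount(y.astype(int))))
        k = self.K if self.K is not None else smallest
        if k < 2:
            raise ValueError("K must be >= 2")
        if k > smallest:
            raise ValueError(f"K={k} exceeds smallest class size {smallest}")
        return k


@dataclass(frozen=True)
class PanelData:
    """Zero-substituted panel matrix, samples x variables."""

    values: np.ndarray
    y: np.ndarray  # 1 = positive class
    variable_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def columns(self, signature: Sequence[str]) -> np.ndarray:
        index = {v: i for i, v in enumerate(self.variable_ids)}
        try:
            idx = [index[v] for v in signature]
        except KeyError as exc:
            raise KeyError(f"signature variable {exc} not in panel") from exc
        return self.values[:, idx]


@dataclass
class PairEvaluation:
    signature: tuple[str, ...]
    classifier: ClassifierSpec
    auc_values: np.ndarray
    sensitivity: float
    specificity: float
    precision: float
    n_models: int
    equivalence_p: float | None = None
    permutation_p: float | None = None
    is_top1: bool = False
    selected: bool = False
    high_performance: bool = False
    error: str | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_values))


def prepare_panel(
    table: pd.DataFrame, labels: Mapping[str, str]
) -> PanelData:
    """Build the model matrix from a variables x samples table.

    Missing values are replaced with 0; samples without a label are
    dropped.
    """
    samples = [s for s in table.columns if s in labels]
    if not samples:
        raise ValueError("no labeled samples in panel")
    X = table[samples].T.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    y = np.array([1 if labels[s] == POSITIVE else 0 for s in samples], dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    return PanelData(
        values=X,
        y=y,
        variable_ids=tuple(str(v) for v in table.index),
        sample_ids=tuple(samples),
    )


def enumerate_signatures(
    variable_ids: Sequence[str], max_size: int = 5
) -> Iterator[tuple[str, ...]]:
    """Stream all nonempty subsets up to ``max_size``, size then
    lexicographic order, each exactly once."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    ids = sorted(set(variable_ids))
    if not ids:
        raise ValueError("variable list is empty")
    if len(ids) != len(variable_ids):
        raise ValueError("variable ids must be unique")
    for k in range(1, min(max_size, len(ids)) + 1):
        yield from itertools.combinations(ids, k)


def count_signatures(n_variables: int, max_size: int = 5) -> int:
    """Closed-form candidate count: sum_k C(V, k) for k = 1..max_size."""
    return sum(math.comb(n_variables, k) for k in range(1, min(max_size, n_variables) + 1))


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0])


def make_splits(
    y: np.ndarray,
    R: int,
    K: int,
    base_seed: int,
    salt: tuple[int, ...] = (),
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Stratified K-fold partitions for each repetition.

    Seeded from (base_seed, salt..., repetition); if a training fold ever
    misses a class the repetition is repartitioned with the next seed.
    """
    splits = []
    for r in range(R):
        attempt = 0
        while True:
            seed = _derive_seed(base_seed, *salt, r, attempt)
            skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
            folds = [(tr, te) for tr, te in skf.split(np.zeros_like(y), y)]
            if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
                break
            attempt += 1
            warnings.warn(
                f"repartitioned repetition {r} (single-class training fold)"
            )
        splits.append(folds)
    return splits


def _continuous_score(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Continuous score plus the model's native decision threshold."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float), 0.0
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float), 0.5


def cv_auc_distribution(
    panel: PanelData,
    signature: Sequence[str],
    classifier: ClassifierSpec,
    cv: CVConfig,
    splits: list[list[tuple[np.ndarray, np.ndarray]]] | None = None,
) -> PairEvaluation:
    """Evaluate one <signature, classifier> pair.

    Trains exactly R*K models; per repetition the held-out continuous
    scores are pooled into one ROC AUC (positive class = 1, ties count
    0.5 via the trapezoidal ROC).  Hard predictions pooled over all folds
    give sensitivity, specificity and precision at the classifier's
    native threshold.
    """
    X = panel.columns(signature)
    y = panel.y
    K = cv.resolve_k(y)
    if splits is None:
        splits = make_splits(y, cv.R, K, cv.base_seed)

    fit_seed = _derive_seed(cv.base_seed, 9973)
    aucs: list[float] = []
    tp = fp = tn = fn = 0
    n_models = 0
    with config_context(assume_finite=True):
        for folds in splits:
            rep_true: list[np.ndarray] = []
            rep_score: list[np.ndarray] = []
            fold_aucs: list[float] = []
            for train, test in folds:
                Xtr, Xte = X[train], X[test]
                if cv.standardize:
                    scaler = StandardScaler().fit(Xtr)
                    Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
                model = classifier.make(random_state=fit_seed)
                model.fit(Xtr, y[train])
                n_models += 1
                scores, threshold = _continuous_score(model, Xte)
                # hard calls at the classifier's native threshold
                preds = (scores > threshold).astype(int)
                yt = y[test]
                tp += int(((preds == 1) & (yt == 1)).sum())
                fp += int(((preds == 1) & (yt == 0)).sum())
                tn += int(((preds == 0) & (yt == 0)).sum())
                fn += int(((preds == 0) & (yt == 1)).sum())
                rep_true.append(yt)
                rep_score.append(scores)
                if cv.per_fold_auc and len(np.unique(yt)) == 2:
                    fold_aucs.append(_auc(yt, scores))
            if cv.per_fold_auc:
                aucs.extend(fold_aucs)
            else:
                aucs.append(_auc(np.concatenate(rep_true), np.concatenate(rep_score)))

    return PairEvaluation(
        signature=tuple(signature),
        classifier=classifier,
        auc_values=np.asarray(aucs, dtype=float),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        n_models=n_models,
    )


def _auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    if len(np.unique(scores)) == 1:
        return 0.5  # constant score: every ranking tie contributes 0.5
    return float(roc_auc_score(y_true, scores))


def evaluate_all_pairs(
    panel: PanelData,
    candidates: Iterable[Sequence[str]],
    classifiers: Sequence[ClassifierSpec],
    cv: CVConfig,
) -> list[PairEvaluation]:
    """Evaluate every candidate x classifier pair on shared fold splits.

    Per-pair failures are recorded on the evaluation and do not stop the
    run.
    """
    y = panel.y
    K = cv.resolve_k(y)
    splits = make_splits(y, cv.R, K, cv.base_seed)
    out: list[PairEvaluation] = []
    for signature in candidates:
        for spec in classifiers:
            try:
                out.append(
                    cv_auc_distribution(panel, signature, spec, cv, splits=splits)
                )
            except Exception as exc:
                out.append(
                    PairEvaluation(
                        signature=tuple(signature),
                        classifier=spec,
                        auc_values=np.array([np.nan]),
                        sensitivity=float("nan"),
                        specificity=float("nan"),
                        precision=float("nan"),
                        n_models=0,
                        error=f"{type(exc).__name__}: {exc}",
                    )
                )
    return out


def _top1_key(ev: PairEvaluation):
    return (
        -ev.mean_auc,
        len(ev.signature),
        ev.signature,
        CLASSIFIER_FAMILIES.index(ev.classifier.family),
    )


def select_equivalent_to_top1(
    evaluations: Sequence[PairEvaluation], alpha: float = 0.05
) -> list[PairEvaluation]:
    """Mark top-1 and the pairs statistically equivalent to it.

    Equivalence: two-sided equal-variance t-test of the R AUC values
    against top-1's, selected iff p >= alpha.  Identical constant vectors
    are equivalent by definition; with a single zero-variance vector the
    comparison falls back to exact equality of means.
    """
    valid = [ev for ev in evaluations if ev.error is None]
    if not valid:
        raise ValueError("no successful evaluations")
    top1 = min(valid, key=_top1_key)
    for ev in evaluations:
        ev.is_top1 = ev is top1
        ev.selected = False
        ev.equivalence_p = None
    top1.selected = True
    a = top1.auc_values
    for ev in valid:
        if ev.is_top1:
            continue
        b = ev.auc_values
        var_a, var_b = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
        if var_a == 0.0 or var_b == 0.0:
            p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        ev.equivalence_p = p
        ev.selected = p >= alpha
    return list(evaluations)


def permutation_pvalue(
    panel: PanelData,
    signature: Sequence[str],
    classifier: ClassifierSpec,
    cv: CVConfig,
    n_permutations: int | None = None,
    observed: float | None = None,
) -> float:
    """Label-permutation p-value for one pair.

    The statistic is the mean cross-validated AUC; p uses the add-one
    estimator (1 + #{perm >= observed}) / (n + 1), so p = 0 is impossible.
    ``observed`` short-circuits recomputing the statistic when the pair
    was already evaluated under the same CV configuration.
    """
    n_perm = cv.n_permutations if n_permutations is None else n_permutations
    if n_perm < 1:
        raise ValueError("n_permutations must be >= 1")
    if observed is None:
        observed = cv_auc_distribution(panel, signature, classifier, cv).mean_auc
    y = panel.y
    K = cv.resolve_k(y)
    exceed = 0
    for i in range(1, n_perm + 1):
        rng = np.random.default_rng([cv.base_seed, 104729, i])
        y_perm = rng.permutation(y)
        perm_panel = PanelData(
            values=panel.values,
            y=y_perm,
            variable_ids=panel.variable_ids,
            sample_ids=panel.sample_ids,
        )
        splits = make_splits(y_perm, cv.R, K, cv.base_seed, salt=(104729, i))
        stat = cv_auc_distribution(
            perm_panel, signature, classifier, cv, splits=splits
        ).mean_auc
        if stat >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def high_performance_filter(
    evaluations: Sequence[PairEvaluation],
    auc_min: float = 0.85,
    perm_alpha: float = 0.05,
) -> list[PairEvaluation]:
    """Keep selected pairs with mean AUC >= auc_min and permutation
    p <= perm_alpha (both bounds inclusive)."""
    kept = []
    for ev in evaluations:
        ev.high_performance = bool(
            ev.selected
            and ev.permutation_p is not None
            and ev.mean_auc >= auc_min
            and ev.permutation_p <= perm_alpha
        )
        if ev.high_performance:
            kept.append(ev)
    return kept


def marker_frequency(
    evaluations: Sequence[PairEvaluation],
) -> dict[str, float]:
    """Percent of distinct high-performance signatures containing each
    variable."""
    signatures = {ev.signature for ev in evaluations}
    if not signatures:
        return {}
    counts: dict[str, int] = {}
    for sig in signatures:
        for v in sig:
            counts[v] = counts.get(v, 0) + 1
    total = len(signatures)
    return {v: 100.0 * c / total for v, c in sorted(counts.items())}


def roc_points(
    panel: PanelData,
    signature: Sequence[str],
    classifier: ClassifierSpec,
    cv: CVConfig,
) -> pd.DataFrame:
    """Pooled out-of-fold ROC coordinates (first repetition)."""
    X = panel.columns(signature)
    y = panel.y
    K = cv.resolve_k(y)
    folds = make_splits(y, 1, K, cv.base_seed)[0]
    fit_seed = _derive_seed(cv.base_seed, 9973)
    trues, scores = [], []
    for train, test in folds:
        model = classifier.make(random_state=fit_seed)
        model.fit(X[train], y[train])
        trues.append(y[test])
        scores.append(_continuous_score(model, X[test])[0])
    fpr, tpr, thr = roc_curve(np.concatenate(trues), np.concatenate(scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def run_search(
    panel: PanelData,
    max_size: int = 5,
    classifiers: Sequence[ClassifierSpec] | None = None,
    cv: CVConfig | None = None,
    auc_min: float = 0.85,
    perm_alpha: float = 0.05,
    candidate_cap: int | None = None,
) -> dict:
    """Full pipeline: enumerate, evaluate, select, permute, filter.

    Permutation tests run only for selected pairs that already clear the
    AUC floor (the others cannot become high-performance).  Returns a
    report dict with all evaluations, the high-performance set and the
    marker-frequency table.
    """
    cv = cv or CVConfig()
    if classifiers is None:
        classifiers = tuple(ClassifierSpec(f) for f in CLASSIFIER_FAMILIES)
    candidates = enumerate_signatures(panel.variable_ids, max_size)
    if candidate_cap is not None:
        candidates = itertools.islice(candidates, candidate_cap)
    evaluations = evaluate_all_pairs(panel, list(candidates), classifiers, cv)
    select_equivalent_to_top1(evaluations)
    for ev in evaluations:
        if ev.selected and ev.error is None and ev.mean_auc >= auc_min:
            ev.permutation_p = permutation_pvalue(
                panel, ev.signature, ev.classifier, cv, observed=ev.mean_auc
            )
    high = high_performance_filter(evaluations, auc_min=auc_min, perm_alpha=perm_alpha)
    top1 = next(ev for ev in evaluations if ev.is_top1)
    return {
        "evaluations": evaluations,
        "top1": top1,
        "high_performance": high,
        "marker_frequency": marker_frequency(high),
    }


def evaluations_to_frame(evaluations: Sequence[PairEvaluation]) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        rows.append(
            {
                "signature": "+".join(ev.signature),
                "classifier": ev.classifier.family,
                "mean_auc": ev.mean_auc,
                "auc_sd": float(np.std(ev.auc_values, ddof=1))
                if len(ev.auc_values) > 1
                else 0.0,
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
                "precision": ev.precision,
                "equivalence_p": ev.equivalence_p,
                "permutation_p": ev.permutation_p,
                "is_top1": ev.is_top1,
                "selected": ev.selected,
                "high_performance": ev.high_performance,
                "n_models": ev.n_models,
                "error": ev.error,
            }
        )
    return pd.DataFrame(rows)
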