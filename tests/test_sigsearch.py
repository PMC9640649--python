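import numpy as np
import pandas as pd
import pytest

from nodesig import sigsearch, simulate
from nodesig.io import NEGATIVE, POSITIVE
from nodesig.sigsearch import (
    CLASSIFIER_FAMILIES,
    ClassifierSpec,
    CVConfig,
    PairEvaluation,
)

from .oracles import auc_rank_oracle


def _label_panel(n_pos=10, n_neg=10, noise=0.01, seed=0, extra_noise_vars=0):
    """Panel whose first variable is the label plus tiny noise."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_pos + [0] * n_neg)
    cols = [f"pos{i:02d}" for i in range(n_pos)] + [
        f"neg{i:02d}" for i in range(n_neg)
    ]
    rows = {"labelcopy": y + rng.normal(0, noise, size=len(y))}
    for j in range(extra_noise_vars):
        rows[f"noise{j}"] = rng.normal(size=len(y))
    table = pd.DataFrame(rows, index=cols).T
    labels = {c: POSITIVE if c.startswith("pos") else NEGATIVE for c in cols}
    return sigsearch.prepare_panel(table, labels)


class TestEnumeration:
    def test_count_v6(self):
        cands = list(sigsearch.enumerate_signatures([f"v{i}" for i in range(6)], 5))
        assert len(cands) == 62

    def test_count_v3_all_subsets(self):
        cands = list(sigsearch.enumerate_signatures(["a", "b", "c"], 5))
        assert len(cands) == 7

    def test_closed_form_counts(self):
        assert sigsearch.count_signatures(6, 5) == 62
        assert sigsearch.count_signatures(45, 5) == 1_385_979
        assert sigsearch.count_signatures(3, 5) == 7

    def test_order_size_then_lexicographic(self):
        cands = list(sigsearch.enumerate_signatures(["b", "a", "c"], 2))
        assert cands == [
            ("a",), ("b",), ("c",),
            ("a", "b"), ("a", "c"), ("b", "c"),
        ]

    def test_uniqueness(self):
        cands = list(sigsearch.enumerate_signatures([f"v{i}" for i in range(7)], 3))
        assert len(cands) == len(set(cands))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            list(sigsearch.enumerate_signatures([], 3))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            list(sigsearch.enumerate_signatures(["a", "a"], 2))


class TestPreparePanel:
    def test_zero_substitution(self):
        table = pd.DataFrame(
            {"pos01": [1.0, np.nan], "neg01": [np.nan, 2.0]},
            index=["v1", "v2"],
        )
        labels = {"pos01": POSITIVE, "neg01": NEGATIVE}
        panel = sigsearch.prepare_panel(table, labels)
        np.testing.assert_allclose(panel.values, [[1.0, 0.0], [0.0, 2.0]])

    def test_single_class_rejected(self):
        table = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["v"])
        with pytest.raises(ValueError):
            sigsearch.prepare_panel(
                table, {"s1": POSITIVE, "s2": POSITIVE}
            )


class TestCvAucDistribution:
    def test_perfect_separator(self):
        panel = _label_panel()
        cv = CVConfig(R=5, K=3, base_seed=1)
        ev = sigsearch.cv_auc_distribution(
            panel, ("labelcopy",), ClassifierSpec("ridge"), cv
        )
        np.testing.assert_allclose(ev.auc_values, 1.0)
        assert ev.sensitivity == 1.0
        assert ev.specificity == 1.0

    def test_constant_variable_auc_half(self):
        table = pd.DataFrame(
            {f"pos{i}": [3.0] for i in range(5)}
            | {f"neg{i}": [3.0] for i in range(5)},
            index=["flat"],
        )
        labels = {
            c: POSITIVE if c.startswith("pos") else NEGATIVE
            for c in table.columns
        }
        panel = sigsearch.prepare_panel(table, labels)
        cv = CVConfig(R=4, K=2, base_seed=2)
        ev = sigsearch.cv_auc_distribution(
            panel, ("flat",), ClassifierSpec("naive_bayes"), cv
        )
        np.testing.assert_allclose(ev.auc_values, 0.5)

    def test_budget_identity_7_12(self):
        panel = _label_panel(n_pos=7, n_neg=12, seed=3)
        cv = CVConfig(R=10, base_seed=4)  # K defaults to smallest class = 7
        assert cv.resolve_k(panel.y) == 7
        ev = sigsearch.cv_auc_distribution(
            panel, ("labelcopy",), ClassifierSpec("naive_bayes"), cv
        )
        assert len(ev.auc_values) == 10
        assert ev.n_models == 70

    def test_k_exceeding_class_size_rejected(self):
        panel = _label_panel(n_pos=4, n_neg=10)
        with pytest.raises(ValueError):
            CVConfig(R=2, K=5, base_seed=0).resolve_k(panel.y)

    def test_unknown_signature_variable(self):
        panel = _label_panel()
        with pytest.raises(KeyError):
            sigsearch.cv_auc_distribution(
                panel, ("ghost",), ClassifierSpec("ridge"), CVConfig(R=2, K=2)
            )

    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_every_family_runs(self, family):
        panel = _label_panel(n_pos=8, n_neg=8, seed=5)
        cv = CVConfig(R=2, K=2, base_seed=6)
        ev = sigsearch.cv_auc_distribution(
            panel, ("labelcopy",), ClassifierSpec(family), cv
        )
        assert ev.mean_auc >= 0.9  # trivially separable for every family

    def test_auc_label_flip_symmetry(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=40)
        y[:3], y[3:6] = 1, 0
        scores = rng.normal(size=40)
        auc = sigsearch._auc(y, scores)
        flipped = sigsearch._auc(1 - y, -scores)
        assert flipped == pytest.approx(auc, abs=1e-12)
        assert auc == pytest.approx(auc_rank_oracle(y, scores), abs=1e-12)


class TestEvaluateAllPairs:
    def test_pair_count(self):
        panel = _label_panel(extra_noise_vars=5, seed=7)
        cands = list(sigsearch.enumerate_signatures(panel.variable_ids, 5))
        assert len(cands) == 62
        specs = [ClassifierSpec("naive_bayes"), ClassifierSpec("ridge")]
        cv = CVConfig(R=2, K=2, base_seed=8)
        evs = sigsearch.evaluate_all_pairs(panel, cands, specs, cv)
        assert len(evs) == 124

    def test_determinism(self):
        panel = _label_panel(extra_noise_vars=2, seed=9)
        cands = list(sigsearch.enumerate_signatures(panel.variable_ids, 2))
        specs = [ClassifierSpec("linear_discriminant")]
        cv = CVConfig(R=3, K=2, base_seed=10)
        a = sigsearch.evaluate_all_pairs(panel, cands, specs, cv)
        b = sigsearch.evaluate_all_pairs(panel, cands, specs, cv)
        np.testing.assert_array_equal(
            [ev.mean_auc for ev in a], [ev.mean_auc for ev in b]
        )

    def test_shared_splits_across_pairs(self):
        # a duplicated variable must give identical AUC vectors
        rng = np.random.default_rng(12)
        y = np.array([1] * 8 + [0] * 8)
        x = y + rng.normal(0, 0.5, 16)
        cols = [f"pos{i}" for i in range(8)] + [f"neg{i}" for i in range(8)]
        table = pd.DataFrame({"v1": x, "v2": x}, index=cols).T
        labels = {c: POSITIVE if c.startswith("pos") else NEGATIVE for c in cols}
        panel = sigsearch.prepare_panel(table, labels)
        cv = CVConfig(R=4, K=2, base_seed=13)
        evs = sigsearch.evaluate_all_pairs(
            panel, [("v1",), ("v2",)], [ClassifierSpec("ridge")], cv
        )
        np.testing.assert_allclose(evs[0].auc_values, evs[1].auc_values)


def _fake_eval(signature, aucs, family="ridge", perm_p=None):
    arr = np.asarray(aucs, dtype=float)
    ev = PairEvaluation(
        signature=tuple(signature),
        classifier=ClassifierSpec(family),
        auc_values=arr,
        sensitivity=0.9,
        specificity=0.9,
        precision=0.9,
        n_models=len(arr),
        permutation_p=perm_p,
    )
    return ev


class TestSelection:
    def test_single_evaluation_is_top1(self):
        evs = [_fake_eval(["a"], [0.7] * 10)]
        sigsearch.select_equivalent_to_top1(evs)
        assert evs[0].is_top1 and evs[0].selected

    def test_identical_constants_equivalent(self):
        evs = [
            _fake_eval(["a"], [1.0] * 10),
            _fake_eval(["b"], [1.0] * 10),
            _fake_eval(["c"], [0.5] * 10),
        ]
        sigsearch.select_equivalent_to_top1(evs)
        selected = {ev.signature[0] for ev in evs if ev.selected}
        assert selected == {"a", "b"}
        assert evs[2].equivalence_p == 0.0

    def test_clearly_inferior_excluded(self):
        rng = np.random.default_rng(14)
        evs = [
            _fake_eval(["a"], rng.normal(0.9, 0.02, 10)),
            _fake_eval(["b"], rng.normal(0.6, 0.02, 10)),
        ]
        sigsearch.select_equivalent_to_top1(evs)
        assert evs[0].is_top1
        assert not evs[1].selected
        assert evs[1].equivalence_p < 0.05

    def test_tie_break_smaller_signature(self):
        evs = [
            _fake_eval(["a", "b"], [0.9] * 10),
            _fake_eval(["a"], [0.9] * 10),
        ]
        sigsearch.select_equivalent_to_top1(evs)
        top = next(ev for ev in evs if ev.is_top1)
        assert top.signature == ("a",)

    def test_tie_break_classifier_order(self):
        evs = [
            _fake_eval(["a"], [0.9] * 10, family="linear_svm"),
            _fake_eval(["a"], [0.9] * 10, family="ridge"),
        ]
        sigsearch.select_equivalent_to_top1(evs)
        top = next(ev for ev in evs if ev.is_top1)
        assert top.classifier.family == "ridge"


class TestPermutation:
    def test_perfect_separator_minimum_p(self):
        panel = _label_panel(n_pos=6, n_neg=6, seed=15)
        cv = CVConfig(R=3, K=3, base_seed=16)
        p = sigsearch.permutation_pvalue(
            panel, ("labelcopy",), ClassifierSpec("ridge"), cv,
            n_permutations=99,
        )
        assert p == pytest.approx(0.01)

    def test_observed_below_all_gives_one(self):
        evs_p = sigsearch.permutation_pvalue(
            _label_panel(n_pos=6, n_neg=6, seed=17),
            ("labelcopy",),
            ClassifierSpec("ridge"),
            CVConfig(R=2, K=2, base_seed=18),
            n_permutations=10,
            observed=0.0,  # below any permuted statistic
        )
        assert evs_p == 1.0

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            sigsearch.permutation_pvalue(
                _label_panel(),
                ("labelcopy",),
                ClassifierSpec("ridge"),
                CVConfig(R=2, K=2),
                n_permutations=0,
            )


class TestHighPerformanceFilter:
    def test_threshold_combinations(self):
        evs = [
            _fake_eval(["a"], [0.90] * 5, perm_p=0.01),
            _fake_eval(["b"], [0.90] * 5, perm_p=0.20),
            _fake_eval(["c"], [0.80] * 5, perm_p=0.01),
        ]
        for ev in evs:
            ev.selected = True
        kept = sigsearch.high_performance_filter(evs)
        assert [ev.signature[0] for ev in kept] == ["a"]

    def test_inclusive_boundaries(self):
        ev = _fake_eval(["a"], [0.85] * 5, perm_p=0.05)
        ev.selected = True
        assert sigsearch.high_performance_filter([ev]) == [ev]

    def test_unselected_never_kept(self):
        ev = _fake_eval(["a"], [0.95] * 5, perm_p=0.01)
        ev.selected = False
        assert sigsearch.high_performance_filter([ev]) == []

    def test_empty(self):
        assert sigsearch.high_performance_filter([]) == []


class TestMarkerFrequency:
    def test_simple_counts(self):
        evs = [
            _fake_eval(["A", "B"], [0.9]),
            _fake_eval(["A", "C"], [0.9]),
        ]
        freq = sigsearch.marker_frequency(evs)
        assert freq == {"A": 100.0, "B": 50.0, "C": 50.0}

    def test_distinct_signatures_only(self):
        evs = [
            _fake_eval(["A"], [0.9], family="ridge"),
            _fake_eval(["A"], [0.9], family="naive_bayes"),
            _fake_eval(["B"], [0.9]),
        ]
        freq = sigsearch.marker_frequency(evs)
        assert freq == {"A": 50.0, "B": 50.0}

    def test_empty(self):
        assert sigsearch.marker_frequency([]) == {}


class TestRunSearch:
    def test_end_to_end_small(self, planted_panel):
        table, truth = planted_panel
        sub = table.iloc[:5]  # 2 planted + 3 noise variables
        panel = sigsearch.prepare_panel(sub, simulate.group_labels(sub))
        cv = CVConfig(R=4, K=2, base_seed=19, n_permutations=19)
        report = sigsearch.run_search(
            panel,
            max_size=2,
            classifiers=(ClassifierSpec("naive_bayes"),),
            cv=cv,
        )
        assert len(report["evaluations"]) == 15
        top1 = report["top1"]
        assert any(v in truth.informative_variables for v in top1.signature)
        for ev in report["high_performance"]:
            assert ev.permutation_p is not None
            assert ev.mean_auc >= 0.85

    def test_candidate_cap(self, planted_panel):
        table, _ = planted_panel
        sub = table.iloc[:4]
        panel = sigsearch.prepare_panel(sub, simulate.group_labels(sub))
        cv = CVConfig(R=2, K=2, base_seed=20, n_permutations=5)
        report = sigsearch.run_search(
            panel,
            max_size=2,
            classifiers=(ClassifierSpec("naive_bayes"),),
            cv=cv,
            candidate_cap=3,
        )
        assert len(report["evaluations"]) == 3


def test_roc_points_monotone(planted_panel):
    table, _ = planted_panel
    sub = table.iloc[:3]
    panel = sigsearch.prepare_panel(sub, simulate.group_labels(sub))
    roc = sigsearch.roc_points(
        panel,
        (panel.variable_ids[0],),
        ClassifierSpec("ridge"),
        CVConfig(R=1, K=2, base_seed=21),
    )
    assert (roc["fpr"].diff().dropna() >= 0).all()
    assert (roc["tpr"].diff().dropna() >= 0).all()


def test_evaluations_to_frame(planted_panel):
    table, _ = planted_panel
    sub = table.iloc[:3]
    panel = sigsearch.prepare_panel(sub, simulate.group_labels(sub))
    evs = sigsearch.evaluate_all_pairs(
        panel,
        [("M00|protein",)],
        [ClassifierSpec("ridge")],
        CVConfig(R=2, K=2, base_seed=22),
    )
    frame = sigsearch.evaluations_to_frame(evs)
    assert list(frame["classifier"]) == ["ridge"]
    assert frame.loc[0, "n_models"] == 4
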