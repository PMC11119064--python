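"""Split protocol, metric panel (vs counting oracle), and significance tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fcnets.evaluation import (ModelSpec, SplitPlan, binomial_significance,
                               compute_metrics, make_splits, run_benchmark,
                               wilcoxon_compare)
from fcnets.synthetic import SimSpec, generate_cohort

from conftest import null_cohort


class TestMakeSplits:
    def cohort100(self):
        cohort, _ = generate_cohort(SimSpec(n_regions=8, n_per_class=(50, 50),
                                            n_timepoints=60, seed=0))
        return cohort

    def test_protocol_arithmetic(self):
        cohort = self.cohort100()
        test_idx, folds = make_splits(cohort, SplitPlan(seed=1))
        assert len(test_idx) == 10
        assert len(folds) == 5
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == sorted(set(range(100)) - set(test_idx))
        for tr, va in folds:
            assert len(tr) + len(va) == 90
            assert set(tr).isdisjoint(va)
            assert set(tr).isdisjoint(test_idx)
            assert set(va).isdisjoint(test_idx)

    def test_deterministic_under_seed(self):
        cohort = self.cohort100()
        a = make_splits(cohort, SplitPlan(seed=3))
        b = make_splits(cohort, SplitPlan(seed=3))
        assert np.array_equal(a[0], b[0])
        for (tr1, va1), (tr2, va2) in zip(a[1], b[1]):
            assert np.array_equal(tr1, tr2) and np.array_equal(va1, va2)

    def test_stratified_folds_balanced(self):
        cohort = self.cohort100()
        y = cohort.labels()
        _, folds = make_splits(cohort, SplitPlan(seed=2))
        for _, va in folds:
            ratio = np.mean(y[va] == 1)
            assert abs(ratio - 0.5) <= 1.0 / len(va)  # within +-1 subject


def metrics_counting_oracle(y_true, y_pred, n_classes):
    """Naive per-class counting, fully independent of sklearn."""
    out = {}
    classes = [1] if n_classes == 2 else range(n_classes)
    precs, recs, specs = [], [], []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = len(y_true) - tp - fp - fn
        if tp + fp:
            precs.append(tp / (tp + fp))
        if tp + fn:
            recs.append(tp / (tp + fn))
        if tn + fp:
            specs.append(tn / (tn + fp))
    out["accuracy"] = np.mean(np.array(y_true) == np.array(y_pred))
    out["precision"] = np.mean(precs) if precs else np.nan
    out["recall"] = np.mean(recs) if recs else np.nan
    out["specificity"] = np.mean(specs) if specs else np.nan
    return out


class TestComputeMetrics:
    def test_binary_hand_example(self):
        y_true = np.array([1] * 4 + [0] * 6)
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])  # TP3 FN1 FP1 TN5
        r = compute_metrics(y_true, y_pred, None, 2)
        assert r.accuracy == pytest.approx(0.8)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.75)
        assert r.specificity == pytest.approx(5 / 6)
        assert r.f1 == pytest.approx(0.75)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1, 1])
        scores = np.eye(2)[y]
        r = compute_metrics(y, y, scores, 2)
        assert (r.accuracy, r.precision, r.recall, r.specificity, r.f1,
                r.auc) == (1, 1, 1, 1, 1, 1)

    def test_diagonal_three_class_table(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        scores = np.eye(3)[y]
        r = compute_metrics(y, y, scores, 3)
        assert r.precision == r.recall == r.f1 == 1.0

    def test_undefined_class_excluded_with_note(self):
        # class 2 never predicted: its precision is undefined
        y_true = np.array([0, 1, 2, 0, 1, 2])
        y_pred = np.array([0, 1, 0, 0, 1, 1])
        r = compute_metrics(y_true, y_pred, None, 3)
        assert any("precision undefined" in n for n in r.notes)
        assert not np.isnan(r.precision)

    @given(st.integers(0, 5000), st.integers(2, 4), st.integers(10, 200))
    @settings(deadline=None, max_examples=60)
    def test_matches_counting_oracle(self, seed, n_classes, n):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, n_classes, size=n)
        y_pred = rng.integers(0, n_classes, size=n)
        r = compute_metrics(y_true, y_pred, None, n_classes)
        oracle = metrics_counting_oracle(y_true, y_pred, n_classes)
        for key, val in oracle.items():
            got = getattr(r, key)
            if np.isnan(val):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(val, abs=1e-12)


class TestBinomialSignificance:
    def test_all_correct_single_term(self):
        assert binomial_significance(10, 10, 0.5) == pytest.approx(0.5 ** 10)

    def test_none_correct_whole_distribution(self):
        assert binomial_significance(0, 10, 0.5) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        from math import comb
        for n in range(1, 26):
            for k in range(n + 1):
                oracle = sum(comb(n, j) for j in range(k, n + 1)) / 2 ** n
                assert binomial_significance(k, n, 0.5) == pytest.approx(
                    oracle, rel=1e-12)

    def test_monotone_decreasing_in_successes(self):
        ps = [binomial_significance(k, 30, 0.5) for k in range(31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            binomial_significance(0, 0)


def ranksum_enumeration_oracle(a, b):
    """Exhaustive rank-assignment enumeration with mid-ranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    observed = ranks[: len(a)].sum()
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), len(a)):
        total += 1
        if ranks[list(combo)].sum() >= observed - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxonCompare:
    def test_textbook_example(self):
        assert wilcoxon_compare([4, 5, 6], [1, 2, 3]) == pytest.approx(0.05)

    def test_identical_lists_give_no_evidence(self):
        assert wilcoxon_compare([1, 2, 3], [1, 2, 3]) >= 0.5

    def test_degenerate_constant_data_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert wilcoxon_compare([1, 1], [1, 1]) == 1.0

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            na, nb = rng.integers(2, 6), rng.integers(2, 6)
            a = rng.integers(0, 8, size=na) / 7  # ties likely
            b = rng.integers(0, 8, size=nb) / 7
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            assert wilcoxon_compare(a, b) == pytest.approx(
                ranksum_enumeration_oracle(a, b), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1.0, size=20)
        b = rng.normal(0.0, 1.0, size=20)
        p = wilcoxon_compare(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="greater",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))


class TestRunBenchmark:
    @staticmethod
    def nearest_mean_trainer(train_cohort, val_cohort, seed):
        """Cheap deterministic model: nearest class-mean on FC features."""
        y = train_cohort.labels()
        iu = np.triu_indices(train_cohort.n_regions, k=1)
        feats = np.stack([fc.values[iu] for fc, _ in train_cohort.subjects])
        means = np.stack([feats[y == c].mean(axis=0)
                          for c in range(len(train_cohort.label_names))])

        def predict(cohort):
            f = np.stack([fc.values[iu] for fc, _ in cohort.subjects])
            d = ((f[:, None, :] - means[None]) ** 2).sum(axis=2)
            inv = 1.0 / (d + 1e-12)
            return inv / inv.sum(axis=1, keepdims=True)

        return predict

    def test_single_model_report_valid(self):
        cohort, _ = generate_cohort(SimSpec(n_regions=10, n_per_class=(20, 20),
                                            n_timepoints=80, seed=1))
        spec = ModelSpec("nearest-mean", self.nearest_mean_trainer)
        report = run_benchmark(cohort, [spec], SplitPlan(seed=0))
        r = report.reports["nearest-mean"]
        assert len(r.fold_accuracies) == 5
        assert 0.0 <= r.accuracy <= 1.0
        assert r.binomial_p is not None
        assert report.wilcoxon_p == {}

    def test_two_models_compared_and_deterministic(self):
        cohort = null_cohort(seed=2, n_per_class=(20, 20), n_regions=10,
                             n_timepoints=60)

        def noisy_trainer(train_cohort, val_cohort, seed):
            rng = np.random.default_rng(seed)
            n_classes = len(train_cohort.label_names)

            def predict(c):
                p = rng.dirichlet(np.ones(n_classes), size=c.n_subjects)
                return p
            return predict

        specs = [ModelSpec("nearest-mean", self.nearest_mean_trainer),
                 ModelSpec("noise", noisy_trainer)]
        r1 = run_benchmark(cohort, specs, SplitPlan(seed=5))
        assert ("nearest-mean", "noise") in r1.wilcoxon_p
        assert set(r1.ranking) == {"nearest-mean", "noise"}
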