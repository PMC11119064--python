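"""Evaluation protocol, metric panel, and significance tests.

Protocol: 10% of subjects are held out as a test set, the remainder is split
by stratified 5-fold cross-validation; each model trains once per fold, the
fold with the best validation accuracy supplies the parameters evaluated
once on the test set.

Metrics: accuracy plus one-vs-rest (macro-averaged) precision, recall /
sensitivity, specificity, F1 and ROC AUC.  Per-class metrics with a zero
denominator (e.g. no positives of a class) are excluded from the macro mean
with a logged note.  In the binary case the panel reduces to the standard
definitions for the designated positive class (by convention the patient,
class index 1).

Significance: an exact one-sided binomial test of the test-set success count
against chance (Bernoulli model of the classifier's outcomes), and a
one-sided Wilcoxon rank-sum test comparing two models' fold accuracies
(exact enumeration with mid-ranks for combined n <= 12, tie-corrected
normal approximation above).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .data_model import Cohort

logger = logging.getLogger(__name__)

__all__ = ["SplitPlan", "EvalReport", "make_splits", "compute_metrics",
           "binomial_significance", "wilcoxon_compare", "run_benchmark",
           "ModelSpec", "BenchmarkReport"]


@dataclass
class SplitPlan:
    """Holdout + cross-validation layout."""

    test_fraction: float = 0.10
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0


@dataclass
class EvalReport:
    """Metric panel for one model."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float
    n_test: int = 0
    n_correct: int = 0
    fold_accuracies: list[float] = field(default_factory=list)
    binomial_p: Optional[float] = None
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "auc": self.auc, "n_test": self.n_test,
            "n_correct": self.n_correct,
            "fold_accuracies": list(self.fold_accuracies),
            "binomial_p": self.binomial_p, "notes": list(self.notes),
        }


def make_splits(cohort: Cohort, plan: SplitPlan
                ) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Return (test indices, [(train idx, validation idx), ...]).

    Test indices are disjoint from every fold; each non-test subject appears
    in exactly one validation fold.  Deterministic under ``plan.seed``.
    """
    y = cohort.labels()
    n = cohort.n_subjects
    idx = np.arange(n)
    if plan.stratified:
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=plan.test_fraction,
                                          random_state=plan.seed)
        rest_idx, test_idx = next(splitter.split(idx[:, None], y))
    else:
        rng = np.random.default_rng(plan.seed)
        perm = rng.permutation(n)
        n_test = int(round(plan.test_fraction * n))
        test_idx, rest_idx = perm[:n_test], perm[n_test:]
    rest_idx, test_idx = np.sort(rest_idx), np.sort(test_idx)

    y_rest = y[rest_idx]
    missing = set(range(len(cohort.label_names))) - set(y_rest.tolist())
    if missing:
        msg = f"classes {sorted(missing)} absent from the training pool"
        if plan.stratified:
            raise ValueError(msg)
        warnings.warn(msg)

    if plan.stratified:
        kf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True,
                             random_state=plan.seed)
        fold_iter = kf.split(rest_idx[:, None], y_rest)
    else:
        from sklearn.model_selection import KFold
        kf = KFold(n_splits=plan.n_folds, shuffle=True, random_state=plan.seed)
        fold_iter = kf.split(rest_idx[:, None])
    folds = [(rest_idx[tr], rest_idx[va]) for tr, va in fold_iter]
    return test_idx, folds


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    y_scores: Optional[np.ndarray], n_classes: int,
                    positive_class: int = 1) -> EvalReport:
    """Accuracy plus OvR macro precision/recall/specificity/F1/AUC.

    ``y_scores`` is the (n, n_classes) probability matrix (may be None; AUC
    is then reported as nan).  Binary problems use the standard
    single-positive-class definitions.
    """
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = y_true.size
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    accuracy = float(np.trace(cm)) / n
    notes: list[str] = []

    classes = ([positive_class] if n_classes == 2 else list(range(n_classes)))
    precisions, recalls, specifics, f1s, aucs = [], [], [], [], []
    for c in classes:
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        tn = n - tp - fp - fn
        if tp + fp > 0:
            precisions.append(tp / (tp + fp))
        else:
            notes.append(f"class {c}: precision undefined (no predicted positives)")
        if tp + fn > 0:
            recalls.append(tp / (tp + fn))
        else:
            notes.append(f"class {c}: recall undefined (no true positives)")
        if tn + fp > 0:
            specifics.append(tn / (tn + fp))
        if tp + fp > 0 and tp + fn > 0:
            p_c, r_c = tp / (tp + fp), tp / (tp + fn)
            f1s.append(0.0 if p_c + r_c == 0 else 2 * p_c * r_c / (p_c + r_c))
        if y_scores is not None:
            binary = (y_true == c).astype(int)
            if 0 < binary.sum() < n:
                aucs.append(roc_auc_score(binary, y_scores[:, c]))
            else:
                notes.append(f"class {c}: AUC undefined (single outcome)")
    for note in notes:
        logger.info("compute_metrics: %s", note)

    def macro(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else float("nan")

    return EvalReport(accuracy=accuracy, precision=macro(precisions),
                      recall=macro(recalls), specificity=macro(specifics),
                      f1=macro(f1s), auc=macro(aucs), n_test=n,
                      n_correct=int(np.trace(cm)), notes=notes)


def binomial_significance(n_correct: int, n_total: int, p0: float = 0.5) -> float:
    """One-sided exact binomial tail P(X >= n_correct | n_total, p0).

    Models the classifier's test outcomes as a Bernoulli process; ``p0`` is
    the chance level (0.5 for binary, 1/n_classes for multiclass).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_correct <= n_total):
        raise ValueError("n_correct must lie in [0, n_total]")
    return float(stats.binom.sf(n_correct - 1, n_total, p0))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_compare(acc_a: Sequence[float], acc_b: Sequence[float],
                     exact_max_n: int = 12) -> float:
    """One-sided Wilcoxon rank-sum p-value for H1: A > B.

    Exact null distribution by enumeration of rank assignments (mid-ranks
    for ties) when the combined sample size is <= ``exact_max_n``; a
    tie-corrected normal approximation otherwise.  Identical constant
    samples return p = 1 with a warning.
    """
    a, b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all accuracies identical; rank-sum test is degenerate")
        return 1.0
    n_a, n_tot = a.size, a.size + b.size
    if n_tot <= exact_max_n:
        ranks = _midranks(pooled)
        observed = ranks[:n_a].sum()
        count = total = 0
        for combo in itertools.combinations(range(n_tot), n_a):
            total += 1
            if ranks[list(combo)].sum() >= observed - 1e-12:
                count += 1
        return count / total
    res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass
class ModelSpec:
    """A named training routine for the benchmark harness.

    ``train`` maps (train cohort, validation cohort, seed) to a predictor;
    the predictor maps a cohort to an (n, n_classes) probability matrix.
    """

    name: str
    train: Callable[[Cohort, Cohort, int], Callable[[Cohort], np.ndarray]]


@dataclass
class BenchmarkReport:
    reports: dict[str, EvalReport]
    wilcoxon_p: dict[tuple[str, str], float]
    ranking: list[str]  # worst -> best by test accuracy

    def as_dict(self) -> dict:
        return {
            "models": {k: v.as_dict() for k, v in self.reports.items()},
            "wilcoxon_p": {f"{a}>{b}": p for (a, b), p in self.wilcoxon_p.items()},
            "ranking_worst_to_best": list(self.ranking),
        }


def run_benchmark(cohort: Cohort, models: Sequence[ModelSpec],
                  plan: SplitPlan) -> BenchmarkReport:
    """Train/evaluate each model under the holdout + 5-fold CV protocol.

    Per model: one training per fold with validation-accuracy model
    selection across folds; the selected predictor is evaluated once on the
    held-out test set.  Pairwise one-sided Wilcoxon tests compare fold
    accuracies; per-model exact binomial tests compare the test success
    count against chance (1/n_classes).
    """
    test_idx, folds = make_splits(cohort, plan)
    test_cohort = cohort.subset(test_idx)
    n_classes = len(cohort.label_names)
    y_test = test_cohort.labels()

    reports: dict[str, EvalReport] = {}
    for m, spec in enumerate(models):
        fold_accs, best_acc, best_predict = [], -1.0, None
        for f, (tr, va) in enumerate(folds):
            seed = plan.seed * 1_000 + m * 100 + f
            predict = spec.train(cohort.subset(tr), cohort.subset(va), seed)
            val_cohort = cohort.subset(va)
            probs = predict(val_cohort)
            acc = float(np.mean(probs.argmax(axis=1) == val_cohort.labels()))
            fold_accs.append(acc)
            if acc > best_acc:
                best_acc, best_predict = acc, predict
        probs = best_predict(test_cohort)
        report = compute_metrics(y_test, probs.argmax(axis=1), probs, n_classes)
        report.fold_accuracies = fold_accs
        report.binomial_p = binomial_significance(report.n_correct, report.n_test,
                                                  p0=1.0 / n_classes)
        reports[spec.name] = report
        logger.info("benchmark: %s test accuracy %.3f (folds %s)",
                    spec.name, report.accuracy,
                    np.round(fold_accs, 3).tolist())

    wilcoxon_p: dict[tuple[str, str], float] = {}
    names = [s.name for s in models]
    for a, b in itertools.combinations(names, 2):
        wilcoxon_p[(a, b)] = wilcoxon_compare(reports[a].fold_accuracies,
                                              reports[b].fold_accuracies)
        wilcoxon_p[(b, a)] = wilcoxon_compare(reports[b].fold_accuracies,
                                              reports[a].fold_accuracies)
    ranking = sorted(names, key=lambda nm: reports[nm].accuracy)
    return BenchmarkReport(reports=reports, wilcoxon_p=wilcoxon_p, ranking=ranking)
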