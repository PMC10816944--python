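"""Ensemble-learning benchmark: 15 classifier families on one design matrix.

The comparison follows the standard protocol for this kind of feature study:
a stratified 70/30 train/test split, 5-fold cross-validated evaluation of
every roster family on the training portion, selection of the family with
the highest mean CV accuracy, and a held-out test set kept untouched for
bootstrap validation.

Metrics come straight from the binary confusion matrix with the severity
level as the positive class:

    ACC     = (TP + TN) / (TP + TN + FP + FN)
    AUC_cm  = 1 - 1/2 (FP/(FP+TN) + FN/(FN+TP))        (balanced accuracy)
    prec    = TP / (TP + FP),  rec = TP / (TP + FN)
    F1      = 2 prec rec / (prec + rec)

Two AUC variants are reported side by side: the confusion-matrix formula
above (a single-threshold quantity) and the usual rank-based AUC — the
probability that a random positive's score exceeds a random negative's,
ties counting one half.

The public surface is the model/results pair: build an
:class:`EnsembleBenchmark` from a design matrix, call :meth:`fit`, and read
the ranked table, the selected classifier and the bootstrap validation off
the returned :class:`BenchmarkResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .models import DesignMatrix

__all__ = [
    "ClassifierSpec",
    "DEFAULT_ROSTER",
    "MetricSet",
    "compute_metrics",
    "cross_validate_classifier",
    "run_benchmark",
    "EnsembleBenchmark",
    "BenchmarkResults",
]

#: Seed echoed from the study's published hyperparameter table.
DEFAULT_SEED = 123


@dataclass(frozen=True)
class ClassifierSpec:
    """One roster member: a classifier family plus its preset hyperparameters."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def make_estimator(self, seed: int = DEFAULT_SEED):
        """Instantiate a fresh scikit-learn-compatible estimator."""
        builder = _FAMILIES.get(self.family)
        if builder is None:
            raise ValueError(f"unknown classifier family {self.family!r}")
        return builder(seed, dict(self.hyperparameters))


def _build_lightgbm(seed, hp):
    from lightgbm import LGBMClassifier

    hp.setdefault("boosting_type", "gbdt")
    hp.setdefault("n_estimators", 100)
    hp.setdefault("num_leaves", 31)
    hp.setdefault("learning_rate", 0.1)
    return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **hp)


def _build_xgboost(seed, hp):
    from xgboost import XGBClassifier

    hp.setdefault("booster", "gbtree")
    hp.setdefault("n_estimators", 100)
    return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **hp)


_FAMILIES = {
    "naive-bayes": lambda seed, hp: GaussianNB(**hp),
    "random-forest": lambda seed, hp: RandomForestClassifier(
        criterion=hp.pop("criterion", "gini"),
        n_estimators=hp.pop("n_estimators", 100),
        random_state=seed,
        n_jobs=1,
        **hp,
    ),
    "linear-discriminant": lambda seed, hp: LinearDiscriminantAnalysis(**hp),
    "ridge": lambda seed, hp: RidgeClassifier(random_state=seed, **hp),
    "k-nearest-neighbors": lambda seed, hp: KNeighborsClassifier(
        algorithm=hp.pop("algorithm", "auto"),
        leaf_size=hp.pop("leaf_size", 30),
        metric=hp.pop("metric", "minkowski"),
        n_neighbors=hp.pop("n_neighbors", 5),
        **hp,
    ),
    "extra-trees": lambda seed, hp: ExtraTreesClassifier(
        n_estimators=hp.pop("n_estimators", 100), random_state=seed, n_jobs=1, **hp
    ),
    "adaptive-boosting": lambda seed, hp: AdaBoostClassifier(
        random_state=seed, **hp
    ),
    "logistic-regression": lambda seed, hp: LogisticRegression(
        max_iter=hp.pop("max_iter", 1000), random_state=seed, **hp
    ),
    "histogram-gradient-boosting": _build_lightgbm,
    # SE and FE are strongly correlated; a small regulariser keeps the
    # per-class covariance invertible
    "quadratic-discriminant": lambda seed, hp: QuadraticDiscriminantAnalysis(
        reg_param=hp.pop("reg_param", 1e-3), **hp
    ),
    "gradient-boosting": lambda seed, hp: GradientBoostingClassifier(
        criterion=hp.pop("criterion", "friedman_mse"),
        n_estimators=hp.pop("n_estimators", 100),
        random_state=seed,
        **hp,
    ),
    "extreme-gradient-boosting": _build_xgboost,
    "decision-tree": lambda seed, hp: DecisionTreeClassifier(random_state=seed, **hp),
    "linear-support-vector": lambda seed, hp: LinearSVC(
        random_state=seed, **hp
    ),
    "majority-dummy": lambda seed, hp: DummyClassifier(
        strategy=hp.pop("strategy", "most_frequent"), **hp
    ),
}

#: The full 15-family roster in canonical order.
DEFAULT_ROSTER = tuple(ClassifierSpec(family) for family in _FAMILIES)


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts and the derived binary-classification metrics.

    auc_rank is None when the truth contains a single class (undefined), and
    auc_cm is None when either class is absent from the truth.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_cm: float | None
    auc_rank: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """P(score of random positive > score of random negative), ties half."""
    pos = y_true == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    true_labels, predicted_labels, scores=None
) -> MetricSet:
    """Tally the confusion matrix (positive = 1) and evaluate all metrics."""
    y = np.asarray(true_labels, dtype=np.int64)
    yhat = np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != yhat.shape:
        raise ValueError("true and predicted labels must have equal length")
    tp = int(((y == 1) & (yhat == 1)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())

    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    if fp + tn > 0 and fn + tp > 0:
        auc_cm = 1.0 - 0.5 * (fp / (fp + tn) + fn / (fn + tp))
    else:
        auc_cm = None
    auc_rank = _rank_auc(y, np.asarray(scores, dtype=np.float64)) if scores is not None else None
    return MetricSet(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        auc_cm=auc_cm, auc_rank=auc_rank,
    )


def _decision_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Continuous score for the positive class, whatever the estimator offers."""
    if hasattr(estimator, "predict_proba"):
        return np.asarray(estimator.predict_proba(X))[:, 1]
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X), dtype=np.float64)
    return np.asarray(estimator.predict(X), dtype=np.float64)


def _fit_eval(spec, X_tr, y_tr, X_ev, y_ev, seed) -> MetricSet:
    est = spec.make_estimator(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X_tr, y_tr)
        pred = est.predict(X_ev)
        scores = _decision_scores(est, X_ev)
    return compute_metrics(y_ev, pred, scores)


_METRIC_FIELDS = ("accuracy", "auc_rank", "auc_cm", "f1", "precision", "recall")


def cross_validate_classifier(
    design: DesignMatrix | None,
    spec: ClassifierSpec,
    k: int = 5,
    seed: int = DEFAULT_SEED,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> MetricSet:
    """Stratified k-fold evaluation; per-fold metrics averaged.

    Pass either a DesignMatrix or explicit (X, y) arrays.  Confusion counts
    in the returned MetricSet are pooled over folds (every sample is
    predicted exactly once); the ratio metrics are fold means, matching the
    usual CV reporting convention.
    """
    if design is not None:
        X, y = design.X, design.y
    if X is None or y is None:
        raise ValueError("provide a design matrix or X and y")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"need at least {k} samples per class for {k}-fold stratification"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        _fit_eval(spec, X[tr], y[tr], X[ev], y[ev], seed)
        for tr, ev in skf.split(X, y)
    ]
    means = {
        name: float(np.mean([getattr(f, name) for f in folds
                             if getattr(f, name) is not None]))
        if any(getattr(f, name) is not None for f in folds) else None
        for name in _METRIC_FIELDS
    }
    return MetricSet(
        tp=sum(f.tp for f in folds), fp=sum(f.fp for f in folds),
        tn=sum(f.tn for f in folds), fn=sum(f.fn for f in folds),
        **means,
    )


class EnsembleBenchmark:
    """Classifier comparison on one binary entropy-feature design.

    Parameters
    ----------
    design : DesignMatrix
        Two-feature binary design built by ``build_design_matrix``.
    roster : sequence of ClassifierSpec, optional
        Families to compare; defaults to the full 15-family roster.
    test_size : float
        Held-out fraction (default 0.30); the remaining 70% is the
        cross-validation pool and bootstrap training set.
    """

    def __init__(self, design: DesignMatrix, roster=None, test_size: float = 0.30):
        self.design = design
        self.roster = tuple(roster) if roster is not None else DEFAULT_ROSTER
        if not self.roster:
            raise ValueError("roster must be non-empty")
        self.test_size = test_size

    @classmethod
    def from_features(cls, features: pd.DataFrame, spec, **kwargs) -> "EnsembleBenchmark":
        from .models import build_design_matrix

        return cls(build_design_matrix(features, spec), **kwargs)

    def fit(self, seed: int = DEFAULT_SEED, folds: int = 5) -> "BenchmarkResults":
        """Split, cross-validate every roster member, rank by accuracy."""
        idx = np.arange(len(self.design))
        train_idx, test_idx = train_test_split(
            idx,
            test_size=self.test_size,
            random_state=seed,
            stratify=self.design.y,
        )
        X_tr, y_tr = self.design.X[train_idx], self.design.y[train_idx]
        rows = []
        for order, spec in enumerate(self.roster):
            ms = cross_validate_classifier(
                None, spec, k=folds, seed=seed, X=X_tr, y=y_tr
            )
            rows.append(
                {
                    "classifier": spec.family,
                    "accuracy": ms.accuracy,
                    "auc_rank": ms.auc_rank,
                    "auc_cm": ms.auc_cm,
                    "f1": ms.f1,
                    "precision": ms.precision,
                    "recall": ms.recall,
                    "_order": order,
                }
            )
        table = pd.DataFrame(rows)
        # rank: accuracy desc, ties broken by rank AUC then roster order
        table = table.sort_values(
            by=["accuracy", "auc_rank", "_order"],
            ascending=[False, False, True],
            na_position="last",
            kind="mergesort",
        ).reset_index(drop=True)
        selected = self.roster[int(table.loc[0, "_order"])]
        table = table.drop(columns="_order")
        return BenchmarkResults(
            benchmark=self,
            table=table,
            selected=selected,
            seed=seed,
            folds=folds,
            train_idx=np.asarray(train_idx),
            test_idx=np.asarray(test_idx),
        )


@dataclass
class BenchmarkResults:
    """Ranked metric table, the selected classifier and the frozen split."""

    benchmark: EnsembleBenchmark
    table: pd.DataFrame
    selected: ClassifierSpec
    seed: int
    folds: int
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def selected_accuracy(self) -> float:
        return float(self.table.loc[0, "accuracy"])

    def summary(self) -> str:
        spec = self.benchmark.design.spec
        lines = [
            "Ensemble benchmark "
            f"[model {spec.index}: NoDR vs {spec.dr_level}, level {spec.preprocessing}]",
            f"n = {len(self.benchmark.design)} "
            f"(train {len(self.train_idx)} / test {len(self.test_idx)}), "
            f"{self.folds}-fold CV, seed {self.seed}",
            "",
            self.table.to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "",
            f"selected: {self.selected.family} "
            f"(mean CV accuracy {self.selected_accuracy:.3f})",
        ]
        return "\n".join(lines)

    def test_accuracy(self) -> float:
        """Single fit of the selected family on train, scored on held-out test."""
        d = self.benchmark.design
        ms = _fit_eval(
            self.selected,
            d.X[self.train_idx], d.y[self.train_idx],
            d.X[self.test_idx], d.y[self.test_idx],
            self.seed,
        )
        return ms.accuracy

    def bootstrap(self, B: int = 100, seed: int | None = None):
        """Bootstrap validation of the selected classifier on the frozen split."""
        from .bootstrap import bootstrap_validate

        d = self.benchmark.design
        return bootstrap_validate(
            d.X[self.train_idx], d.y[self.train_idx],
            d.X[self.test_idx], d.y[self.test_idx],
            self.selected,
            B=B,
            seed=self.seed if seed is None else seed,
        )


def run_benchmark(
    design: DesignMatrix,
    roster=None,
    test_size: float = 0.30,
    seed: int = DEFAULT_SEED,
    folds: int = 5,
) -> BenchmarkResults:
    """Functional wrapper: EnsembleBenchmark(design, roster).fit(seed)."""
    return EnsembleBenchmark(design, roster=roster, test_size=test_size).fit(
        seed=seed, folds=folds
    )
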