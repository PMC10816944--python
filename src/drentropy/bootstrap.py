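"""Bootstrap validation of a selected classifier.

The selected (model, classifier) pair is validated by drawing B resamples
with replacement from the training set — each of the same size as the
training set, the classical bootstrap — retraining the classifier on each
resample, and scoring accuracy on the untouched held-out test set.  The B
accuracies and their mean summarise how stable the selection is under
sampling variability of the training data.

A resample that happens to contain a single class cannot train a binary
classifier; it is redrawn (with a bounded number of retries) so the result
always carries exactly B accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bench import ClassifierSpec, _decision_scores, compute_metrics

__all__ = ["BootstrapResult", "bootstrap_validate"]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BootstrapResult:
    """B held-out accuracies from resampled retraining, plus their mean."""

    B: int
    accuracies: tuple[float, ...]
    seed: int
    n_redraws: int = 0
    #: fraction of distinct training rows in each resample (diagnostic;
    #: expected about 1 - 1/e for the classical n-out-of-n bootstrap)
    unique_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.accuracies) != self.B:
            raise ValueError("must hold exactly B accuracies")
        if any(not 0.0 <= a <= 1.0 for a in self.accuracies):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "accuracies": list(self.accuracies),
            "mean_accuracy": self.mean_accuracy,
        }


def bootstrap_validate(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    spec: ClassifierSpec,
    B: int = 100,
    seed: int = 123,
) -> BootstrapResult:
    """Retrain on B bootstrap resamples of the training set; score on test.

    Each resample draws n_train rows with replacement.  Deterministic given
    ``seed``; the test set is fixed across iterations.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    test_X = np.asarray(test_X, dtype=np.float64)
    test_y = np.asarray(test_y, dtype=np.int64)
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train and test must share feature columns")
    n = len(train_y)
    rng = np.random.default_rng(seed)
    accuracies: list[float] = []
    unique_fractions: list[float] = []
    n_redraws = 0
    for _ in range(B):
        for attempt in range(_MAX_REDRAWS + 1):
            rows = rng.integers(0, n, size=n)
            if len(np.unique(train_y[rows])) > 1:
                break
            n_redraws += 1
        else:
            raise RuntimeError(
                "could not draw a two-class bootstrap resample; "
                "training set is too unbalanced"
            )
        unique_fractions.append(len(np.unique(rows)) / n)
        est = spec.make_estimator(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(train_X[rows], train_y[rows])
            pred = est.predict(test_X)
        accuracies.append(compute_metrics(test_y, pred).accuracy)
    if n_redraws:
        warnings.warn(
            f"redrew {n_redraws} single-class bootstrap resample(s)",
            stacklevel=2,
        )
    return BootstrapResult(
        B=B,
        accuracies=tuple(accuracies),
        seed=seed,
        n_redraws=n_redraws,
        unique_fractions=tuple(unique_fractions),
    )
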