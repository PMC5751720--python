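"""Cross-validation, accuracy/confidence reporting and method comparison.

The evaluation protocol is k-fold (default ten-fold) cross-validation:
every fitted transform — unit scaler, z-scorer, reducer, auto-encoder
pretraining, fine-tuning — is refit on the training folds of each split, and
accuracy is measured on the held-out fold.  The dispersion statistic across
folds ("interval of confidence") defaults to the standard error of the mean
(sample sd / sqrt(k)); a Student-t 95% half-width mode is available.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .signal_io import SampleSet

__all__ = ["CVResult", "kfold_split", "interval_of_confidence",
           "cross_validate", "comparison_report"]


@dataclass
class CVResult:
    """Per-fold accuracies with their mean and dispersion for one method."""

    method: str
    fold_accuracies: list[float]
    interval_mode: str = "sem"
    epoch_budget: int | None = None
    confusion: np.ndarray | None = None   # n_classes x n_classes, summed over folds
    wall_time_s: float | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def interval_half_width(self) -> float:
        return interval_of_confidence(self.fold_accuracies, self.interval_mode)


def kfold_split(n: int, k: int, seed: int = 0,
                labels=None) -> list[np.ndarray]:
    """k disjoint index groups of near-equal size (seeded shuffle).

    With ``labels`` given (the default protocol), folds are stratified so
    per-class counts differ by at most one across folds.  ``k = n`` gives
    leave-one-out.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        groups = [test for _, test in splitter.split(np.zeros(n), np.asarray(labels))]
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        groups = [test for _, test in splitter.split(np.zeros(n))]
    return groups


def interval_of_confidence(fold_accuracies, mode: str = "sem") -> float:
    """Dispersion of fold accuracies: SEM (default) or t-based 95% half-width."""
    a = np.asarray(fold_accuracies, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 folds")
    sem = float(a.std(ddof=1) / np.sqrt(a.size))
    if mode == "sem":
        return sem
    if mode == "t95":
        return float(stats.t.ppf(0.975, a.size - 1) * sem)
    raise ValueError("mode must be 'sem' or 't95'")


def cross_validate(pipeline, sample_set: SampleSet, k: int = 10,
                   seed: int = 0, stratified: bool = True,
                   interval_mode: str = "sem",
                   shuffle_labels: bool = False) -> CVResult:
    """k-fold cross-validation of one pipeline over a SampleSet.

    The pipeline is refit from scratch on the training folds of every split
    (the leakage-free protocol).  ``shuffle_labels=True`` permutes the labels
    once before splitting — the resulting accuracy should sit at chance and
    serves as a leakage detector.
    """
    y = sample_set.label_indices()
    if shuffle_labels:
        rng = np.random.default_rng(seed + 7919)
        y = rng.permutation(y)
        sample_set = _relabel(sample_set, y)
    n = len(sample_set)
    if stratified and np.min(np.bincount(y)) < k:
        raise ValueError("stratified CV needs >= k members per class")
    folds = kfold_split(n, k, seed, labels=y if stratified else None)
    n_classes = len(sample_set.class_names)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    accs = []
    t0 = time.perf_counter()
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        try:
            pipeline.fit(sample_set, train_idx)
            pred = np.asarray(pipeline.predict(sample_set, test_idx))
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"pipeline failed in fold {f}: {exc}") from exc
        truth = y[test_idx]
        accs.append(float(np.mean(pred == truth)))
        np.add.at(confusion, (truth, pred), 1)
    return CVResult(method=getattr(pipeline, "name", type(pipeline).__name__),
                    fold_accuracies=accs, interval_mode=interval_mode,
                    confusion=confusion,
                    wall_time_s=time.perf_counter() - t0)


def _relabel(sample_set: SampleSet, y_idx: np.ndarray) -> SampleSet:
    from dataclasses import replace
    samples = [replace(s, label=sample_set.class_names[y_idx[i]])
               for i, s in enumerate(sample_set.samples)]
    return SampleSet(samples, list(sample_set.class_names),
                     list(sample_set.panel))


def comparison_report(results: list[CVResult]) -> pd.DataFrame:
    """Method-comparison table: one row per (method, epoch budget).

    Columns: accuracy, interval of confidence, wall time (informational).
    Rows are sorted by accuracy, descending.  Write with ``.to_csv`` or print
    with ``.to_string``.
    """
    if not results:
        raise ValueError("no results to report")
    rows = [{
        "method": r.method,
        "epochs": r.epoch_budget,
        "accuracy": r.mean_accuracy,
        "interval_of_confidence": r.interval_half_width,
        "wall_time_s": r.wall_time_s,
    } for r in results]
    df = pd.DataFrame(rows).sort_values("accuracy", ascending=False,
                                        kind="stable")
    return df.reset_index(drop=True)
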