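"""Evaluation suite: classification metrics, reliability recovery, the
Friedman rank test, and the cumulative annotator-sweep protocol."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import f1_score

from .data import CrowdDataset

__all__ = [
    "MetricsReport",
    "classification_report",
    "reliability_recovery_f1",
    "friedman_test",
    "annotator_sweep",
    "SweepResult",
]


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy and F1 scores, all as percentages in [0, 100]."""

    accuracy: float
    per_class_f1: tuple[float, ...]
    macro_f1: float
    n_evaluated: int


def classification_report(
    y_true: np.ndarray, y_pred: np.ndarray, class_count: int
) -> MetricsReport:
    """Accuracy, per-class F1 and macro F1 over all K classes.

    Classes with zero true and zero predicted support contribute F1 = 0 to
    the macro average (conservative, never excluded).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if ((arr < 0) | (arr >= class_count)).any():
            raise ValueError(f"{name} contains labels outside [0, {class_count})")
    per_class = f1_score(
        y_true, y_pred, labels=range(class_count), average=None, zero_division=0.0
    )
    return MetricsReport(
        accuracy=100.0 * float((y_true == y_pred).mean()),
        per_class_f1=tuple(100.0 * per_class),
        macro_f1=100.0 * float(per_class.mean()),
        n_evaluated=len(y_true),
    )


def reliability_recovery_f1(
    estimated: list[dict[str, float]],
    truth: list[dict[str, int]],
    threshold: float = 0.5,
) -> tuple[dict[str, float], float]:
    """Score how well estimated reliabilities recover true correctness.

    ``estimated`` holds per-instance ``{annotator_id: score}`` dicts (scores
    in [0, 1]); ``truth`` the matching binary indicators (1 = the annotator
    labelled that instance correctly). Estimates are binarised at
    ``threshold`` (``>=`` means reliable) and scored per annotator with F1,
    treating "reliable" as the positive class. Returns per-annotator F1 (%)
    and their unweighted mean.
    """
    if len(estimated) != len(truth):
        raise ValueError("estimated and truth must cover the same instances")
    per_ann: dict[str, list[tuple[int, int]]] = {}
    for est_n, tru_n in zip(estimated, truth):
        if set(est_n) != set(tru_n):
            raise ValueError(
                "estimated and truth disagree on the annotator set of an instance"
            )
        for aid, score in est_n.items():
            per_ann.setdefault(aid, []).append(
                (1 if score >= threshold else 0, int(tru_n[aid]))
            )
    f1s: dict[str, float] = {}
    for aid, pairs in sorted(per_ann.items()):
        pred, tru = (np.array(v) for v in zip(*pairs))
        f1s[aid] = 100.0 * float(f1_score(tru, pred, zero_division=0.0))
    return f1s, float(np.mean(list(f1s.values())))


def friedman_test(scores: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test across methods evaluated on matched blocks.

    ``scores`` is ``(k methods, N conditions)``; higher is better. Within
    each condition, methods are ranked (rank 1 = best, ties get average
    ranks) and the classical statistic

        chi2 = 12 / (N k (k+1)) * sum_j R_j^2  -  3 N (k+1)

    is referred to a chi-square distribution with k-1 degrees of freedom.
    No tie-correction factor is applied.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 3:
        raise ValueError("need a (methods x conditions) matrix with >= 3 methods")
    k, N = S.shape
    if N < 2:
        raise ValueError("need at least 2 conditions")
    # rank within each condition, best (largest) score gets rank 1
    ranks = np.apply_along_axis(stats.rankdata, 0, -S)
    R = ranks.sum(axis=1)
    chi2 = 12.0 / (N * k * (k + 1)) * float((R**2).sum()) - 3.0 * N * (k + 1)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return float(chi2), p


@dataclass
class SweepResult:
    """Cumulative annotator-sweep outcome: macro F1 per method and subset size."""

    subset_sizes: list[int]
    annotator_order: list[str]
    scores: dict[str, list[float]] = field(default_factory=dict)
    n_train_used: list[int] = field(default_factory=list)


def sweep_subset_sizes(n_annotators: int, step: int = 4) -> list[int]:
    """Cumulative subset sizes 1, 1+step, 1+2*step, ... capped at W; the full
    annotator pool is always the final size."""
    if step < 1:
        raise ValueError("step must be >= 1")
    sizes = list(range(1, n_annotators + 1, step))
    if sizes[-1] != n_annotators:
        sizes.append(n_annotators)
    return sizes


def restrict_annotators(
    dataset: CrowdDataset, keep: Sequence[str]
) -> tuple[CrowdDataset, np.ndarray]:
    """Drop all annotations by annotators outside ``keep``; instances left
    without any annotation are removed. Returns the reduced dataset and the
    boolean mask of retained instances."""
    keep_set = set(keep)
    kept_rows = []
    mask = np.zeros(dataset.n_instances, dtype=bool)
    annotations = []
    for n, ann in enumerate(dataset.annotations):
        sub = {a: l for a, l in ann.items() if a in keep_set}
        if sub:
            mask[n] = True
            kept_rows.append(n)
            annotations.append(sub)
    reduced = CrowdDataset(
        instance_ids=[dataset.instance_ids[n] for n in kept_rows],
        features=dataset.features[kept_rows],
        annotations=annotations,
        class_count=dataset.class_count,
        annotator_ids=[a for a in dataset.annotator_ids if a in keep_set],
        gold_labels=None
        if dataset.gold_labels is None
        else dataset.gold_labels[kept_rows],
    )
    return reduced, mask


def annotator_sweep(
    dataset: CrowdDataset,
    methods: dict[str, Callable[[CrowdDataset], float]],
    step: int = 4,
) -> SweepResult:
    """Evaluate methods on cumulative annotator subsets.

    Annotators are sorted by descending number of labelled instances (ties
    broken by annotator id) and added ``step`` at a time after the initial
    singleton: sizes 1, 1+step, 1+2*step, ... with the full pool always
    included last. Each method is a callable mapping the reduced training
    dataset to a score (e.g. test macro F1); instances that lose all their
    annotations under a subset are dropped for that run.
    """
    if not methods:
        raise ValueError("at least one method is required")
    counts = dataset.annotator_label_counts()
    order = sorted(counts, key=lambda a: (-counts[a], a))
    sizes = sweep_subset_sizes(len(order), step)
    result = SweepResult(subset_sizes=sizes, annotator_order=order)
    result.scores = {name: [] for name in methods}
    for size in sizes:
        reduced, _ = restrict_annotators(dataset, order[:size])
        result.n_train_used.append(reduced.n_instances)
        for name, fn in methods.items():
            result.scores[name].append(float(fn(reduced)))
    return result
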