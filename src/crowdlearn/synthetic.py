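"""Synthetic multi-annotator benchmark: a 1-D three-class task with five
simulated annotators whose reliabilities depend on the input.

The task draws scalar inputs uniformly on [0, 1] and assigns the true class
as the argmax of three sinusoids::

    f0(x) = sin(2*pi*x)
    f1(x) = -sin(2*pi*x)
    f2(x) = 0.5 - sin(2*pi*(x + 0.25))

which partitions [0, 1] into interleaved class regions with nonlinear
boundaries. Annotators are simulated with deterministic *reliable sets*:
finite unions of half-open subintervals of [0, 1]. Inside its reliable set an
annotator reports the true label; outside, it errs according to its error
rule (by default drawing uniformly among the K-1 wrong classes, so an
annotator with a small reliable set is genuinely adversarial -- below-chance
accuracy). The measure of each reliable set therefore equals the annotator's
expected accuracy.

The five default profiles are calibrated so their expected accuracies are
84.66%, 59.66%, 66.33%, 55.66% and 27.66%, spanning four archetypes: sharp
transitions (annotators 1 and 3), non-monotonic alternation (2 and 4) and a
sparse reliability signal (5).

Because labels are generated from known reliable sets, the simulator also
emits per-(instance, annotator) binary correctness indicators, the ground
truth for reliability-recovery evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CrowdDataset, assemble_dataset

__all__ = [
    "SyntheticTaskSpec",
    "AnnotatorProfile",
    "SyntheticCrowdData",
    "true_label",
    "generate_task",
    "reliability_value",
    "default_profiles",
    "simulate_annotations",
    "make_synthetic_crowd",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Size specification for the synthetic task (inputs live on [0, 1])."""

    n_train: int = 300
    n_test: int = 200
    class_count: int = 3

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_test <= 0:
            raise SyntheticError("sample counts must be positive")
        if self.class_count != 3:
            raise SyntheticError("the sinusoidal task defines exactly 3 classes")


def _class_scores(x: np.ndarray) -> np.ndarray:
    """Stack the three class-score sinusoids; shape (n, 3)."""
    x = np.asarray(x, dtype=float)
    return np.stack(
        [
            np.sin(2 * np.pi * x),
            -np.sin(2 * np.pi * x),
            0.5 - np.sin(2 * np.pi * (x + 0.25)),
        ],
        axis=-1,
    )


def true_label(x):
    """True class of input(s) ``x`` in [0, 1]: argmax of the three sinusoids.

    Ties break toward the lowest class index (numpy argmax convention).
    """
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise SyntheticError("input outside the task domain [0, 1]")
    labels = _class_scores(arr).argmax(axis=-1)
    return int(labels) if np.isscalar(x) or arr.ndim == 0 else labels


def generate_task(
    spec: SyntheticTaskSpec = SyntheticTaskSpec(), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw the train/test inputs and their true labels.

    Returns ``(x_train, y_train, x_test, y_test)`` with inputs uniform on
    [0, 1]. Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=spec.n_train + spec.n_test)
    y = true_label(x)
    return (
        x[: spec.n_train],
        y[: spec.n_train],
        x[spec.n_train :],
        y[spec.n_train :],
    )


@dataclass(frozen=True)
class AnnotatorProfile:
    """An input-dependent annotator reliability function.

    ``intervals`` is a finite union of disjoint half-open subintervals
    [a, b) of [0, 1] on which the annotator is reliable (always reports the
    true label). Elsewhere it errs: ``uniform-wrong`` draws uniformly among
    the K-1 incorrect classes; ``uniform-any`` draws uniformly among all K
    classes (so it may be accidentally correct). ``target_accuracy`` is the
    intended expected accuracy in percent; the reliable-set measure must
    match it to within 0.005.
    """

    name: str
    intervals: tuple[tuple[float, float], ...]
    target_accuracy: float
    error_rule: str = "uniform-wrong"

    def __post_init__(self) -> None:
        if self.error_rule not in ("uniform-wrong", "uniform-any"):
            raise SyntheticError(f"unknown error rule {self.error_rule!r}")
        ivs = sorted(self.intervals)
        for (a, b) in ivs:
            if not (0.0 <= a < b <= 1.0):
                raise SyntheticError(f"bad interval [{a}, {b})")
        for (_, b), (a2, _) in zip(ivs, ivs[1:]):
            if a2 < b:
                raise SyntheticError("reliable intervals overlap")
        if abs(self.measure - self.target_accuracy / 100.0) > 0.005:
            raise SyntheticError(
                f"{self.name}: reliable-set measure {self.measure:.4f} is not "
                f"calibrated to target accuracy {self.target_accuracy}%"
            )

    @property
    def measure(self) -> float:
        """Total length of the reliable set."""
        return float(sum(b - a for a, b in self.intervals))


def reliability_value(profile: AnnotatorProfile, x):
    """1 if ``x`` lies in the profile's reliable set (half-open), else 0."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise SyntheticError("input outside the task domain [0, 1]")
    out = np.zeros(arr.shape, dtype=int)
    for a, b in profile.intervals:
        out |= (arr >= a) & (arr < b)
    return int(out) if np.isscalar(x) or arr.ndim == 0 else out


# Mean accuracies of the five simulated annotators, in percent.
DEFAULT_ACCURACIES = (84.66, 59.66, 66.33, 55.66, 27.66)


def default_profiles() -> list[AnnotatorProfile]:
    """The five calibrated annotator profiles of the synthetic benchmark.

    Interval measures equal the target accuracies exactly. Annotators a1 and
    a3 are plateaus with sharp transitions, a2 and a4 alternate reliable and
    unreliable bands (non-monotonic), and a5 is reliable only on one short
    central interval. All err uniformly among wrong classes, so expected
    accuracy equals the reliable-set measure.
    """
    w2 = 0.5966 / 3  # bump width, annotator 2
    w4 = 0.5566 / 4  # bump width, annotator 4
    return [
        AnnotatorProfile("a1", ((0.0, 0.42), (0.5734, 1.0)), 84.66),
        AnnotatorProfile(
            "a2",
            tuple((s, s + w2) for s in (0.0, 0.35, 0.70)),
            59.66,
        ),
        AnnotatorProfile("a3", ((0.17, 0.8333),), 66.33),
        AnnotatorProfile(
            "a4",
            tuple((s, s + w4) for s in (0.05, 0.28, 0.51, 0.74)),
            55.66,
        ),
        AnnotatorProfile("a5", ((0.3617, 0.6383),), 27.66),
    ]


def simulate_annotations(
    profiles: list[AnnotatorProfile],
    x: np.ndarray,
    y: np.ndarray,
    class_count: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate every annotator labelling every instance.

    Returns ``(labels, reliable)``, both shaped ``(n, W)``: the emitted class
    labels and the binary correctness indicators (1 iff the emitted label
    equals the true label). Where an annotator is reliable it emits the true
    label; elsewhere it draws according to its error rule. Deterministic
    given ``seed``.
    """
    if not profiles:
        raise SyntheticError("at least one annotator profile is required")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    n, W = x.shape[0], len(profiles)
    labels = np.empty((n, W), dtype=int)
    for w, prof in enumerate(profiles):
        reliable = reliability_value(prof, x).astype(bool)
        col = np.where(reliable, y, -1)
        m = (~reliable).sum()
        if prof.error_rule == "uniform-wrong":
            # uniform over the K-1 wrong classes: shift draws past the truth
            draws = rng.integers(0, class_count - 1, size=m)
            wrong = np.where(draws >= y[~reliable], draws + 1, draws)
            col[~reliable] = wrong
        else:  # uniform-any
            col[~reliable] = rng.integers(0, class_count, size=m)
        labels[:, w] = col
    reliable_ind = (labels == y[:, None]).astype(int)
    return labels, reliable_ind


@dataclass
class SyntheticCrowdData:
    """A simulated crowd benchmark: train/test datasets plus ground-truth
    reliability indicators for the training and test annotations."""

    train: CrowdDataset
    test: CrowdDataset
    profiles: list[AnnotatorProfile] = field(default_factory=list)
    # (n, W) correctness indicators, aligned with each dataset's annotations
    train_reliability: np.ndarray | None = None
    test_reliability: np.ndarray | None = None

    def annotator_accuracies(self, split: str = "train") -> np.ndarray:
        """Realised per-annotator accuracy (%) on the given split."""
        rel = self.train_reliability if split == "train" else self.test_reliability
        return 100.0 * rel.mean(axis=0)


def _to_dataset(
    x: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    profiles: list[AnnotatorProfile],
    prefix: str,
    class_count: int,
) -> CrowdDataset:
    ids = [f"{prefix}{j}" for j in range(x.shape[0])]
    rows = [
        (ids[nn], profiles[w].name, int(labels[nn, w]))
        for nn in range(x.shape[0])
        for w in range(len(profiles))
    ]
    table = pd.DataFrame(rows, columns=["instance_id", "annotator_id", "label"])
    return assemble_dataset(
        x[:, None],
        table,
        class_count,
        instance_ids=ids,
        gold=dict(zip(ids, y.tolist())),
        annotator_ids=[p.name for p in profiles],
    )


def make_synthetic_crowd(
    spec: SyntheticTaskSpec = SyntheticTaskSpec(),
    profiles: list[AnnotatorProfile] | None = None,
    seed: int = 0,
) -> SyntheticCrowdData:
    """Generate the full benchmark: task, annotations and reliability truth.

    Uses independent seeded streams for the task draw and the train/test
    annotation noise, all derived from ``seed``.
    """
    if profiles is None:
        profiles = default_profiles()
    K = spec.class_count
    x_tr, y_tr, x_te, y_te = generate_task(spec, seed=seed)
    lab_tr, rel_tr = simulate_annotations(profiles, x_tr, y_tr, K, seed=seed + 1)
    lab_te, rel_te = simulate_annotations(profiles, x_te, y_te, K, seed=seed + 2)
    return SyntheticCrowdData(
        train=_to_dataset(x_tr, y_tr, lab_tr, profiles, "tr", K),
        test=_to_dataset(x_te, y_te, lab_te, profiles, "te", K),
        profiles=list(profiles),
        train_reliability=rel_tr,
        test_reliability=rel_te,
    )


def write_reliability(
    dataset: CrowdDataset, reliability: np.ndarray, path: str | Path
) -> None:
    """Write the ``instance_id,annotator_id,reliable`` ground-truth table."""
    rows = [
        (iid, aid, int(reliability[nn, w]))
        for nn, iid in enumerate(dataset.instance_ids)
        for w, aid in enumerate(dataset.annotator_ids)
    ]
    pd.DataFrame(rows, columns=["instance_id", "annotator_id", "reliable"]).to_csv(
        path, index=False
    )


def read_reliability(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"instance_id": str, "annotator_id": str})
    df["reliable"] = df["reliable"].astype(int)
    return df
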