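"""Domain types and CSV interchange for crowdsourced classification datasets.

A crowdsourced dataset couples an ``N x D`` feature matrix with a *long-format*
annotation table: one row per (instance, annotator) pair, holding the class
label that annotator assigned. Missing annotations are simply absent rows, so
each instance ``n`` carries an observed annotator subset ``W_n``; every
instance must have at least one annotation. Gold-standard labels, when known,
are kept separate and are never consumed by crowd training -- they exist only
for evaluation and for the gold-trained upper-bound baseline.

On-disk formats (UTF-8, comma-separated, mandatory header):

* features:     ``instance_id,f1,...,fD``
* annotations:  ``instance_id,annotator_id,label``
* gold:         ``instance_id,label``
* predictions:  ``instance_id,p_0,...,p_{K-1},pred_label``

Instance order is defined by the features file; annotation tables may come in
any order. Labels are 0-based class indices in ``{0, ..., K-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("instance_id", "annotator_id", "label")


class CrowdDataError(ValueError):
    """Raised for malformed or inconsistent crowdsourced data."""


def one_hot(label: int, class_count: int) -> np.ndarray:
    """Encode a class index as a length-``class_count`` one-hot vector."""
    if not 0 <= label < class_count:
        raise CrowdDataError(
            f"label {label} outside valid range [0, {class_count})"
        )
    vec = np.zeros(class_count, dtype=float)
    vec[label] = 1.0
    return vec


def read_annotations(path: str | Path, class_count: int) -> pd.DataFrame:
    """Read a long-format annotation table, validating labels against K.

    Returns a DataFrame with columns ``instance_id`` (str), ``annotator_id``
    (str) and ``label`` (int), preserving file order. Duplicate
    (instance, annotator) pairs and out-of-range labels are rejected.
    """
    df = pd.read_csv(path, dtype={"instance_id": str, "annotator_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise CrowdDataError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {','.join(ANNOTATION_COLUMNS)}"
        )
    df = df[list(ANNOTATION_COLUMNS)].copy()
    df["label"] = pd.to_numeric(df["label"], errors="raise").astype(int)
    bad = df[(df["label"] < 0) | (df["label"] >= class_count)]
    if len(bad):
        row = bad.iloc[0]
        raise CrowdDataError(
            f"label {row['label']} for ({row['instance_id']}, "
            f"{row['annotator_id']}) outside [0, {class_count})"
        )
    dup = df.duplicated(subset=["instance_id", "annotator_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise CrowdDataError(
            f"duplicate annotation for pair "
            f"({row['instance_id']}, {row['annotator_id']})"
        )
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[list(ANNOTATION_COLUMNS)].to_csv(path, index=False)


def read_features(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a features CSV; returns (instance ids in file order, N x D matrix)."""
    df = pd.read_csv(path, dtype={"instance_id": str})
    if "instance_id" not in df.columns:
        raise CrowdDataError(f"{path}: missing 'instance_id' column")
    ids = df["instance_id"].tolist()
    X = df.drop(columns="instance_id").to_numpy(dtype=float)
    return ids, X


def write_features(ids: Sequence[str], X: np.ndarray, path: str | Path) -> None:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = {"instance_id": list(ids)}
    for j in range(X.shape[1]):
        cols[f"f{j + 1}"] = X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_gold(path: str | Path, class_count: int) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"instance_id": str})
    for col in ("instance_id", "label"):
        if col not in df.columns:
            raise CrowdDataError(f"{path}: missing '{col}' column")
    df["label"] = df["label"].astype(int)
    if ((df["label"] < 0) | (df["label"] >= class_count)).any():
        raise CrowdDataError(f"{path}: gold label outside [0, {class_count})")
    return df[["instance_id", "label"]]


def write_gold(ids: Sequence[str], labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"instance_id": list(ids), "label": np.asarray(labels, int)}).to_csv(
        path, index=False
    )


def write_predictions(
    ids: Sequence[str], probabilities: np.ndarray, path: str | Path
) -> None:
    """Write per-instance class probabilities and argmax labels."""
    P = np.asarray(probabilities, dtype=float)
    cols = {"instance_id": list(ids)}
    for k in range(P.shape[1]):
        cols[f"p_{k}"] = P[:, k]
    cols["pred_label"] = P.argmax(axis=1)
    pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class CrowdDataset:
    """A validated multi-annotator classification dataset.

    Attributes
    ----------
    instance_ids : ordered instance identifiers (order defines row order).
    features : ``N x D`` real matrix aligned with ``instance_ids``.
    annotations : per-instance mapping ``annotator_id -> class index``
        (the observed annotator sets ``W_n``).
    class_count : number of classes ``K >= 2``.
    annotator_ids : ordered distinct annotator identifiers (size ``W``).
    gold_labels : optional length-``N`` true labels, evaluation only.
    """

    instance_ids: list[str]
    features: np.ndarray
    annotations: list[dict[str, int]]
    class_count: int
    annotator_ids: list[str] = field(default_factory=list)
    gold_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[0] != len(self.instance_ids):
            raise CrowdDataError(
                f"{len(self.instance_ids)} instance ids but "
                f"{self.features.shape[0]} feature rows"
            )
        if not np.isfinite(self.features).all():
            raise CrowdDataError("non-finite feature value")
        if self.class_count < 2:
            raise CrowdDataError("class_count must be >= 2")
        if len(self.annotations) != len(self.instance_ids):
            raise CrowdDataError("annotations length differs from instance count")
        seen: set[str] = set()
        for iid, ann in zip(self.instance_ids, self.annotations):
            if not ann:
                raise CrowdDataError(
                    f"instance {iid!r} has no annotations (|W_n| >= 1 required)"
                )
            for a, lab in ann.items():
                if not 0 <= lab < self.class_count:
                    raise CrowdDataError(
                        f"label {lab} by annotator {a!r} on instance {iid!r} "
                        f"outside [0, {self.class_count})"
                    )
                seen.add(a)
        if not self.annotator_ids:
            self.annotator_ids = sorted(seen)
        elif not seen.issubset(self.annotator_ids):
            raise CrowdDataError(
                f"annotator ids {sorted(seen - set(self.annotator_ids))} "
                "absent from declared annotator list"
            )
        if self.gold_labels is not None:
            self.gold_labels = np.asarray(self.gold_labels, dtype=int)
            if self.gold_labels.shape != (len(self.instance_ids),):
                raise CrowdDataError(
                    f"gold labels shape {self.gold_labels.shape} does not match "
                    f"instance count {len(self.instance_ids)}"
                )
            if ((self.gold_labels < 0) | (self.gold_labels >= self.class_count)).any():
                raise CrowdDataError("gold label outside class range")

    @property
    def n_instances(self) -> int:
        return len(self.instance_ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_annotators(self) -> int:
        return len(self.annotator_ids)

    def annotation_table(self) -> pd.DataFrame:
        """Long-format view of the annotations, in instance order."""
        rows = [
            (iid, a, lab)
            for iid, ann in zip(self.instance_ids, self.annotations)
            for a, lab in ann.items()
        ]
        return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))

    def annotator_label_counts(self) -> dict[str, int]:
        counts = {a: 0 for a in self.annotator_ids}
        for ann in self.annotations:
            for a in ann:
                counts[a] += 1
        return counts


def assemble_dataset(
    features: np.ndarray,
    annotations: pd.DataFrame,
    class_count: int,
    instance_ids: Sequence[str] | None = None,
    gold: Mapping[str, int] | pd.DataFrame | None = None,
    annotator_ids: Sequence[str] | None = None,
) -> CrowdDataset:
    """Join features, an annotation table and optional gold labels.

    ``instance_ids`` defaults to ``i0..i{N-1}``; every annotation row must
    reference a known instance, and every instance must receive at least one
    annotation. ``W`` is inferred from the distinct annotator ids unless an
    explicit list is given.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = features.shape[0]
    if instance_ids is None:
        instance_ids = [f"i{j}" for j in range(n)]
    instance_ids = [str(i) for i in instance_ids]
    index = {iid: j for j, iid in enumerate(instance_ids)}
    if len(index) != n:
        raise CrowdDataError("duplicate instance ids")

    per_instance: list[dict[str, int]] = [{} for _ in range(n)]
    for iid, aid, lab in annotations[list(ANNOTATION_COLUMNS)].itertuples(index=False):
        iid = str(iid)
        if iid not in index:
            raise CrowdDataError(f"annotation references unknown instance {iid!r}")
        per_instance[index[iid]][str(aid)] = int(lab)

    gold_arr = None
    if gold is not None:
        if isinstance(gold, pd.DataFrame):
            gold = dict(zip(gold["instance_id"].astype(str), gold["label"]))
        if set(gold) != set(instance_ids):
            raise CrowdDataError(
                "gold labels must cover exactly the feature instances"
            )
        gold_arr = np.array([int(gold[iid]) for iid in instance_ids])

    return CrowdDataset(
        instance_ids=list(instance_ids),
        features=features,
        annotations=per_instance,
        class_count=class_count,
        annotator_ids=list(annotator_ids) if annotator_ids else [],
        gold_labels=gold_arr,
    )


def load_dataset(
    features_path: str | Path,
    annotations_path: str | Path,
    class_count: int,
    gold_path: str | Path | None = None,
) -> CrowdDataset:
    """Load a CrowdDataset from the CSV triplet."""
    ids, X = read_features(features_path)
    ann = read_annotations(annotations_path, class_count)
    gold = read_gold(gold_path, class_count) if gold_path else None
    return assemble_dataset(X, ann, class_count, instance_ids=ids, gold=gold)


def save_dataset(dataset: CrowdDataset, prefix: str | Path) -> dict[str, Path]:
    """Write the CSV triplet ``<prefix>_{features,annotations,gold}.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"features": Path(f"{prefix}_features.csv")}
    write_features(dataset.instance_ids, dataset.features, paths["features"])
    paths["annotations"] = Path(f"{prefix}_annotations.csv")
    write_annotations(dataset.annotation_table(), paths["annotations"])
    if dataset.gold_labels is not None:
        paths["gold"] = Path(f"{prefix}_gold.csv")
        write_gold(dataset.instance_ids, dataset.gold_labels, paths["gold"])
    return paths
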