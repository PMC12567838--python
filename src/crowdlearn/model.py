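"""Joint training of the classifier and the attention-based crowd consensus.

Each epoch alternates implicitly between two coupled roles of the same
forward pass: the predicted class distributions act as attention queries
that score every annotator's label (the predicted probability of the class
that annotator chose), those scores aggregate the one-hot annotations into
reliability-weighted pseudo-labels, and the network takes a gradient step on
the cross-entropy between its predictions and the pseudo-labels. No gold
labels are consumed anywhere in the loop.

Because early predictions from a symmetric random initialisation are near
uniform, the first pseudo-labels are close to soft majority votes; as the
classifier sharpens, annotators that agree with it in a region of input
space gain weight there, so the consensus progressively discounts unreliable
annotators instance by instance.

By default the pseudo-label is treated as a constant target within each step
(the standard pseudo-labelling convention: no gradient flows through the
query inside the crowd network). Setting ``detach_pseudo_label=False``
differentiates the full composite objective instead, including the
pseudo-label's dependence on the predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attention import DEFAULT_EPSILON, LOG_CLAMP, pseudo_labels_from_counts
from .data import CrowdDataset
from .nnet import MLP, AdamState, NetworkConfig

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "train_attention_classifier",
    "train_on_targets",
    "estimate_reliabilities",
    "annotation_counts",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: Adam, full-batch by default."""

    learning_rate: float = 0.005
    epochs: int = 500
    batch_size: int | None = None  # None = full batch
    seed: int = 0
    detach_pseudo_label: bool = True
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be positive")


@dataclass
class TrainedModel:
    """A trained classifier plus its per-epoch loss history."""

    network: MLP
    history: list[float] = field(default_factory=list)

    @property
    def config(self) -> NetworkConfig:
        return self.network.config

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities; rows on the K-simplex. Uses features only."""
        return self.network.forward(X)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, argmax labels); ties break to the lowest index."""
        probs = self.predict_proba(X)
        return probs, probs.argmax(axis=1)

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: config JSON + parameter arrays."""
        cfg = {
            "input_dim": self.config.input_dim,
            "class_count": self.config.class_count,
            "hidden_sizes": list(self.config.hidden_sizes),
        }
        np.savez(
            path,
            __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            __history__=np.asarray(self.history, dtype=float),
            **self.network.get_params(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            net = MLP(
                NetworkConfig(
                    cfg["input_dim"], cfg["class_count"], tuple(cfg["hidden_sizes"])
                ),
                np.random.default_rng(0),
            )
            net.set_params({k: data[k] for k in data.files if not k.startswith("__")})
            history = data["__history__"].tolist()
        return cls(network=net, history=history)


def annotation_counts(dataset: CrowdDataset) -> np.ndarray:
    """``(N, K)`` matrix of per-class annotation counts per instance."""
    counts = np.zeros((dataset.n_instances, dataset.class_count))
    for n, ann in enumerate(dataset.annotations):
        for lab in ann.values():
            counts[n, lab] += 1
    return counts


def _batches(n: int, batch_size: int | None, rng: np.random.Generator):
    if batch_size is None or batch_size >= n:
        yield np.arange(n)
        return
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _pseudo_label_grad(
    probs: np.ndarray, counts: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Per-instance dL/d(probs) for the non-detached composite objective.

    With c the annotation counts, S = sum_j c_j q_j and y~_k = c_k q_k / S,
    the target's dependence on the query q contributes
    -(c_m / S) * (log q_m - sum_k y~_k log q_k) on top of the usual
    cross-entropy term -y~_m / q_m.
    """
    q = np.clip(probs, LOG_CLAMP, None)
    logq = np.log(q)
    S = (counts * probs).sum(axis=1, keepdims=True)
    S = np.clip(S, LOG_CLAMP, None)
    ce_term = -targets / q
    inner = logq - (targets * logq).sum(axis=1, keepdims=True)
    return ce_term - (counts / S) * inner


def train_attention_classifier(
    dataset: CrowdDataset,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Train the classifier jointly with the attention crowd consensus.

    Only the features and the noisy annotations of ``dataset`` are used;
    gold labels, if present, are ignored. Returns the trained model with the
    per-epoch mean loss history. Identical (dataset, configs) including the
    seed give bitwise-identical histories.
    """
    if net_cfg is None:
        net_cfg = NetworkConfig(dataset.n_features, dataset.class_count)
    if net_cfg.class_count != dataset.class_count:
        raise ValueError(
            f"network class_count {net_cfg.class_count} != dataset "
            f"class_count {dataset.class_count}"
        )
    rng = np.random.default_rng(train_cfg.seed)
    net = MLP(net_cfg, rng)
    opt = AdamState(learning_rate=train_cfg.learning_rate)
    X = dataset.features
    counts = annotation_counts(dataset)
    history: list[float] = []
    for _ in range(train_cfg.epochs):
        epoch_loss = 0.0
        n_seen = 0
        for idx in _batches(X.shape[0], train_cfg.batch_size, rng):
            probs, acts = net.forward(X[idx], cache=True)
            targets = pseudo_labels_from_counts(
                probs, counts[idx], epsilon=train_cfg.epsilon
            )
            logs = np.log(np.clip(probs, LOG_CLAMP, None))
            loss = float(-(targets * logs).sum(axis=1).mean())
            m = idx.shape[0]
            if train_cfg.detach_pseudo_label:
                dlogits = (probs - targets) / m
            else:
                dprobs = _pseudo_label_grad(probs, counts[idx], targets) / m
                inner = (dprobs * probs).sum(axis=1, keepdims=True)
                dlogits = probs * (dprobs - inner)
            opt.step(net, net.backward(acts, dlogits))
            epoch_loss += loss * m
            n_seen += m
        history.append(epoch_loss / n_seen)
    return TrainedModel(network=net, history=history)


def train_on_targets(
    features: np.ndarray,
    targets: np.ndarray,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig = TrainConfig(),
    class_count: int | None = None,
) -> TrainedModel:
    """Train the same backbone on fixed targets (gold or aggregated labels).

    ``targets`` may be hard labels (1-D integer array, one-hot encoded
    internally) or soft rows on the K-simplex (2-D array). This covers the
    gold-trained upper bound and the majority-vote / EM-aggregation
    baselines, which share the architecture and optimiser of the attention
    model but use a fixed cross-entropy target throughout training.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    T = np.asarray(targets, dtype=float)
    if T.ndim == 1:
        K = class_count or int(T.max()) + 1
        T = np.eye(K)[T.astype(int)]
    if T.shape[0] != X.shape[0]:
        raise ValueError(
            f"{X.shape[0]} feature rows but {T.shape[0]} target rows"
        )
    if net_cfg is None:
        net_cfg = NetworkConfig(X.shape[1], T.shape[1])
    rng = np.random.default_rng(train_cfg.seed)
    net = MLP(net_cfg, rng)
    opt = AdamState(learning_rate=train_cfg.learning_rate)
    history: list[float] = []
    for _ in range(train_cfg.epochs):
        epoch_loss = 0.0
        n_seen = 0
        for idx in _batches(X.shape[0], train_cfg.batch_size, rng):
            probs, acts = net.forward(X[idx], cache=True)
            logs = np.log(np.clip(probs, LOG_CLAMP, None))
            loss = float(-(T[idx] * logs).sum(axis=1).mean())
            m = idx.shape[0]
            opt.step(net, net.backward(acts, (probs - T[idx]) / m))
            epoch_loss += loss * m
            n_seen += m
        history.append(epoch_loss / n_seen)
    return TrainedModel(network=net, history=history)


def estimate_reliabilities(
    model: TrainedModel, dataset: CrowdDataset
) -> list[dict[str, float]]:
    """Instance-dependent reliability of each observed annotator.

    For every instance ``n`` and annotator ``w`` in ``W_n``, the score is the
    model's predicted probability of the class that annotator assigned --
    the dot product of the prediction with the one-hot annotation. Returns
    one ``{annotator_id: score}`` dict per instance, aligned with
    ``dataset.instance_ids``.
    """
    known = set(dataset.annotator_ids)
    probs = model.predict_proba(dataset.features)
    out: list[dict[str, float]] = []
    for n, ann in enumerate(dataset.annotations):
        scores: dict[str, float] = {}
        for aid, lab in ann.items():
            if aid not in known:
                raise KeyError(f"annotator {aid!r} not in dataset")
            scores[aid] = float(probs[n, lab])
        out.append(scores)
    return out
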