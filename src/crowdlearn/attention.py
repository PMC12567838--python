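"""Cross-attention label aggregation: the pure math of the method.

The classifier's predicted class distribution ``q`` (the *query*) is matched
against each annotator's one-hot label (serving as both *key* and *value*)
with a plain dot product. Because the query lies on the probability simplex
and keys are one-hot, the score for annotator ``w`` is simply the predicted
probability of the class that annotator chose -- an instance-dependent
reliability in [0, 1]. No softmax is applied across annotators: scores are
already normalised individually, and the pseudo-label normalises the
weighted vote itself::

    p(w)    = q . k(w)                      (reliability score)
    y_tilde = sum_w p(w) o(w) / sum_w p(w)  (pseudo-label)

The training loss is the mean cross-entropy of the predictions against the
pseudo-labels. Aggregation is O(W*K) per instance: one pass to score the W
annotators, one weighted sum over K-vectors.

Everything here is side-effect-free NumPy; the model module wires these into
the training loop.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "reliability_scores",
    "pseudo_label",
    "pseudo_labels_from_counts",
    "crowd_cross_entropy",
]

#: below this total score mass the pseudo-label falls back to a uniform vote
DEFAULT_EPSILON = 1e-8

#: floor applied to predicted probabilities inside logarithms
LOG_CLAMP = 1e-12


def _check_simplex(q: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim != 1:
        raise ValueError("query must be a 1-D probability vector")
    if (q < -tol).any() or (q > 1 + tol).any() or abs(q.sum() - 1.0) > tol:
        raise ValueError("query is not on the probability simplex")
    return q


def reliability_scores(query: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """Dot-product attention scores of a simplex query against one-hot keys.

    Parameters
    ----------
    query : length-K probability vector (the model's predicted distribution).
    keys : ``(m, K)`` array of one-hot annotation vectors, one row per
        observed annotator.

    Returns the length-m vector of scores ``p(w) = query . key_w``, each the
    query's probability of the class annotator ``w`` chose. Values lie in
    [0, 1] and are deliberately not normalised across annotators.
    """
    q = _check_simplex(query)
    k = np.asarray(keys, dtype=float)
    if k.ndim != 2 or k.shape[1] != q.shape[0]:
        raise ValueError(
            f"keys shape {k.shape} incompatible with query length {q.shape[0]}"
        )
    if not ((k == 0) | (k == 1)).all() or not (k.sum(axis=1) == 1).all():
        raise ValueError("keys must be one-hot vectors")
    return k @ q


def pseudo_label(
    scores: np.ndarray, values: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Reliability-weighted consensus of one-hot annotations.

    ``scores`` is the length-m vector of annotator reliabilities, ``values``
    the matching ``(m, K)`` one-hot annotations. Returns the normalised
    weighted vote, a point on the K-simplex. When the total score mass does
    not exceed ``epsilon`` (a query orthogonal to every key), the weights
    fall back to uniform over the observed annotators, i.e. a soft majority
    vote.
    """
    s = np.asarray(scores, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or s.shape != (v.shape[0],):
        raise ValueError("scores and values must agree on the annotator set")
    if v.shape[0] == 0:
        raise ValueError("at least one annotation is required")
    total = s.sum()
    if total <= epsilon:
        s = np.ones_like(s)
        total = s.sum()
    return (s @ v) / total


def pseudo_labels_from_counts(
    predictions: np.ndarray, counts: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Batched pseudo-labels from per-class annotation counts.

    Equivalent to scoring each annotation with the predicted probability of
    its class and aggregating, but grouped by class: with ``c_nk`` the number
    of annotators assigning class ``k`` to instance ``n`` and ``q_nk`` the
    predicted probabilities,

        y_tilde_nk = c_nk * q_nk / sum_j c_nj * q_nj.

    ``predictions`` and ``counts`` are ``(N, K)``. Rows whose weighted mass
    is below ``epsilon`` fall back to the empirical annotation distribution.
    """
    q = np.asarray(predictions, dtype=float)
    c = np.asarray(counts, dtype=float)
    if q.shape != c.shape:
        raise ValueError("predictions and counts must have identical shape")
    if (c.sum(axis=1) < 1).any():
        raise ValueError("every instance needs at least one annotation")
    num = c * q
    mass = num.sum(axis=1, keepdims=True)
    fallback = mass[:, 0] <= epsilon
    if fallback.any():
        num[fallback] = c[fallback]
        mass = num.sum(axis=1, keepdims=True)
    return num / mass


def crowd_cross_entropy(
    predictions: np.ndarray, pseudo_labels: np.ndarray
) -> float:
    """Mean cross-entropy of predicted distributions against pseudo-labels.

    Both arguments are ``(N, K)`` (a single pair of vectors is promoted).
    Predictions are clamped at 1e-12 before the logarithm.
    """
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    t = np.atleast_2d(np.asarray(pseudo_labels, dtype=float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    logs = np.log(np.clip(p, LOG_CLAMP, None))
    return float(-(t * logs).sum(axis=1).mean())
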