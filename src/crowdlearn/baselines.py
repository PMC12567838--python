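"""Label-aggregation baselines: majority voting and Dawid-Skene EM.

Both produce training targets for the shared network backbone
(:func:`crowdlearn.model.train_on_targets`), giving the three reference
systems used alongside the attention model: the gold-trained upper bound,
the majority-vote pipeline, and the EM-aggregation pipeline.

The Dawid-Skene model treats the true class of each instance as a latent
variable and each annotator as a row-stochastic K x K confusion matrix
(row = latent class, column = emitted label). EM alternates between
posterior inference over latent classes (E-step) and re-estimation of class
priors and confusion matrices (M-step), starting from majority-vote
posteriors. Additive smoothing keeps confusion rows and priors strictly
positive so no annotator pattern locks the posteriors at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CrowdDataset

__all__ = ["majority_vote", "dawid_skene", "DawidSkeneResult"]

_SMOOTHING = 1e-6


def majority_vote(
    annotations: list[dict[str, int]] | CrowdDataset, class_count: int | None = None
) -> np.ndarray:
    """Most frequent label per instance; ties break to the lowest class index."""
    if isinstance(annotations, CrowdDataset):
        class_count = annotations.class_count
        annotations = annotations.annotations
    if class_count is None:
        raise ValueError("class_count required when passing raw annotations")
    labels = np.empty(len(annotations), dtype=int)
    for n, ann in enumerate(annotations):
        if not ann:
            raise ValueError(f"instance {n} has no annotations")
        counts = np.bincount(list(ann.values()), minlength=class_count)
        labels[n] = counts.argmax()  # argmax takes the lowest index on ties
    return labels


@dataclass
class DawidSkeneResult:
    """EM output: latent-class posteriors, per-annotator confusion matrices,
    class priors, and convergence diagnostics."""

    posteriors: np.ndarray  # (N, K), rows on the simplex
    confusions: dict[str, np.ndarray]  # annotator id -> (K, K) row-stochastic
    priors: np.ndarray  # (K,)
    log_likelihoods: list[float]
    converged: bool

    @property
    def hard_labels(self) -> np.ndarray:
        return self.posteriors.argmax(axis=1)


def dawid_skene(
    annotations: list[dict[str, int]] | CrowdDataset,
    class_count: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> DawidSkeneResult:
    """Dawid-Skene EM truth inference from a long-format annotation set.

    Initialises posteriors from (soft) majority votes, then iterates:

    * M-step: priors = mean posterior; confusion row ``M_w[k, :]`` =
      posterior-weighted frequency of annotator w's emitted labels given
      latent class k, with additive smoothing 1e-6 before row normalisation.
    * E-step: posterior(n, k) proportional to
      ``prior_k * prod_{w in W_n} M_w[k, o_n(w)]``.

    Stops when the max absolute posterior change drops below ``tol``. The
    observed-data log likelihood is recorded every iteration and is
    non-decreasing. Non-convergence within ``max_iter`` sets
    ``converged=False`` rather than raising.
    """
    if isinstance(annotations, CrowdDataset):
        class_count = annotations.class_count
        annotations = annotations.annotations
    if class_count is None:
        raise ValueError("class_count required when passing raw annotations")
    K = class_count
    N = len(annotations)
    annotator_ids = sorted({a for ann in annotations for a in ann})
    aindex = {a: w for w, a in enumerate(annotator_ids)}
    W = len(annotator_ids)

    # (n, w, label) triples in flat arrays for vectorised accumulation
    nn, ww, ll = [], [], []
    for n, ann in enumerate(annotations):
        if not ann:
            raise ValueError(f"instance {n} has no annotations")
        for a, lab in ann.items():
            nn.append(n)
            ww.append(aindex[a])
            ll.append(lab)
    nn = np.asarray(nn)
    ww = np.asarray(ww)
    ll = np.asarray(ll)

    # soft-MV initialisation of the posteriors
    posteriors = np.zeros((N, K))
    np.add.at(posteriors, (nn, ll), 1.0)
    posteriors /= posteriors.sum(axis=1, keepdims=True)

    log_likelihoods: list[float] = []
    converged = False
    for _ in range(max_iter):
        # M-step
        priors = posteriors.mean(axis=0) + _SMOOTHING
        priors /= priors.sum()
        conf = np.full((W, K, K), _SMOOTHING)
        np.add.at(conf, (ww, slice(None), ll), posteriors[nn])
        conf /= conf.sum(axis=2, keepdims=True)

        # E-step in log space
        logpost = np.tile(np.log(priors), (N, 1))
        np.add.at(logpost, (nn, slice(None)), np.log(conf[ww, :, ll]))
        mx = logpost.max(axis=1, keepdims=True)
        unnorm = np.exp(logpost - mx)
        norm = unnorm.sum(axis=1, keepdims=True)
        new_post = unnorm / norm
        log_likelihoods.append(float((np.log(norm) + mx).sum()))

        delta = np.abs(new_post - posteriors).max()
        posteriors = new_post
        if delta < tol:
            converged = True
            break

    confusions = {a: conf[aindex[a]] for a in annotator_ids}
    return DawidSkeneResult(
        posteriors=posteriors,
        confusions=confusions,
        priors=priors,
        log_likelihoods=log_likelihoods,
        converged=converged,
    )
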