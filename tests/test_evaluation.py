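"""Metrics, reliability recovery, Friedman test, annotator sweep."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from crowdlearn.evaluation import (
    annotator_sweep,
    classification_report,
    friedman_test,
    reliability_recovery_f1,
    restrict_annotators,
    sweep_subset_sizes,
)


# -- classification report ----------------------------------------------------

def test_perfect_and_flipped_predictions():
    y = np.array([0, 1, 0, 1])
    rep = classification_report(y, y, 2)
    assert rep.accuracy == 100.0 and rep.macro_f1 == 100.0
    flipped = classification_report(y, 1 - y, 2)
    assert flipped.macro_f1 == 0.0


def test_hand_computed_three_class_report():
    rep = classification_report([0, 0, 1, 1, 2, 2], [0, 1, 1, 1, 2, 0], 3)
    assert rep.per_class_f1 == pytest.approx((50.0, 80.0, 200 / 3), abs=0.01)
    assert rep.macro_f1 == pytest.approx(65.56, abs=0.01)
    assert rep.macro_f1 == pytest.approx(np.mean(rep.per_class_f1))
    assert rep.accuracy == pytest.approx(100 * 4 / 6)


def test_zero_support_class_scores_zero():
    # class 2 never appears in truth or prediction -> F1 contribution 0
    rep = classification_report([0, 1], [0, 1], 3)
    assert rep.per_class_f1[2] == 0.0
    assert rep.macro_f1 == pytest.approx(200 / 3)


def test_report_rejects_out_of_range_labels():
    with pytest.raises(ValueError):
        classification_report([0, 3], [0, 1], 3)


# -- reliability recovery -----------------------------------------------------

def _wrap(scores_by_ann):
    """{ann: [v,...]} -> list of per-instance dicts."""
    n = len(next(iter(scores_by_ann.values())))
    return [{a: v[i] for a, v in scores_by_ann.items()} for i in range(n)]


def test_recovery_perfect_and_degenerate():
    truth = _wrap({"a": [1, 0, 1, 0]})
    per, avg = reliability_recovery_f1(_wrap({"a": [1, 0, 1, 0]}), truth)
    assert avg == 100.0
    per, avg = reliability_recovery_f1(_wrap({"a": [0, 0, 0, 0]}), truth)
    assert avg == 0.0  # no positives predicted


def test_recovery_thresholding_hand_case():
    est = _wrap({"a": [0.9, 0.4, 0.6, 0.1]})
    truth = _wrap({"a": [1, 0, 1, 0]})
    per, avg = reliability_recovery_f1(est, truth)
    assert per["a"] == 100.0 and avg == 100.0


def test_recovery_invariant_to_monotone_transform_preserving_threshold():
    rng = np.random.default_rng(0)
    est = {"a": rng.uniform(0, 1, 50).tolist(), "b": rng.uniform(0, 1, 50).tolist()}
    truth = {
        a: (rng.uniform(0, 1, 50) > 0.4).astype(int).tolist() for a in est
    }
    _, base = reliability_recovery_f1(_wrap(est), _wrap(truth))

    def squash(v):  # strictly monotone, fixes the 0.5 crossing
        return 0.5 + 0.5 * np.tanh(4 * (v - 0.5))

    est2 = {a: [float(squash(v)) for v in vs] for a, vs in est.items()}
    _, transformed = reliability_recovery_f1(_wrap(est2), _wrap(truth))
    assert transformed == pytest.approx(base)


def test_recovery_rejects_misaligned_sets():
    with pytest.raises(ValueError):
        reliability_recovery_f1(_wrap({"a": [1.0]}), _wrap({"b": [1]}))


# -- Friedman test ------------------------------------------------------------

def _friedman_oracle(scores):
    """Exact-arithmetic ranking + the rank-sum formula, via Fractions."""
    k, N = scores.shape
    rank_sums = [Fraction(0)] * k
    for j in range(N):
        col = scores[:, j]
        for i in range(k):
            less = sum(1 for v in col if v > col[i])
            ties = sum(1 for v in col if v == col[i])
            # average rank of the tied group
            rank_sums[i] += Fraction(2 * less + ties + 1, 2)
    total = sum(r * r for r in rank_sums)
    chi2 = Fraction(12, N * k * (k + 1)) * total - 3 * N * (k + 1)
    return float(chi2)


def test_friedman_all_identical_is_zero():
    chi2, p = friedman_test(np.ones((4, 5)))
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_friedman_strict_ordering_hand_case():
    """3 methods x 3 conditions, same strict ordering everywhere: rank sums
    (3, 6, 9) give chi-square exactly 6."""
    scores = np.array([[3, 3, 3], [2, 2, 2], [1, 1, 1]], dtype=float)
    chi2, p = friedman_test(scores)
    assert chi2 == pytest.approx(6.0, abs=1e-12)
    assert p == pytest.approx(float(stats.chi2.sf(6.0, 2)))


def test_friedman_row_permutation_invariance():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=(5, 7))
    chi2, _ = friedman_test(scores)
    perm = rng.permutation(5)
    chi2_p, _ = friedman_test(scores[perm])
    assert chi2_p == pytest.approx(chi2, abs=1e-12)


def test_friedman_matches_exact_oracle_on_random_matrices():
    rng = np.random.default_rng(3)
    for _ in range(20):
        scores = rng.normal(size=(4, 6))  # continuous draws: ties a.s. absent
        chi2, _ = friedman_test(scores)
        assert chi2 == pytest.approx(_friedman_oracle(scores), abs=1e-9)
        # scipy implements the same tie-free statistic
        ref = stats.friedmanchisquare(*scores).statistic
        assert chi2 == pytest.approx(ref, abs=1e-9)


def test_friedman_validates_shape():
    with pytest.raises(ValueError):
        friedman_test(np.ones((2, 5)))
    with pytest.raises(ValueError):
        friedman_test(np.ones((3, 1)))


# -- annotator sweep ----------------------------------------------------------

def test_sweep_sizes_capped_progression():
    assert sweep_subset_sizes(57, 4) == list(range(1, 58, 4))
    assert len(sweep_subset_sizes(57, 4)) == 15
    assert sweep_subset_sizes(5, 4) == [1, 5]
    assert sweep_subset_sizes(6, 4) == [1, 5, 6]
    assert sweep_subset_sizes(1, 4) == [1]


def test_sweep_orders_by_count_then_id_and_drops_uncovered(tiny_dataset):
    # counts: a=4, b=3, c=3 -> order a, b, c (tie b/c broken by id)
    calls = []

    def probe(ds):
        calls.append((ds.n_annotators, ds.n_instances))
        return float(ds.n_annotators)

    res = annotator_sweep(tiny_dataset, {"probe": probe}, step=1)
    assert res.annotator_order == ["a", "b", "c"]
    assert res.subset_sizes == [1, 2, 3]
    assert res.scores["probe"] == [1.0, 2.0, 3.0]
    reduced, mask = restrict_annotators(tiny_dataset, ["b"])
    # instance i2 has only annotators a and c -> dropped under {b}
    assert reduced.instance_ids == ["i0", "i1", "i3"]
    assert mask.tolist() == [True, True, False, True]


def test_sweep_sizes_independent_of_method(tiny_dataset):
    res1 = annotator_sweep(tiny_dataset, {"m": lambda ds: 0.0}, step=2)
    res2 = annotator_sweep(tiny_dataset, {"m": lambda ds: 1.0}, step=2)
    assert res1.subset_sizes == res2.subset_sizes == [1, 3]
    with pytest.raises(ValueError):
        annotator_sweep(tiny_dataset, {}, step=2)
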