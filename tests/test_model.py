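"""Classifier backbone and the joint attention training loop."""

import numpy as np
import pytest

from crowdlearn.attention import pseudo_labels_from_counts
from crowdlearn.model import (
    TrainConfig,
    TrainedModel,
    annotation_counts,
    estimate_reliabilities,
    train_attention_classifier,
    train_on_targets,
)
from crowdlearn.nnet import MLP, NetworkConfig

FAST = TrainConfig(epochs=30, seed=0)


def test_forward_outputs_lie_on_simplex():
    net = MLP(NetworkConfig(2, 4), np.random.default_rng(0))
    probs = net.forward(np.random.default_rng(1).normal(size=(10, 2)))
    assert probs.shape == (10, 4)
    assert (probs >= 0).all()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_forward_is_deterministic_and_validates_input():
    net = MLP(NetworkConfig(1, 3), np.random.default_rng(5))
    x = np.array([[0.3]])
    np.testing.assert_array_equal(net.forward(x), net.forward(x))
    with pytest.raises(ValueError):
        net.forward(np.zeros((2, 4)))
    with pytest.raises(ValueError):
        net.forward(np.array([[np.inf]]))


def test_zeroed_head_gives_uniform_distribution():
    net = MLP(NetworkConfig(1, 3), np.random.default_rng(0))
    net.weights[-1][:] = 0.0
    net.biases[-1][:] = 0.0
    probs = net.forward(np.array([[0.4], [0.9]]))
    np.testing.assert_allclose(probs, 1 / 3, atol=1e-12)


def test_training_ignores_gold_labels(benchmark):
    """The crowd loop must not consume gold labels: corrupting them changes
    nothing."""
    ds = benchmark.train
    corrupted = type(ds)(
        instance_ids=ds.instance_ids,
        features=ds.features,
        annotations=ds.annotations,
        class_count=ds.class_count,
        annotator_ids=ds.annotator_ids,
        gold_labels=(ds.gold_labels + 1) % 3,
    )
    a = train_attention_classifier(ds, train_cfg=FAST)
    b = train_attention_classifier(corrupted, train_cfg=FAST)
    np.testing.assert_array_equal(a.history, b.history)


def test_identical_seeds_give_identical_histories(benchmark):
    cfg = TrainConfig(epochs=15, seed=3)
    a = train_attention_classifier(benchmark.train, train_cfg=cfg)
    b = train_attention_classifier(benchmark.train, train_cfg=cfg)
    assert a.history == b.history
    for Wa, Wb in zip(a.network.weights, b.network.weights):
        np.testing.assert_array_equal(Wa, Wb)


def test_loss_descends_over_training(benchmark):
    for seed in (0, 1, 2):
        m = train_attention_classifier(
            benchmark.train, train_cfg=TrainConfig(epochs=60, seed=seed)
        )
        assert m.history[-1] < m.history[0]


def test_warm_start_pseudo_labels_near_soft_majority_vote(benchmark):
    """At a symmetric random init the query is near uniform, so the first
    pseudo-labels track soft majority votes; their deviation is controlled
    by the query's own deviation from uniform."""
    ds = benchmark.train
    counts = annotation_counts(ds)
    soft_mv = counts / counts.sum(axis=1, keepdims=True)
    for seed in range(5):
        net = MLP(NetworkConfig(1, 3), np.random.default_rng(seed))
        probs = net.forward(ds.features)
        spread = np.abs(probs - 1 / 3).max()
        deviation = np.abs(pseudo_labels_from_counts(probs, counts) - soft_mv).max()
        assert spread < 0.15  # init is near-uniform
        assert deviation <= 3 * spread + 1e-9


def test_detach_flag_changes_the_gradient_path(benchmark):
    cfg_d = TrainConfig(epochs=10, seed=0, detach_pseudo_label=True)
    cfg_f = TrainConfig(epochs=10, seed=0, detach_pseudo_label=False)
    a = train_attention_classifier(benchmark.train, train_cfg=cfg_d)
    b = train_attention_classifier(benchmark.train, train_cfg=cfg_f)
    assert a.history != b.history


def test_predictions_do_not_depend_on_annotations(benchmark):
    m = train_attention_classifier(benchmark.train, train_cfg=FAST)
    X = benchmark.test.features
    probs1, labels1 = m.predict(X)
    probs2, labels2 = m.predict(X)  # annotations play no role at inference
    np.testing.assert_array_equal(probs1, probs2)
    assert probs1.shape[0] == X.shape[0]
    np.testing.assert_array_equal(labels1, probs1.argmax(axis=1))


def test_argmax_tie_break_to_lowest_index():
    assert int(np.array([0.2, 0.5, 0.3]).argmax()) == 1
    assert int(np.array([0.4, 0.4, 0.2]).argmax()) == 0


def test_reliability_extraction_is_predicted_probability_of_chosen_class(
    benchmark,
):
    m = train_attention_classifier(benchmark.train, train_cfg=FAST)
    ds = benchmark.test
    scores = estimate_reliabilities(m, ds)
    probs = m.predict_proba(ds.features)
    for n, ann in enumerate(ds.annotations):
        for aid, lab in ann.items():
            assert scores[n][aid] == probs[n, lab]
            assert 0.0 <= scores[n][aid] <= 1.0


def test_reliability_extraction_unknown_annotator(tiny_dataset):
    m = train_attention_classifier(tiny_dataset, train_cfg=TrainConfig(epochs=2))
    # sneak in an annotator the dataset never declared
    tampered = type(tiny_dataset)(
        instance_ids=tiny_dataset.instance_ids,
        features=tiny_dataset.features,
        annotations=[dict(a) for a in tiny_dataset.annotations],
        class_count=3,
    )
    tampered.annotations[0]["zz"] = 0
    with pytest.raises(KeyError, match="zz"):
        estimate_reliabilities(m, tampered)


def test_train_on_targets_determinism_and_mv_gold_equivalence(tiny_dataset):
    X = tiny_dataset.features
    y = tiny_dataset.gold_labels
    cfg = TrainConfig(epochs=20, seed=1)
    a = train_on_targets(X, y, train_cfg=cfg, class_count=3)
    b = train_on_targets(X, y, train_cfg=cfg, class_count=3)
    for Wa, Wb in zip(a.network.weights, b.network.weights):
        np.testing.assert_array_equal(Wa, Wb)
    # a unanimous noise-free crowd's MV equals gold -> identical models
    from crowdlearn.baselines import majority_vote

    unanimous = type(tiny_dataset)(
        instance_ids=tiny_dataset.instance_ids,
        features=X,
        annotations=[{"a": int(l), "b": int(l)} for l in y],
        class_count=3,
    )
    mv = majority_vote(unanimous)
    c = train_on_targets(X, mv, train_cfg=cfg, class_count=3)
    for Wa, Wc in zip(a.network.weights, c.network.weights):
        np.testing.assert_array_equal(Wa, Wc)


def test_checkpoint_round_trip(tmp_path, tiny_dataset):
    m = train_attention_classifier(tiny_dataset, train_cfg=TrainConfig(epochs=5))
    path = tmp_path / "model.npz"
    m.save(path)
    back = TrainedModel.load(path)
    np.testing.assert_array_equal(
        m.predict_proba(tiny_dataset.features),
        back.predict_proba(tiny_dataset.features),
    )
    assert back.history == m.history


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1)
    with pytest.raises(ValueError):
        NetworkConfig(1, 1)
    with pytest.raises(ValueError):
        NetworkConfig(1, 3, hidden_sizes=())


def test_class_count_mismatch_rejected(tiny_dataset):
    with pytest.raises(ValueError, match="class_count"):
        train_attention_classifier(
            tiny_dataset, NetworkConfig(1, 4), TrainConfig(epochs=1)
        )
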