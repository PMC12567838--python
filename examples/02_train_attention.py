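"""Train the attention-aggregation classifier on noisy crowd labels only.

The model never sees the true labels: each epoch its predicted class
distribution scores every annotator's label (the predicted probability of
the class that annotator chose), the scores form a weighted consensus
pseudo-label, and the network fits that target. Prints test macro F1
against the withheld gold labels and how well the learned instance-wise
reliabilities recover which annotations were actually correct.
"""

from crowdlearn import (
    TrainConfig,
    classification_report,
    estimate_reliabilities,
    make_synthetic_crowd,
    reliability_recovery_f1,
    train_attention_classifier,
)

crowd = make_synthetic_crowd(seed=1)
model = train_attention_classifier(crowd.train, train_cfg=TrainConfig(seed=0))

_, preds = model.predict(crowd.test.features)
rep = classification_report(crowd.test.gold_labels, preds, 3)
print(f"loss: {model.history[0]:.3f} (epoch 1) -> {model.history[-1]:.3f} (epoch 500)")
print(f"test accuracy {rep.accuracy:.2f}%, macro F1 {rep.macro_f1:.2f}%")

estimated = estimate_reliabilities(model, crowd.test)
truth = [
    {aid: int(crowd.test_reliability[n, w])
     for w, aid in enumerate(crowd.test.annotator_ids)}
    for n in range(crowd.test.n_instances)
]
per_annotator, average = reliability_recovery_f1(estimated, truth)
print("reliability recovery F1 per annotator (threshold 0.5):")
for aid, f1 in per_annotator.items():
    print(f"  {aid}: {f1:.2f}%")
print(f"average: {average:.2f}%  (how well the model knows who to trust, where)")
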