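"""Compare the attention model with aggregation baselines.

All four systems share the same 512/256 backbone and optimiser; they differ
only in the training target: true labels (upper bound), majority-vote
labels, Dawid-Skene EM posteriors, or the attention pseudo-labels that
co-evolve with the model. A Friedman rank test across seeds checks whether
the differences are systematic.
"""

import numpy as np

from crowdlearn import (
    TrainConfig,
    classification_report,
    friedman_test,
    make_synthetic_crowd,
    train_attention_classifier,
    train_on_targets,
)
from crowdlearn.baselines import dawid_skene, majority_vote

crowd = make_synthetic_crowd(seed=1)
X, test = crowd.train.features, crowd.test
mv_targets = majority_vote(crowd.train)
ds_targets = dawid_skene(crowd.train).posteriors

SEEDS = range(3)
scores: dict[str, list[float]] = {}
for seed in SEEDS:
    cfg = TrainConfig(seed=seed)
    runs = {
        "gold": train_on_targets(X, crowd.train.gold_labels, train_cfg=cfg, class_count=3),
        "attention": train_attention_classifier(crowd.train, train_cfg=cfg),
        "ds": train_on_targets(X, ds_targets, train_cfg=cfg),
        "mv": train_on_targets(X, mv_targets, train_cfg=cfg, class_count=3),
    }
    for name, model in runs.items():
        _, preds = model.predict(test.features)
        f1 = classification_report(test.gold_labels, preds, 3).macro_f1
        scores.setdefault(name, []).append(f1)

print("test macro F1 (%) by seed:")
for name, vals in scores.items():
    print(f"  {name:>9}: " + "  ".join(f"{v:.2f}" for v in vals)
          + f"   mean {np.mean(vals):.2f}")

# rank the three crowd methods (gold is the oracle, excluded) across seeds
matrix = np.array([scores["attention"], scores["ds"], scores["mv"]])
chi2, p = friedman_test(matrix)
print(f"\nFriedman test over crowd methods: chi2 = {chi2:.2f}, p = {p:.3f}")
print("(small p: consistent ranking differences across initialisations)")
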