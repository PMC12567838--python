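"""Cumulative annotator sweep: how much does each extra annotator help?

Annotators are sorted by the number of instances they labelled and added
four at a time (sizes 1, 5, ... capped at W). At each subset size the
training set is restricted to the surviving annotations and each method is
retrained from scratch; instances that lose all annotations are dropped.
"""

from crowdlearn import TrainConfig, classification_report, make_synthetic_crowd
from crowdlearn.baselines import majority_vote
from crowdlearn.evaluation import annotator_sweep
from crowdlearn.model import train_attention_classifier, train_on_targets

crowd = make_synthetic_crowd(seed=1)
test = crowd.test
cfg = TrainConfig(epochs=200, seed=0)


def score(model):
    _, preds = model.predict(test.features)
    return classification_report(test.gold_labels, preds, 3).macro_f1


methods = {
    "attention": lambda ds: score(train_attention_classifier(ds, train_cfg=cfg)),
    "mv": lambda ds: score(
        train_on_targets(ds.features, majority_vote(ds), train_cfg=cfg, class_count=3)
    ),
}

result = annotator_sweep(crowd.train, methods, step=4)
print("annotators (by label count):", ", ".join(result.annotator_order))
print("\nsubset size  " + "  ".join(f"{m:>9}" for m in result.scores))
for i, size in enumerate(result.subset_sizes):
    row = "  ".join(f"{result.scores[m][i]:9.2f}" for m in result.scores)
    print(f"{size:>11}  {row}")
print("\ntest macro F1 (%) per subset; with one annotator both methods can only")
print("fit that annotator's noisy labels, the full pool approaches the gold bound.")
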