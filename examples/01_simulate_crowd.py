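"""Generate the synthetic multi-annotator benchmark and inspect it.

Builds the three-class sinusoidal task (300 train / 200 test scalar inputs
on [0, 1]) and simulates five annotators whose reliability depends on where
the input falls: each has a fixed union of subintervals on which it always
labels correctly, and errs uniformly among the wrong classes elsewhere.
"""

import numpy as np

from crowdlearn import make_synthetic_crowd
from crowdlearn.baselines import majority_vote
from crowdlearn.synthetic import DEFAULT_ACCURACIES, default_profiles

crowd = make_synthetic_crowd(seed=1)

print("annotator  target%  realised% (train, n=300)  reliable set")
for prof, target, acc in zip(
    default_profiles(), DEFAULT_ACCURACIES, crowd.annotator_accuracies("train")
):
    ivs = " u ".join(f"[{a:.3f},{b:.3f})" for a, b in prof.intervals)
    print(f"{prof.name:>9}  {target:6.2f}  {acc:8.2f}              {ivs}")

mv = majority_vote(crowd.train)
mv_acc = 100 * (mv == crowd.train.gold_labels).mean()
print(f"\nplain majority vote labels the training set at {mv_acc:.1f}% accuracy;")
print("the gap to 100% is what input-aware reliability weighting can recover.")
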