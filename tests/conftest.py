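import numpy as np
import pandas as pd
import pytest

from crowdlearn import assemble_dataset, make_synthetic_crowd


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark (300 train / 200 test, 5 annotators)."""
    return make_synthetic_crowd(seed=1)


@pytest.fixture
def tiny_dataset():
    """4 instances, 3 annotators with one missing annotation, K=3, with gold."""
    X = np.array([[0.1], [0.4], [0.6], [0.9]])
    ann = pd.DataFrame(
        [
            ("i0", "a", 0), ("i0", "b", 0), ("i0", "c", 1),
            ("i1", "a", 2), ("i1", "b", 2),
            ("i2", "a", 2), ("i2", "c", 2),
            ("i3", "a", 1), ("i3", "b", 0), ("i3", "c", 1),
        ],
        columns=["instance_id", "annotator_id", "label"],
    )
    return assemble_dataset(
        X, ann, class_count=3, instance_ids=["i0", "i1", "i2", "i3"],
        gold={"i0": 0, "i1": 2, "i2": 2, "i3": 1},
    )
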