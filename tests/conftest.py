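import numpy as np
import pandas as pd
import pytest

from unicorp import FeatureMatrix, HierarchyTable, TargetVariable

TOY_COLUMNS = ["A1", "A2", "A3", "A4", "A5"]

# 8 samples x 5 leaves under the 3-level tree C1 -> {B1 -> {A1,A2,A3},
# B2 -> {A4,A5}}; with Pearson, no transform and threshold 0.2 exactly A1
# is promoted at the leaf level and exactly B2 one level up.
TOY_VALUES = np.array(
    [
        [1.0, 1.1335, 2.3120, 1.1008, 1.8347],
        [2.0, 1.9335, 1.6508, 1.7451, 2.6688],
        [3.0, 3.5440, 5.3883, 2.7534, 1.0000],
        [4.0, 1.7779, 3.2774, 1.0000, 4.4450],
        [5.0, 1.0000, 1.0000, 4.1054, 4.9710],
        [6.0, 3.2292, 2.7596, 3.7760, 6.8313],
        [7.0, 1.6642, 3.4338, 2.1574, 6.2923],
        [8.0, 4.3084, 3.1366, 5.5469, 5.8265],
    ]
)


@pytest.fixture
def toy_tree():
    return HierarchyTable(
        data=pd.DataFrame(
            [["C1"] * 5, ["B1"] * 3 + ["B2"] * 2, TOY_COLUMNS],
            index=["C", "B", "A"],
            columns=TOY_COLUMNS,
        )
    )


@pytest.fixture
def toy_features():
    samples = [f"s{i}" for i in range(8)]
    return FeatureMatrix(
        data=pd.DataFrame(TOY_VALUES, index=samples, columns=TOY_COLUMNS)
    )


@pytest.fixture
def toy_target(toy_features):
    return TargetVariable(
        values=pd.Series(np.arange(1.0, 9.0), index=toy_features.sample_ids),
        name="y",
    )


def random_inputs(rng, n=10, groups=(3, 3)):
    """Small random (features, target, groups) triple for metric tests."""
    m = sum(groups)
    cols = [f"f{i}" for i in range(m)]
    fm = FeatureMatrix(
        data=pd.DataFrame(
            rng.random((n, m)) * 10,
            index=[f"s{i}" for i in range(n)],
            columns=cols,
        )
    )
    tv = TargetVariable(
        values=pd.Series(rng.normal(size=n), index=fm.sample_ids), name="y"
    )
    grouping, start = {}, 0
    for gi, size in enumerate(groups):
        grouping[f"g{gi}"] = cols[start : start + size]
        start += size
    return fm, tv, grouping
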