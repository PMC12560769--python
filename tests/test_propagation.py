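import itertools

import numpy as np
import pandas as pd
import pytest

from unicorp import (
    CorrelationSpec,
    DataError,
    FeatureMatrix,
    HierarchyTable,
    SelectionSpec,
    TargetVariable,
    TransformSpec,
    aggregate_to_level,
    build_tree,
    select_unicorns,
    unicorp_run,
)
from unicorp.unicor import ScoreRecord, ScoreSet


def _scoreset(scores: dict[str, float]) -> ScoreSet:
    records = [
        ScoreRecord(feature=f, lineage=(f,), parent_group="G", abs_fcc=2 * s, mean_ffc=0.0)
        for f, s in scores.items()
    ]
    return ScoreSet(level="L", records=records, method="pearson", transform="none")


class TestSelectUnicorns:
    def test_threshold_is_strict(self):
        scores = _scoreset({"A1": 0.30, "A2": 0.10, "A3": -0.20})
        sel = select_unicorns(scores, SelectionSpec(mode="threshold", theta=0.2))
        assert sel == {"A1"}
        # a score exactly at the threshold is not selected
        at = select_unicorns(scores, SelectionSpec(mode="threshold", theta=0.30))
        assert at == set()

    def test_top_k_zero_and_overflow(self):
        scores = _scoreset({"A1": 0.30, "A2": 0.10, "A3": -0.20})
        assert select_unicorns(scores, SelectionSpec(mode="top_k", k=0)) == set()
        assert select_unicorns(scores, SelectionSpec(mode="top_k", k=99)) == {
            "A1", "A2", "A3",
        }

    def test_top_k_tie_break_matches_enumeration(self):
        """With ties at the k-th rank, the choice is the lexicographically
        smallest among all valid top-k sets (checked by enumeration)."""
        scores = _scoreset({"b": 0.3, "d": 0.2, "a": 0.2, "c": 0.2, "e": 0.1})
        k = 3
        got = select_unicorns(scores, SelectionSpec(mode="top_k", k=k))
        vals = scores.scores()
        valid = [
            set(combo)
            for combo in itertools.combinations(vals, k)
            if min(vals[f] for f in combo)
            >= max(v for f, v in vals.items() if f not in combo)
        ]
        assert got in valid
        assert got == min(valid, key=lambda s: sorted(s))  # deterministic choice
        assert got == {"b", "a", "c"}

    def test_mutually_exclusive_modes(self):
        with pytest.raises(ValueError):
            SelectionSpec(mode="threshold", theta=0.1, k=3)
        with pytest.raises(ValueError):
            SelectionSpec(mode="top_k")
        with pytest.raises(ValueError):
            SelectionSpec(mode="threshold", theta=1.5)


class TestWorkedExample:
    """The 3-level toy: A1 promoted at the leaf level, B2 one level up."""

    def run(self, toy_target, toy_features, toy_tree, **kw):
        kw.setdefault("transform", TransformSpec(kind="none"))
        kw.setdefault("correlation", CorrelationSpec("pearson"))
        kw.setdefault("selection", SelectionSpec(mode="threshold", theta=0.2))
        return unicorp_run(toy_target, toy_features, toy_tree, **kw)

    def test_propagation_narrative(self, toy_target, toy_features, toy_tree):
        res = self.run(toy_target, toy_features, toy_tree)
        assert res.unicorns == {"A": ["A1"], "B": ["B2"]}
        assert list(res.level_matrices["B"].data.columns) == ["A1", "B1", "B2"]
        assert list(res.level_matrices["C"].data.columns) == ["C1", "B2"]
        # A1 and B1 fold back into C1; B2 keeps its own values at the top
        leaves = toy_features.data
        pd.testing.assert_series_equal(
            res.level_matrices["C"].data["C1"],
            leaves[["A1", "A2", "A3"]].sum(axis=1),
            check_names=False,
        )
        pd.testing.assert_series_equal(
            res.level_matrices["C"].data["B2"],
            leaves[["A4", "A5"]].sum(axis=1),
            check_names=False,
        )

    def test_promoted_node_keeps_upper_ancestry(self, toy_target, toy_features, toy_tree):
        res = self.run(toy_target, toy_features, toy_tree)
        # A1 became its own parent at level B but still descends from C1
        assert res.hierarchy.data.loc["B", "A1"] == "A1"
        assert res.hierarchy.data.loc["C", "A1"] == "C1"

    def test_conservation_under_propagation(self, toy_target, toy_features, toy_tree):
        res = self.run(toy_target, toy_features, toy_tree)
        totals = toy_features.data.sum(axis=1)
        for level, fm in res.level_matrices.items():
            np.testing.assert_allclose(fm.data.sum(axis=1), totals)

    def test_determinism(self, toy_target, toy_features, toy_tree):
        a = self.run(toy_target, toy_features, toy_tree)
        b = self.run(toy_target, toy_features, toy_tree)
        pd.testing.assert_frame_equal(a.hierarchy.data, b.hierarchy.data)
        for level in a.level_matrices:
            pd.testing.assert_frame_equal(
                a.level_matrices[level].data, b.level_matrices[level].data
            )

    @pytest.mark.parametrize(
        "selection",
        [
            SelectionSpec(mode="threshold", theta=1.0),
            SelectionSpec(mode="top_k", k=0),
        ],
    )
    def test_baseline_equivalence(self, toy_target, toy_features, toy_tree, selection):
        """theta = 1 (nothing strictly exceeds the max) or k = 0 reproduces
        plain per-level aggregation bit-for-bit."""
        res = self.run(toy_target, toy_features, toy_tree, selection=selection)
        pd.testing.assert_frame_equal(res.hierarchy.data, toy_tree.data)
        tree = build_tree(toy_tree)
        for level in ["A", "B", "C"]:
            plain = aggregate_to_level(toy_features, tree, level)
            assert res.level_matrices[level].data.equals(plain.data)

    def test_threshold_monotone_at_leaf_level(self, toy_target, toy_features, toy_tree):
        sel = {}
        for theta in (0.05, 0.2, 0.5):
            res = self.run(
                toy_target, toy_features, toy_tree,
                selection=SelectionSpec(mode="threshold", theta=theta),
            )
            sel[theta] = set(res.unicorns["A"])
        assert sel[0.5] <= sel[0.2] <= sel[0.05]

    def test_feature_count_bound_with_top_k(self, toy_target, toy_features, toy_tree):
        for k in (0, 1, 2):
            res = self.run(
                toy_target, toy_features, toy_tree,
                selection=SelectionSpec(mode="top_k", k=k),
            )
            n_top = res.level_matrices["C"].shape[1]
            assert n_top <= 1 + k * 2  # original top taxa + k per scored level


class TestRunValidation:
    def test_single_level_hierarchy_rejected(self, toy_target, toy_features):
        flat = HierarchyTable(
            data=pd.DataFrame(
                [list(toy_features.feature_ids)],
                index=["A"],
                columns=toy_features.feature_ids,
            )
        )
        with pytest.raises(DataError, match="single-level"):
            unicorp_run(toy_target, toy_features, flat)

    def test_transformed_leaf_matrix_rejected(self, toy_target, toy_features, toy_tree):
        fm = FeatureMatrix(data=toy_features.data, transform="clr")
        with pytest.raises(DataError, match="untransformed"):
            unicorp_run(toy_target, fm, toy_tree)

    def test_misaligned_samples_rejected(self, toy_target, toy_features, toy_tree):
        tv = TargetVariable(
            values=toy_target.values.iloc[::-1], name="y"
        )
        with pytest.raises(DataError, match="aligned"):
            unicorp_run(tv, toy_features, toy_tree)


def test_always_selected_leaf_reaches_top_with_leaf_values(toy_tree):
    """A leaf promoted at every level ends as its own top-level column with
    values identical to its leaf column."""
    rng = np.random.default_rng(4)
    samples = [f"s{i}" for i in range(8)]
    data = pd.DataFrame(
        rng.integers(1, 9, (8, 5)).astype(float),
        index=samples,
        columns=["A1", "A2", "A3", "A4", "A5"],
    )
    y = np.arange(8.0)
    data["A1"] = y * 2 + 1  # perfectly correlated, unlike its siblings
    fm = FeatureMatrix(data=data)
    tv = TargetVariable(values=pd.Series(y, index=samples), name="y")
    res = unicorp_run(
        tv, fm, toy_tree,
        transform=TransformSpec(kind="none"),
        correlation=CorrelationSpec("pearson"),
        selection=SelectionSpec(mode="top_k", k=1),
    )
    top = res.level_matrices["C"]
    assert "A1" in top.data.columns
    pd.testing.assert_series_equal(top.data["A1"], data["A1"], check_names=False)
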