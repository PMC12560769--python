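"""Bottom-up propagation of uniquely correlated features (UniCorP).

Plain taxonomic aggregation sums every leaf into its ancestor, which can
dilute the signal of a single informative leaf inside an uninformative
group. The propagation algorithm walks the hierarchy from the most
specific level upward and, at each level:

1. aggregates the raw leaf matrix to the level's nodes (using the current,
   possibly already-enriched hierarchy),
2. applies the chosen per-sample transform to the aggregated matrix,
3. scores every node with the UniCor metric inside its parent group,
4. selects high scorers — by a strict threshold on the score, or the k
   best of the level — and
5. promotes each selected node to be *its own parent* at the next level,
   leaving its ancestry above that level untouched.

A promoted node therefore survives aggregation one level up, competes
again among its former parent's siblings, and can be promoted repeatedly —
all the way to the top if it keeps scoring high. Non-selected nodes are
absorbed into their parent as usual, so per-sample totals are conserved at
every level: promotion relabels parents, it never duplicates or drops
mass.

The result is an enriched hierarchy whose upper levels carry both the
original taxa and the promoted features, plus per-level aggregated
matrices and score tables.
"""

from __future__ import annotations

import dataclasses
import warnings

from .hierarchy import TreeIndex, aggregate_to_level, build_tree
from .io_tabular import DataError, FeatureMatrix, HierarchyTable, TargetVariable
from .transforms import TransformSpec, apply_transform
from .unicor import CorrelationSpec, ScoreSet, unicor_scores

__all__ = [
    "SelectionSpec",
    "PropagationResult",
    "select_unicorns",
    "propagate_level",
    "unicorp_run",
]


@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """Which scored features count as UNICORNs at a level.

    Exactly one of the two strategies is active: ``threshold`` keeps every
    feature whose score strictly exceeds ``theta`` (recommended range 0-1;
    values down to -0.5 are legal but rarely useful), ``top_k`` keeps the
    ``k`` best-scoring features of the whole level, which fixes the output
    dimensionality directly.
    """

    mode: str = "top_k"
    theta: float | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "threshold":
            if self.theta is None or self.k is not None:
                raise ValueError("threshold mode takes theta and no k")
            if not (-0.5 < self.theta <= 1.0):
                raise ValueError(f"theta must lie in (-0.5, 1], got {self.theta}")
        elif self.mode == "top_k":
            if self.k is None or self.theta is not None:
                raise ValueError("top_k mode takes k and no theta")
            if self.k < 0 or self.k != int(self.k):
                raise ValueError(f"k must be a non-negative integer, got {self.k}")
        else:
            raise ValueError(f"mode must be 'threshold' or 'top_k', got {self.mode!r}")


def select_unicorns(scores: ScoreSet, spec: SelectionSpec) -> set[str]:
    """Apply the selection strategy to one level's scores.

    Threshold selection is strict (score > theta; a score equal to theta is
    not selected). Top-k pools the whole level, breaking ties by descending
    score then lexicographic feature ID, so selection is deterministic.
    An empty selection is valid and means plain aggregation at this level.
    """
    if spec.mode == "threshold":
        return {r.feature for r in scores.records if r.unicor > spec.theta}
    ranked = sorted(scores.records, key=lambda r: (-r.unicor, r.feature))
    return {r.feature for r in ranked[: spec.k]}


@dataclasses.dataclass
class LevelState:
    """One level's artifacts plus the hierarchy as updated by its selection."""

    hierarchy: HierarchyTable
    matrix: FeatureMatrix  # aggregated, untransformed
    scores: ScoreSet
    selected: set[str]


def _quiet_tree(ht: HierarchyTable) -> TreeIndex:
    # propagation legitimately inflates upper-level node counts; silence
    # the structural warnings the initial validation already covered
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_tree(ht)


def propagate_level(
    ht: HierarchyTable,
    fm: FeatureMatrix,
    tv: TargetVariable,
    level: str,
    transform: TransformSpec = TransformSpec(),
    correlation: CorrelationSpec = CorrelationSpec(),
    selection: SelectionSpec = SelectionSpec(k=150),
) -> LevelState:
    """Score one level and promote its UNICORNs into the next level up.

    ``level`` must not be the most general level (there is nowhere to
    promote to). Returns the updated hierarchy together with the level's
    aggregated matrix, scores and selection.
    """
    levels = ht.level_names
    idx = levels.index(level)
    if idx == 0:
        raise DataError(f"cannot propagate from the most general level {level!r}")

    tree = _quiet_tree(ht)
    agg = aggregate_to_level(fm, tree, level)
    transformed = apply_transform(agg, transform)

    # parent groups: nodes of this level sharing their prefix at the level above
    groups: dict[str, list[str]] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    for node in tree.nodes_at[level]:
        parent = node[:-1]
        groups.setdefault(tree.display[parent], []).append(tree.display[node])
        lineages[tree.display[node]] = node

    scores = unicor_scores(
        transformed, tv, groups, correlation, level=level, lineages=lineages
    )
    selected = select_unicorns(scores, selection)

    new = ht.data.copy()
    parent_level = levels[idx - 1]
    depth = idx + 1  # path length of nodes at `level`
    for disp in selected:
        node = lineages[disp]
        member_mask = [
            tree.leaf_paths[str(c)][:depth] == node for c in new.columns
        ]
        new.loc[parent_level, member_mask] = node[-1]
    return LevelState(
        hierarchy=HierarchyTable(data=new),
        matrix=agg,
        scores=scores,
        selected=selected,
    )


@dataclasses.dataclass
class PropagationResult:
    """Full output of a bottom-up run: enriched hierarchy + per-level artifacts."""

    hierarchy: HierarchyTable
    level_matrices: dict[str, FeatureMatrix]  # aggregated, untransformed, per level
    score_sets: dict[str, ScoreSet]  # all levels except the most general
    unicorns: dict[str, list[str]]  # selected features per scored level
    config: dict


def unicorp_run(
    tv: TargetVariable,
    fm: FeatureMatrix,
    ht: HierarchyTable,
    transform: TransformSpec = TransformSpec(kind="relative_abundance"),
    correlation: CorrelationSpec = CorrelationSpec(method="spearman"),
    selection: SelectionSpec = SelectionSpec(k=150),
) -> PropagationResult:
    """Run the full bottom-up propagation from the leaf level to the top.

    Inputs must be aligned (identical sample sets, identical feature sets)
    and the hierarchy filled; the leaf matrix must be untransformed — each
    level is re-aggregated from the leaves and re-transformed, so
    transform distortions never compound across levels. Deterministic for
    identical inputs and specs, including tie cases.
    """
    if not fm.sample_ids.equals(tv.sample_ids):
        raise DataError("samples of feature matrix and target are not aligned")
    if list(map(str, fm.feature_ids)) != list(map(str, ht.feature_ids)):
        raise DataError("feature IDs of matrix and hierarchy differ")
    if fm.transform != "none":
        raise DataError("unicorp_run expects the untransformed leaf matrix")
    if ht.n_levels < 2:
        raise DataError("single-level hierarchy provides no exploitable information")

    build_tree(ht)  # upfront validation, with warnings

    levels = ht.level_names
    current = ht
    level_matrices: dict[str, FeatureMatrix] = {}
    score_sets: dict[str, ScoreSet] = {}
    unicorns: dict[str, list[str]] = {}
    for level in reversed(levels[1:]):  # leaf level up to just below the top
        state = propagate_level(
            current, fm, tv, level,
            transform=transform, correlation=correlation, selection=selection,
        )
        current = state.hierarchy
        level_matrices[level] = state.matrix
        score_sets[level] = state.scores
        unicorns[level] = sorted(state.selected)

    top = levels[0]
    level_matrices[top] = aggregate_to_level(fm, _quiet_tree(current), top)

    config = {
        "levels": levels,
        "transform": dataclasses.asdict(transform),
        "correlation": dataclasses.asdict(correlation),
        "selection": dataclasses.asdict(selection),
        "n_samples": int(fm.shape[0]),
        "n_leaf_features": int(fm.shape[1]),
        "unicorns_per_level": {k: len(v) for k, v in unicorns.items()},
        "target_name": tv.name,
    }
    return PropagationResult(
        hierarchy=current,
        level_matrices=level_matrices,
        score_sets=score_sets,
        unicorns=unicorns,
        config=config,
    )
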