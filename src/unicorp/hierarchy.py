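"""Strict-tree handling: annotation fill, lineage-path keying, aggregation.

A hierarchical annotation (e.g. a taxonomy from Kingdom down to ASV) is a
strict tree: every child has exactly one parent and node counts shrink
toward more general levels. Real taxonomies routinely violate naive
name-keying — the same genus name can occur under two families — so nodes
are identified by their full *lineage path* (the tuple of annotations from
the most general level down to the node). Identically named nodes under
different parents are therefore distinct, and display names only carry a
disambiguating suffix when two nodes at one level share a name.

Aggregation to a level sums the untransformed leaf columns of each node's
descendants, which conserves per-sample totals at every level.
"""

from __future__ import annotations

import dataclasses
import warnings

import pandas as pd

from .io_tabular import DataError, FeatureMatrix, HierarchyTable

__all__ = ["TreeIndex", "fill_missing", "build_tree", "aggregate_to_level"]

LineagePath = tuple[str, ...]


def fill_missing(ht: HierarchyTable, strategy: str = "leaf_id") -> HierarchyTable:
    """Fill empty annotation cells so the tree is unambiguous.

    Two conventions are supported:

    * ``"leaf_id"`` — every empty cell receives the feature's own (leaf)
      identifier, so unannotated ranks of an ASV are represented by the ASV
      itself at those levels;
    * ``"propagate_down"`` — every empty cell receives the nearest non-empty
      annotation from a more general level, so unannotated ranks inherit
      e.g. their family name.

    Empty cells in the leaf row are filled with the column's feature ID
    under both strategies (the leaf identifier is the feature ID).
    """
    if strategy not in ("leaf_id", "propagate_down"):
        raise ValueError(f"unknown fill strategy: {strategy!r}")
    df = ht.data.copy()
    leaf = df.index[-1]
    for feat in df.columns:
        if df.loc[leaf, feat] == "":
            if str(feat) == "":
                raise DataError("empty leaf annotation and no feature ID available")
            df.loc[leaf, feat] = str(feat)
    if strategy == "leaf_id":
        for feat in df.columns:
            col = df[feat]
            df[feat] = col.where(col != "", str(feat))
    else:
        for feat in df.columns:
            carry = ""
            col = df[feat].tolist()
            for i, val in enumerate(col):
                if val == "":
                    col[i] = carry if carry != "" else str(feat)
                else:
                    carry = val
            df[feat] = col
    return HierarchyTable(data=df)


@dataclasses.dataclass
class TreeIndex:
    """Lineage-path index over a filled hierarchy table.

    ``leaf_paths`` maps each feature ID to its full root-to-leaf path;
    ``nodes_at`` lists the distinct node paths per level in first-appearance
    order; ``display`` gives each node a unique per-level column label;
    ``m_gmax`` is the largest sibling-group size anywhere in the tree.
    """

    level_names: list[str]
    leaf_paths: dict[str, LineagePath]
    nodes_at: dict[str, list[LineagePath]]
    display: dict[LineagePath, str]
    node_counts: dict[str, int]
    m_gmax: int

    def members(self, level: str) -> dict[LineagePath, list[str]]:
        """Leaf feature IDs under each node at ``level``."""
        depth = self.level_names.index(level) + 1
        out: dict[LineagePath, list[str]] = {p: [] for p in self.nodes_at[level]}
        for feat, path in self.leaf_paths.items():
            out[path[:depth]].append(feat)
        return out

    def parent(self, node: LineagePath) -> LineagePath | None:
        return node[:-1] if len(node) > 1 else None


def build_tree(ht: HierarchyTable) -> TreeIndex:
    """Validate the tree property and index nodes by lineage path.

    Raises on empty annotation cells (fill first). Warns on a flat
    hierarchy (one child per parent everywhere — no exploitable grouping)
    and on node counts that fail to shrink toward more general levels
    (legitimate after propagation, suspicious in raw input).
    """
    df = ht.data
    if (df == "").any().any():
        bad = [c for c in df.columns if (df[c] == "").any()]
        raise DataError(f"hierarchy has empty annotations (run fill_missing): {bad[:5]}")

    levels = list(df.index)
    leaf_paths: dict[str, LineagePath] = {
        str(feat): tuple(df[feat].tolist()) for feat in df.columns
    }

    nodes_at: dict[str, list[LineagePath]] = {}
    for depth, level in enumerate(levels, start=1):
        seen: dict[LineagePath, None] = {}
        for path in leaf_paths.values():
            seen.setdefault(path[:depth])
        nodes_at[level] = list(seen)

    # unique per-level display names; suffix only on same-name collisions
    display: dict[LineagePath, str] = {}
    for level in levels:
        by_name: dict[str, list[LineagePath]] = {}
        for node in nodes_at[level]:
            by_name.setdefault(node[-1], []).append(node)
        for name, nodes in by_name.items():
            if len(nodes) == 1:
                display[nodes[0]] = name
            else:
                for node in nodes:
                    display[node] = f"{name}|{'/'.join(node[:-1])}"

    node_counts = {level: len(nodes_at[level]) for level in levels}

    # sibling-group sizes (children per parent); the top level has no parent
    # and is never scored, so it does not define a group
    group_sizes: list[int] = []
    for level in levels[1:]:
        sizes: dict[LineagePath, int] = {}
        for node in nodes_at[level]:
            sizes[node[:-1]] = sizes.get(node[:-1], 0) + 1
        group_sizes.extend(sizes.values())
    m_gmax = max(group_sizes) if group_sizes else node_counts[levels[0]]

    if len(levels) > 1 and m_gmax == 1:
        warnings.warn(
            "flat hierarchy (one child per parent everywhere) provides no "
            "exploitable grouping information",
            stacklevel=2,
        )
    for higher, lower in zip(levels[:-1], levels[1:]):
        if node_counts[higher] > node_counts[lower]:
            warnings.warn(
                f"node count increases toward the more general level {higher!r} "
                f"({node_counts[higher]} > {node_counts[lower]})",
                stacklevel=2,
            )
    return TreeIndex(
        level_names=levels,
        leaf_paths=leaf_paths,
        nodes_at=nodes_at,
        display=display,
        node_counts=node_counts,
        m_gmax=m_gmax,
    )


def aggregate_to_level(fm: FeatureMatrix, tree: TreeIndex, level: str) -> FeatureMatrix:
    """Sum leaf columns up to the nodes of ``level``.

    Requires untransformed values: aggregation always happens on raw
    quantities, transforms are applied afterwards per level.
    """
    if fm.transform != "none":
        raise DataError("aggregate_to_level requires untransformed values")
    if level not in tree.nodes_at:
        raise DataError(f"level {level!r} not in hierarchy {tree.level_names}")
    members = tree.members(level)
    data = {tree.display[node]: fm.data[feats].sum(axis=1) for node, feats in members.items()}
    out = pd.DataFrame(data, index=fm.data.index)
    # preserve first-appearance node order
    out = out[[tree.display[n] for n in tree.nodes_at[level]]]
    return FeatureMatrix(data=out, transform="none")
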