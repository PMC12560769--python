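"""Reading, validation and writing of the three tabular inputs.

The tool consumes three delimited text files:

* a continuous target variable (``n`` samples x 1 column),
* a quantitative feature matrix (``n`` samples x ``m`` features, e.g. an
  ASV count table),
* a hierarchical annotation table (``l`` levels x ``m`` features of text
  annotations, e.g. a taxonomy from Kingdom down to ASV).

All three are wrapped in light dataclasses around pandas objects so that
invariants (unique IDs, non-negativity, matching feature sets) are checked
once at the boundary and the rest of the package can rely on them.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .propagation import PropagationResult

__all__ = [
    "TargetVariable",
    "FeatureMatrix",
    "HierarchyTable",
    "AlignedInputs",
    "read_target",
    "read_features",
    "read_hierarchy",
    "align_inputs",
    "write_outputs",
]


class DataError(ValueError):
    """Raised when an input file or table violates the data contract."""


@dataclasses.dataclass
class TargetVariable:
    """Continuous per-sample target, e.g. a coral thermal-tolerance ED50 or SST.

    ``values`` is a pandas Series indexed by sample ID.
    """

    values: pd.Series
    name: str = "target"

    def __post_init__(self) -> None:
        s = self.values
        if s.index.has_duplicates:
            dups = s.index[s.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs in target: {dups}")
        if len(s) < 3:
            raise DataError(f"target needs at least 3 samples, got {len(s)}")
        arr = s.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = s.index[~np.isfinite(arr)].tolist()
            raise DataError(f"non-finite target values for samples: {bad}")
        if np.ptp(arr) == 0:
            raise DataError("target has no variance (all values identical)")
        self.values = s.astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return len(self.values)


@dataclasses.dataclass
class FeatureMatrix:
    """Samples x features table of non-negative quantities (counts or abundances).

    ``transform`` records which per-sample transformation has been applied
    ("none", "relative_abundance" or "clr"); transformed matrices may contain
    negative values (CLR) and are never transformed twice.
    """

    data: pd.DataFrame
    transform: str = "none"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs in feature matrix: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature IDs in feature matrix: {dups}")
        if df.shape[1] < 1:
            raise DataError("feature matrix has no features")
        if df.shape[0] < 3:
            raise DataError(
                f"feature matrix needs at least 3 samples, got {df.shape[0]}"
            )
        self.data = df.astype(float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclasses.dataclass
class HierarchyTable:
    """Levels x features table of text annotations, most-general level first.

    Row order is normalised at read time, so ``data.index[0]`` is always the
    most general level (e.g. Kingdom) and ``data.index[-1]`` the leaf level
    (e.g. ASV). Empty cells are allowed until :func:`unicorp.hierarchy.fill_missing`
    has been applied.
    """

    data: pd.DataFrame  # str dtype; "" marks a missing annotation

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise DataError("hierarchy table is empty")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(
                "duplicate hierarchy level rows (a feature would have two "
                f"parents at one level): {dups}"
            )
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature IDs in hierarchy: {dups}")
        self.data = df.fillna("").astype(str)

    @property
    def level_names(self) -> list[str]:
        """Level names ordered most-general first."""
        return list(self.data.index)

    @property
    def n_levels(self) -> int:
        return self.data.shape[0]

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def leaf_level(self) -> str:
        return self.data.index[-1]


def _check_unique_header(path: str | Path, sep: str) -> None:
    """pandas silently de-duplicates header names; inspect the raw header row."""
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    names = header[1:]  # first column is the index
    if len(set(names)) != len(names):
        seen, dups = set(), []
        for n in names:
            if n in seen:
                dups.append(n)
            seen.add(n)
        raise DataError(f"duplicate column IDs in {path}: {sorted(set(dups))}")


def read_target(path: str | Path, sep: str = ",", name: str | None = None) -> TargetVariable:
    """Read the continuous target variable (one index column + one value column)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] != 1:
        raise DataError(
            f"target file must have exactly one value column, got {df.shape[1]}"
        )
    col = df.iloc[:, 0]
    numeric = pd.to_numeric(col, errors="coerce")
    bad = col.index[numeric.isna()].tolist()
    if bad:
        raise DataError(f"non-numeric or missing target values for samples: {bad}")
    return TargetVariable(values=numeric, name=name or str(df.columns[0]))


def read_features(path: str | Path, sep: str = ",") -> FeatureMatrix:
    """Read the quantitative feature matrix; absent cells are zero abundance."""
    _check_unique_header(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce").fillna(0.0)
    if (df.to_numpy() < 0).any():
        cols = df.columns[(df < 0).any(axis=0)].tolist()
        raise DataError(f"negative values in feature columns: {cols}")
    return FeatureMatrix(data=df, transform="none")


def read_hierarchy(
    path: str | Path,
    sep: str = ",",
    level_order: str = "general_first",
) -> HierarchyTable:
    """Read the hierarchical annotation table.

    ``level_order`` declares how the file lists its rows: ``"general_first"``
    (Kingdom on the first row) or ``"specific_first"`` (leaf level first).
    The in-memory representation is always most-general-first.
    """
    if level_order not in ("general_first", "specific_first"):
        raise ValueError(f"unknown level_order: {level_order!r}")
    _check_unique_header(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if level_order == "specific_first":
        df = df.iloc[::-1]
    return HierarchyTable(data=df)


@dataclasses.dataclass
class AlignedInputs:
    """Result of :func:`align_inputs`: a consistent (target, features, hierarchy)."""

    target: TargetVariable
    features: FeatureMatrix
    hierarchy: HierarchyTable
    dropped_samples: list = dataclasses.field(default_factory=list)
    dropped_features: list = dataclasses.field(default_factory=list)
    dropped_zero_features: list = dataclasses.field(default_factory=list)

    def __iter__(self):
        return iter((self.target, self.features, self.hierarchy))


def align_inputs(
    tv: TargetVariable,
    fm: FeatureMatrix,
    ht: HierarchyTable,
    mode: str = "strict",
) -> AlignedInputs:
    """Bring the three inputs onto identical sample and feature sets.

    ``strict`` (default) raises on any mismatch; ``intersect`` inner-joins
    samples (target vs features) and features (features vs hierarchy),
    recording what was dropped. In both modes feature columns that are all
    zero over the retained samples are removed, mirroring the usual removal
    of taxa without abundance in a sample subset.
    """
    if mode not in ("strict", "intersect"):
        raise ValueError(f"unknown align mode: {mode!r}")

    t_samples = tv.sample_ids
    f_samples = fm.sample_ids
    sample_mismatch = set(t_samples).symmetric_difference(f_samples)
    dropped_samples: list = []
    if sample_mismatch:
        if mode == "strict":
            raise DataError(
                f"sample IDs differ between target and features: {sorted(sample_mismatch)}"
            )
        common = t_samples.intersection(f_samples)
        if len(common) == 0:
            raise DataError("no samples shared between target and features")
        dropped_samples = sorted(sample_mismatch)
        # keep feature-matrix row order for the surviving samples
        common = f_samples[f_samples.isin(common)]
    else:
        common = f_samples

    feat_mismatch = set(fm.feature_ids).symmetric_difference(ht.feature_ids)
    dropped_features: list = []
    if feat_mismatch:
        if mode == "strict":
            raise DataError(
                f"feature IDs differ between features and hierarchy: {sorted(feat_mismatch)}"
            )
        keep = fm.feature_ids.intersection(ht.feature_ids)
        if len(keep) == 0:
            raise DataError("no features shared between feature matrix and hierarchy")
        dropped_features = sorted(feat_mismatch)
    else:
        keep = fm.feature_ids

    fdata = fm.data.loc[common, keep]
    tvals = tv.values.loc[common]

    nonzero = fdata.columns[(fdata != 0).any(axis=0)]
    dropped_zero = [c for c in fdata.columns if c not in set(nonzero)]
    fdata = fdata[nonzero]
    if fdata.shape[1] == 0:
        raise DataError("all feature columns are zero after alignment")

    return AlignedInputs(
        target=TargetVariable(values=tvals, name=tv.name),
        features=FeatureMatrix(data=fdata, transform=fm.transform),
        hierarchy=HierarchyTable(data=ht.data[fdata.columns]),
        dropped_samples=dropped_samples,
        dropped_features=dropped_features,
        dropped_zero_features=dropped_zero,
    )


def write_outputs(result: "PropagationResult", out_dir: str | Path) -> dict[str, str]:
    """Write all per-level artifacts of a propagation run.

    Produces, per hierarchy level, the aggregated feature matrix and (where
    computed) the score table; plus the enriched hierarchy in the same
    levels x features layout the reader consumes, and a JSON run report.
    Returns a manifest mapping artifact names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    for level, fm in result.level_matrices.items():
        p = out / f"matrix_{level}.csv"
        fm.data.to_csv(p)
        manifest[f"matrix_{level}"] = str(p)
    for level, scores in result.score_sets.items():
        p = out / f"scores_{level}.csv"
        selected = set(result.unicorns.get(level, []))
        scores.to_frame(selected=selected).to_csv(p, index=False)
        manifest[f"scores_{level}"] = str(p)

    p = out / "hierarchy_enriched.csv"
    result.hierarchy.data.to_csv(p)
    manifest["hierarchy_enriched"] = str(p)

    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(result.config, fh, indent=2, default=str)
    manifest["report"] = str(p)
    return manifest
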