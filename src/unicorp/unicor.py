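"""The UniCor metric: uniqueness-weighted feature-target correlation.

For a feature *i* inside a sibling group *G* (e.g. the species of one
genus), with feature-target correlation ``fcc_i`` and feature-feature
correlations ``ffc_i`` to the other members of *G*::

    UniCor(i) = (|fcc_i| - mean(ffc_i)) / 2

The absolute target correlation lies in [0, 1] and the mean sibling
correlation in [-1, 1], so the score is bounded in [-1/2, 1]. High scores
mark features that track the target while being unlike their siblings —
non-redundant predictors. Scoring within sibling groups (rather than
against the full feature set) keeps the mean sibling correlation
informative in wide, sparse matrices, where a global mean would converge
to the same value for every feature.

Pearson and Spearman (average ranks for ties) correlations are supported.
Constant vectors have no defined correlation; by convention they correlate
0 with everything, which keeps dead columns inside the score bounds
instead of aborting a run.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_tabular import DataError, FeatureMatrix, TargetVariable

__all__ = ["CorrelationSpec", "ScoreRecord", "ScoreSet", "correlate", "unicor_scores"]

_METHODS = ("pearson", "spearman")


@dataclasses.dataclass(frozen=True)
class CorrelationSpec:
    method: str = "spearman"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")


@dataclasses.dataclass
class ScoreRecord:
    """UniCor score of one feature node within its parent group."""

    feature: str
    lineage: tuple[str, ...]
    parent_group: str
    abs_fcc: float
    mean_ffc: float

    @property
    def unicor(self) -> float:
        return (self.abs_fcc - self.mean_ffc) / 2.0


@dataclasses.dataclass
class ScoreSet:
    """All score records of one hierarchical level."""

    level: str
    records: list[ScoreRecord]
    method: str
    transform: str

    def to_frame(self, selected: set[str] | None = None) -> pd.DataFrame:
        rows = [
            {
                "feature_id": r.feature,
                "lineage_path": "/".join(r.lineage),
                "parent_group": r.parent_group,
                "abs_fcc": r.abs_fcc,
                "mean_ffc": r.mean_ffc,
                "unicor": r.unicor,
                "selected": r.feature in selected if selected is not None else False,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "feature_id", "lineage_path", "parent_group",
                "abs_fcc", "mean_ffc", "unicor", "selected",
            ],
        )

    def scores(self) -> dict[str, float]:
        return {r.feature: r.unicor for r in self.records}


def _corr_matrix(cols: np.ndarray, method: str) -> np.ndarray:
    """Pairwise correlations of the columns of ``cols`` (n x p).

    Constant columns get correlation 0 with every other column (and 1 with
    themselves), per the package convention.
    """
    if method == "spearman":
        cols = np.apply_along_axis(stats.rankdata, 0, cols)
    sd = cols.std(axis=0)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(cols, rowvar=False)
    corr = np.atleast_2d(corr)
    if const.any():
        corr[const, :] = 0.0
        corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.nan_to_num(corr, nan=0.0)
    return np.clip(corr, -1.0, 1.0)


def correlate(x, y, spec: CorrelationSpec = CorrelationSpec()) -> float:
    """Correlation between two vectors; 0 by convention if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DataError(f"need at least 3 observations, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant vector in correlation; returning 0", stacklevel=2)
        return 0.0
    return float(_corr_matrix(np.column_stack([x, y]), spec.method)[0, 1])


def unicor_scores(
    fm_level: FeatureMatrix,
    tv: TargetVariable,
    groups: dict[str, list[str]],
    spec: CorrelationSpec = CorrelationSpec(),
    level: str = "",
    lineages: dict[str, tuple[str, ...]] | None = None,
) -> ScoreSet:
    """Score every feature of a level within its parent group.

    ``groups`` maps each parent-group label to the feature columns it
    contains; the groups must partition ``fm_level``'s columns. Sibling
    correlations are computed inside each group only, so a feature's score
    is local to its group. A feature with no siblings (singleton group)
    gets a neutral mean sibling correlation of 0, i.e. its score is half
    its absolute target correlation.
    """
    if not fm_level.sample_ids.equals(tv.sample_ids):
        raise DataError("samples of feature matrix and target are not aligned")
    y = tv.values.to_numpy()
    if y.std() == 0:
        raise DataError("target has no variance")

    grouped = [f for feats in groups.values() for f in feats]
    if sorted(grouped) != sorted(map(str, fm_level.feature_ids)) or len(grouped) != len(
        set(grouped)
    ):
        raise DataError("groups do not partition the level's features")

    records: list[ScoreRecord] = []
    for parent, feats in groups.items():
        cols = fm_level.data[feats].to_numpy()
        mat = _corr_matrix(np.column_stack([cols, y]), spec.method)
        j = len(feats)
        for i, feat in enumerate(feats):
            abs_fcc = abs(mat[i, j])
            if j == 1:
                mean_ffc = 0.0
            else:
                mean_ffc = float((mat[i, :j].sum() - mat[i, i]) / (j - 1))
            records.append(
                ScoreRecord(
                    feature=str(feat),
                    lineage=(lineages or {}).get(str(feat), (str(feat),)),
                    parent_group=str(parent),
                    abs_fcc=float(abs_fcc),
                    mean_ffc=mean_ffc,
                )
            )
    return ScoreSet(level=level, records=records, method=spec.method, transform=fm_level.transform)
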