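"""Per-sample compositional transforms applied before correlation scoring.

Abundance data from marker-gene sequencing are compositional: only relative
information is meaningful, and library sizes vary across samples. Two
standard remedies are supported, besides using raw values:

* **relative abundance** — divide each sample row by its total, giving
  proportions that sum to 1;
* **centered log-ratio (CLR)** — per sample, log of each component minus
  the mean log, mapping the simplex to real space with rows summing to 0.
  Zeros are handled with an additive pseudocount (default 1) before the log.

Transforms are always recomputed on a level's aggregated raw values, never
by aggregating transformed values (sums of CLR values are not the CLR of
sums).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_tabular import DataError, FeatureMatrix

__all__ = ["TransformSpec", "to_relative_abundance", "clr_transform", "apply_transform"]

_KINDS = ("none", "relative_abundance", "clr")


@dataclasses.dataclass(frozen=True)
class TransformSpec:
    kind: str = "none"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"transform kind must be one of {_KINDS}, got {self.kind!r}")
        if self.pseudocount <= 0:
            raise ValueError(f"pseudocount must be positive, got {self.pseudocount}")


def to_relative_abundance(fm: FeatureMatrix) -> FeatureMatrix:
    """Normalise each sample row to proportions summing to 1."""
    values = fm.data.to_numpy()
    if (values < 0).any():
        raise DataError("relative abundance requires non-negative values")
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = fm.sample_ids[zero].tolist()
        raise DataError(f"samples with zero total abundance cannot be normalised: {bad}")
    out = fm.data.div(totals, axis=0)
    return FeatureMatrix(data=out, transform="relative_abundance")


def clr_transform(fm: FeatureMatrix, pseudocount: float = 1.0) -> FeatureMatrix:
    """Centered log-ratio: log(x + pseudocount) minus the per-sample mean log."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if (fm.data.to_numpy() < 0).any():
        raise DataError("CLR requires non-negative values")
    logged = np.log(fm.data.to_numpy() + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    out = fm.data.copy()
    out.loc[:, :] = centered
    return FeatureMatrix(data=out, transform="clr")


def apply_transform(fm: FeatureMatrix, spec: TransformSpec) -> FeatureMatrix:
    """Dispatch on ``spec.kind``; refuses to transform an already-transformed matrix."""
    if fm.transform != "none":
        raise DataError(
            f"matrix already carries transform {fm.transform!r}; transforms are not stacked"
        )
    if spec.kind == "none":
        return fm
    if spec.kind == "relative_abundance":
        return to_relative_abundance(fm)
    return clr_transform(fm, spec.pseudocount)
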