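"""Seedable generator of sparse, wide, hierarchically annotated count data.

Emulates the shape of marker-gene community matrices: many leaf features
(ASV-like), few samples, zero-inflated long-tailed counts, and a strict
taxonomy tree. Optionally *plants* leaves with a prescribed rank
correlation to the continuous target — ground-truth UNICORNs whose
recovery through the hierarchy can be measured.

Count model: per-leaf log-normal abundances (per-feature location drawn
from a normal, giving the long tail across taxa) with a shared per-group
latent factor controlling sibling correlation, thinned by independent
zero-inflation, rounded to integer counts.

Planted leaves are built on a latent Gaussian coupled to the target with
loading ``2*sin(pi*rho/6)`` — the bivariate-normal inverse of Spearman's
rho — then mapped to positive counts by an affine (hence monotone) map,
so the realised Spearman correlation approximates the requested rho and
the Pearson correlation is close to it as well. Planted leaves are not
zero-inflated (zero ties would erode the planted signal).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from .io_tabular import DataError, FeatureMatrix, HierarchyTable, TargetVariable

__all__ = ["GeneratorSpec", "make_hierarchy", "make_dataset"]


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    ``branching`` gives children per node from the top level downward;
    the leaf count is its product and the number of levels is
    ``len(branching) + 1``. ``planted`` maps leaf IDs (``ASV0001``, ...)
    to target rank correlations.
    """

    n_samples: int = 100
    branching: tuple[int, ...] = (4, 4, 4, 4)
    log_mean: float = math.log(50.0)
    log_sd: float = 1.5
    mu_sd: float = 1.5
    zero_inflation: float = 0.6
    sibling_correlation: float = 0.3
    planted: dict[str, float] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if len(self.branching) < 1 or any(b < 1 for b in self.branching):
            raise ValueError(f"branching factors must be >= 1, got {self.branching}")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError(f"zero_inflation must be in [0, 1), got {self.zero_inflation}")
        if not 0 <= self.sibling_correlation < 1:
            raise ValueError(
                f"sibling_correlation must be in [0, 1), got {self.sibling_correlation}"
            )
        for leaf, rho in self.planted.items():
            if not -1 < rho < 1:
                raise ValueError(f"planted rho for {leaf} must be in (-1, 1), got {rho}")

    @property
    def n_levels(self) -> int:
        return len(self.branching) + 1

    @property
    def n_leaves(self) -> int:
        return int(np.prod(self.branching))


def make_hierarchy(spec: GeneratorSpec) -> HierarchyTable:
    """Build the strict tree: one row per level (most general first).

    Internal node names encode their index path (``n0``, ``n0.1``, ...),
    so annotations are unique per lineage path; leaves are ``ASV0001`` etc.
    """
    L = spec.n_levels
    level_names = [f"level_{i}" for i in range(1, L + 1)]
    n_leaves = spec.n_leaves
    leaf_ids = [f"ASV{i + 1:04d}" for i in range(n_leaves)]

    rows: list[list[str]] = []
    for depth in range(1, L):
        n_nodes = int(np.prod(spec.branching[:depth]))
        leaves_per_node = n_leaves // n_nodes
        ann = []
        for node_idx in range(n_nodes):
            # index path of this node, e.g. n0.2.1
            path, rem = [], node_idx
            for b in reversed(spec.branching[:depth]):
                path.append(rem % b)
                rem //= b
            name = "n" + ".".join(str(p) for p in reversed(path))
            ann.extend([name] * leaves_per_node)
        rows.append(ann)
    rows.append(leaf_ids)

    if all(b == 1 for b in spec.branching):
        warnings.warn(
            "flat hierarchy (branching all 1) provides no exploitable grouping",
            stacklevel=2,
        )
    df = pd.DataFrame(rows, index=level_names, columns=leaf_ids)
    return HierarchyTable(data=df)


def make_dataset(
    spec: GeneratorSpec,
) -> tuple[FeatureMatrix, TargetVariable, HierarchyTable]:
    """Draw one dataset (features, target, hierarchy) for the given conditions."""
    ht = make_hierarchy(spec)
    leaf_ids = list(ht.feature_ids)
    unknown = [leaf for leaf in spec.planted if leaf not in set(leaf_ids)]
    if unknown:
        raise DataError(f"planted leaves not present in the hierarchy: {unknown}")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    y = rng.normal(0.0, 1.0, size=n)
    y_std = (y - y.mean()) / y.std()

    # siblings share a latent factor scaled by sibling_correlation; group by
    # the most specific level that actually groups (the row just above the
    # leaves names each leaf uniquely, so it induces no sharing)
    parent_row = pd.Series("root", index=leaf_ids)
    for i in range(ht.n_levels - 2, -1, -1):
        row = ht.data.iloc[i]
        if row.nunique() < len(leaf_ids):
            parent_row = row
            break
    group_latent = {g: rng.normal(0.0, 1.0, size=n) for g in dict.fromkeys(parent_row)}

    sc = spec.sibling_correlation
    counts = np.empty((n, len(leaf_ids)))
    mus = rng.normal(spec.log_mean, spec.mu_sd, size=len(leaf_ids))
    for j, leaf in enumerate(leaf_ids):
        eps = rng.normal(0.0, 1.0, size=n)
        if leaf in spec.planted:
            rho = spec.planted[leaf]
            loading = 2.0 * math.sin(math.pi * rho / 6.0)
            u = loading * y_std + math.sqrt(1.0 - loading**2) * eps
            # log-scale (monotone) map with the community's dispersion: the
            # planted leaf's variation spans orders of magnitude, so its
            # signal survives per-sample normalisation against the
            # heavy-tailed total; no zero-inflation (zero ties erode rho)
            counts[:, j] = np.round(np.exp(math.log(500.0) + spec.log_sd * u))
        else:
            u = sc * group_latent[parent_row.iloc[j]] + math.sqrt(1.0 - sc**2) * eps
            col = np.round(np.exp(mus[j] + spec.log_sd * u))
            if spec.zero_inflation > 0:
                col = col * (rng.random(n) >= spec.zero_inflation)
            counts[:, j] = col

    fm = FeatureMatrix(
        data=pd.DataFrame(counts, index=[f"S{i + 1:03d}" for i in range(n)], columns=leaf_ids),
        transform="none",
    )
    tv = TargetVariable(
        values=pd.Series(y, index=fm.sample_ids, name="target"), name="target"
    )
    return fm, tv, ht
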