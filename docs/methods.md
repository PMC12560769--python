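# Methods

## Model and assumptions

The package operates on three tables: a continuous target `y ∈ ℝⁿ`, a
non-negative feature matrix `X ∈ ℝⁿˣᵐ` (counts or abundances), and a strict
tree hierarchy `H = {H₁ … H_L}` over the `m` leaf features (one row of text
annotations per level). Strictness means every child has exactly one parent;
DAG-shaped annotations (KEGG/GO-style multiple parenthood) are rejected —
they cannot be encoded in the `l × m` table form consumed here, which is
exactly the structural guarantee the algorithm relies on. Flat hierarchies
(one child per parent throughout) are accepted with a warning: they carry no
exploitable grouping information.

The score of feature *i* within its sibling group *G* is

    UniCor(i) = (|fcc_i| − mean_ffc_i) / 2,

with `fcc_i = corr(x_i, y)` and `mean_ffc_i` the average of `corr(x_i, x_j)`
over the other members of *G*. Since `|fcc| ∈ [0, 1]` and
`mean_ffc ∈ [−1, 1]`, the score lies in `[−1/2, 1]`. Grouping matters: over a
large flat feature set the mean feature–feature correlation converges to the
same value for every feature and the uniqueness term loses discrimination;
sibling groups keep it local and informative.

Propagation iterates levels `l = 1 … L−1` (most specific first): aggregate
raw leaves to level *l* via the current hierarchy, transform, score within
parent groups at level *l+1*, select, and set the selected nodes' parent
annotation to themselves. A promoted node keeps its original ancestry above
the level it enters, is re-scored there among its former parent's siblings,
and may be promoted repeatedly. No scoring pass happens at level L itself
(there is nowhere left to promote), so score tables exist for levels
1 … L−1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| correlation method | `spearman` | rank-based; robust for sparse, tie-heavy, non-normal counts. `pearson` for linear signals. |
| transform | `relative_abundance` | per-sample proportions; `clr` (centered log-ratio) or `none` also supported. |
| CLR pseudocount | 1.0 | added before the log; exposed because zero handling is a convention, not a fact. |
| selection | `top_k`, k = 150 | direct control of feature-set size; applied per level, pooled across groups. |
| threshold θ | 0.15 (when used) | strict comparison (`score > θ`); useful range 0–1, legal down to −0.5. |
| fill strategy | `leaf_id` | empty annotation cells get the feature's own ID; `propagate_down` copies the nearest more general name instead. |

Numerical conventions, fixed for reproducibility:

- Correlations are computed in double precision via the per-group
  correlation matrix; Spearman uses average ranks for ties.
- A constant vector correlates 0 with everything (undefined in theory;
  0 keeps dead columns inside the score bounds instead of aborting).
- A singleton group has `mean_ffc = 0`: a lone child is neither rewarded nor
  penalised for uniqueness.
- Top-k ties at the k-th rank break by descending score, then lexicographic
  feature ID — deterministic across runs.
- Threshold comparison applies no tolerance (strict `>`; a score equal to θ
  is not selected).
- Nodes are keyed by their full lineage path, so identically named taxa
  under different parents are distinct nodes; display names gain a
  `name|path` suffix only when two nodes at one level share a name.
- Aggregation always sums *untransformed* leaf values, and the transform is
  re-applied per level: sums of CLR values are not the CLR of sums, and
  re-deriving every level from the leaves prevents transform distortions
  from compounding.

Degenerate inputs: constant targets, single-level hierarchies, zero-total
samples under relative abundance, and non-positive pseudocounts are hard
errors; all-zero feature columns are dropped (and counted) at alignment.

## Synthetic data

The generator emulates the shape of ASV community matrices: leaf counts are
zero-inflated log-normals whose per-feature location is itself normal
(giving the long tail — few abundant taxa, many rare), with a per-group
latent factor scaled by `sibling_correlation`, under a strict tree with
configurable branching. Defaults: 100 samples, branching 4×4×4×4
(256 leaves, 5 levels), zero-inflation 0.6, log-location `log 50` with
spread 1.5, log-scale 1.5, sibling correlation 0.3 — a desk-scale analogue
of the sparse, wide tables the method targets.

Planted leaves couple a latent Gaussian to the target with loading
`2·sin(πρ/6)` — the bivariate-normal inverse of Spearman's ρ — and map it to
counts through an exponential (monotone) curve with the community's log
dispersion, without zero-inflation. The monotone map preserves the requested
Spearman correlation exactly in the latent limit; the realised Pearson
correlation on the count scale is positive but attenuated (the exponential
stretches the upper tail). Planting on the log scale is deliberate: the
planted leaf's variation spans orders of magnitude, so its rank signal
survives per-sample normalisation against the heavy-tailed community total,
as a genuinely associated taxon's relative abundance does in real data.

What the generator does **not** emulate: phylogenetic signal in abundances,
batch effects, variable sequencing depth, longitudinal structure, and
compositional negative correlation bias. Passing recovery tests therefore
shows the algorithm finds uniquely correlated leaves under idealised
sparsity and grouping — not that it is robust to those real-data effects.

## Evaluation harness

`joint_cv` fits both the propagation and the regressor inside each training
fold; the fold's enriched hierarchy is applied to held-out samples only as
an aggregation recipe over leaf columns. This avoids the selection leakage
that inflates scores when features are chosen on the full dataset.
R² and MSE are pooled over all held-out predictions (one global sum of
squares) — per-fold R² is undefined for leave-one-out folds of size one, so
pooling is used uniformly for every scheme. Two pipelines exist: the
regressor sees the transformed enriched matrix, or the raw aggregated
counts (tree ensembles often prefer the latter). The regressor is an
injection point (`fit`/`predict`); the reference configuration in the
examples is a random forest with 100 trees and seed 42.

`paired_gain_stats` summarises (baseline, enriched) R² pairs: mean and
sample SD of the gains, a one-sided paired t-test for mean gain > 0, and a
seeded percentile bootstrap 95% CI of the mean gain. Zero-variance gains are
reported as degenerate (t undefined) rather than as an error.

## Problem sizes used in the checks

The recovery experiments run 100 generator seeds at n = 100 samples,
256 leaves, one leaf planted at ρ = 0.9 among independent siblings,
threshold 0.15; the paired cross-validated comparison uses 20 seeds with
5-fold CV and the 100-tree reference forest. These sizes exercise the full
propagation depth while keeping the whole suite runnable on a laptop core
in a few minutes.

## Known limitations

- No statistical significance or false-discovery control is attached to the
  scores; rare taxa can score high by chance correlation. The score ranks
  candidates, it does not test them.
- Hierarchy levels are processed as given; uneven information content across
  levels (e.g. mostly-unannotated intermediate ranks) is handled only through
  the fill strategies.
- `top_k` with very small k can drop a group's only informative member at a
  higher level if a stronger feature exists elsewhere on the level — pooled
  selection trades per-group guarantees for global dimensionality control.
- The propagation is greedy and level-local: a feature unremarkable at its
  own level but informative two levels up will not be found.
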