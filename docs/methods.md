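# Methods

## Model and procedure

The integration model assumes every dataset measures a (noisy, linear) view
of the same underlying cell-state space. One or more datasets act as
references; each reference's decomposition defines a coordinate block of the
joint embedding.

**Mosaic data topology.** Datasets are nodes; an edge joins two datasets
sharing at least one feature name, weighted by the exact shared count.
Feature matching is exact string equality — no identifier translation (e.g.
peak-to-gene) is attempted, so whether chromatin peaks "are" genes is the
caller's explicit preprocessing decision. Integration requires the graph to
be connected; `assert_connected` reports the components otherwise.

**Path cost.** Shortest paths minimize the sum of `1 / n_shared` over
edges, so routes through large feature overlaps are preferred: more shared
predictors give better-conditioned regression bridges. Costs are computed
in exact rational arithmetic, so equal-cost alternatives are recognized
exactly; ties are broken by hop count, then by lexicographic node order.
This makes every embedding bit-reproducible for a given input order.

**Reference decomposition.** PCA on feature-centered data (all of the
reference's features; default 50 components, capped at
`min(requested, n_features, n_cells − 1)`). When labels cover the reference,
LDA is used instead, capped additionally at `n_classes − 1`; the
discriminants come from the generalized eigenproblem of between- versus
within-class scatter, the latter ridge-regularized by `1e-8 ×` its mean
diagonal so that scatter singularity (features > cells) degrades gracefully.
An existing decomposition (e.g. from a vertical integration method) can be
supplied directly via `make_user_reference`.

**Projection.** A dataset holding every loading feature is projected as
`(X − mean)^T A`. Otherwise each score column is regressed on the shared
feature panel by OLS. Every bridge includes an intercept, and direct
projection centers by the stored reference feature means: the scores live
in a centered space while query features have arbitrary means, and the
intercept is what makes the bridge reproduce direct projection exactly in
the full-overlap case (a tested invariant). Rank-deficient panels (shared
features ≥ cells, or collinear features) fall back to the minimum-norm
least-squares solution with a warning rather than failing — small shared
panels are the norm in mosaic settings. Multi-hop projection refits a
bridge at each hop from the previous node's *estimated* scores; an
intermediate node holding the full loading panel is projected directly.

**Multiple references.** Per-reference score blocks are divided by their
own matrix L1 norm (sum of absolute entries), multiplied by the
user weight `w_j ∈ [0, 1]` (default 1), and concatenated column-wise, so
equally weighted blocks contribute equally to Euclidean distances. An L2
(Frobenius) variant is available via `reweight_norm="l2"`; the choice of
norm only rescales blocks and does not change within-block geometry.

## Downstream analysis

Label transfer and imputation are k-nearest-neighbor operations under
Euclidean distance in the embedding. Neighbor search is brute-force with
deterministic tie handling (distance, then cell order); imputation averages
the k nearest reference cells' original feature vectors (default k = 5,
matching classification — the choice is exposed). Vote ties in
classification go to the nearest neighbor among the tied classes.

Integration quality metrics operate on matched two-layer embeddings:
per-cell Jaccard overlap of within-layer k-NN sets (default k = 100,
self excluded, opposite-layer identities mapped through the matching), and
the number-of-nearest-cells statistic `N_i2` = number of opposite-layer
cells at distance ≤ the matched partner's distance. The `≤` means the
partner always counts itself, so `N_i2 ≥ 1` and its ideal value is 1; the
cumulative curve `M(x)` counts cells with `N_i2 ≤ x`.

## Spatial features and enrichment test

`neighbor_mean_features` computes, per gene and cell, the mean expression
over cells within `max_steps` hops (default 2) of the spatial neighbor
graph, excluding the cell itself; isolated cells keep their own value so
the derived feature stays defined. When only coordinates are given, the
graph is a symmetrized k-NN graph (default k = 6, a typical planar packing
density). The derived features are suffixed and intended to be concatenated
with the measured panel before integration, giving spatially resolved cells
features that dissociated data cannot have.

The local enrichment test asks, for each query cell, whether
lineage-labeled (td-Tomato+) cells of perturbed samples are locally over- or
under-represented around it. Among each biological sample's `n` nearest
cells in the embedding (default 1000), the labeled fraction is the response
of a binomial GLM, `logit(p) = β0 + β1·x1 + β2·x2`, with `x1` the
sample-wide labeled fraction (injection-efficiency control, constant per
sample) and `x2` the genotype indicator. Neighborhood sizes enter as
binomial weights so equally sized replicates are exchangeable. Significance
of `β2` comes from a likelihood-ratio test against the model without `x2`
(χ², 1 df); failed or separated fits carry missing p-values and are
excluded from the Benjamini–Hochberg adjustment across query cells. With a
handful of samples the LRT is asymptotic; simulation at the default
neighborhood size shows type-I error close to nominal (≈0.05).

## Synthetic data

The generator draws cell latent positions from a mixture of spherical
Gaussians (one component per cell type; centers scaled by
`type_separation`, default 3, in units of within-type spread), maps them
through a fixed loading matrix (`N(0, 1/latent_dim)` entries) and adds iid
Gaussian noise (`noise_sd`, default 0.3). Each dataset observes only its
feature panel, so panel intersections — and hence the MDT — are controlled
exactly. Because the generative map is linear, noiseless draws make the
projection algebra exactly recoverable, which is what gives the sharp
oracle tests. An `informative_fraction < 1` silences the loadings of the
remaining features, emulating uninformative probes, and a
negative-binomial count option with library-size log-normalization provides
count-like marginals.

Scenario builders reproduce three stress designs at desk scale: a
reference/query split where the query keeps a random feature subset (down
to 50 features); a three-way split of a two-modality collection into
modality-1-only, multi-modal bridge, and modality-2-only datasets with no
features shared between the ends; and a chain of eight datasets whose
windows of the feature pool overlap ~50% between neighbors only, making the
MDT a path graph — the hardest routing case.

What the generator does *not* emulate: count overdispersion structure tied
to expression level, batch effects, doublets, or realistic cell-type
abundance skew. Passing tests therefore demonstrate the correctness of the
algebra and the behavior of the method under its own model assumptions, not
performance on any particular real dataset.

## Numerical choices and problem sizes

- PCA uses a dense SVD up to 500 cells/features and a seeded randomized
  solver beyond; both are required by tests to match a dense oracle.
- Bridge regressions use `numpy.linalg.lstsq` (minimum-norm under rank
  deficiency, with warning).
- k-NN distance computations are chunked (2048 queries at a time) to bound
  memory on large collections.
- The evaluation suite runs the sweep analyses at reduced sizes chosen so
  the phenomena are visible off ceiling: bridge-size sweeps use 2000 cells
  with 100-feature modality panels and bridge sizes {50, 200, 1000}
  (keeping 200 and 1000 above the shared-panel size, i.e. in the proper
  OLS regime); chain sweeps use 8 datasets × 200 cells at 100 versus 1000
  features per dataset, 5 seeds.
- Degenerate inputs: zero-variance references, single-class LDA, empty
  reference sets, disconnected topologies, zero-norm score blocks and
  oversized neighbor counts all raise informative errors; all-zero cells in
  normalization and empty bridges in the three-way split warn.

## Known limitations

- Bridges are strictly linear; systematic nonlinear cross-modality
  relationships are captured only to first order.
- Minimum-norm fallback near the interpolation threshold (cells ≈ shared
  features) can predict worse than either regime; the sweep designs avoid
  this region deliberately, and users bridging with few cells should prefer
  smaller shared panels or fewer dimensions.
- The enrichment GLM's p-values rely on asymptotics in the number of
  samples (typically ≈7); calibration was verified by simulation at the
  default design but very small replicate counts warrant caution.
- No batch correction is built in; the embedding is intended as input to
  downstream horizontal integration tools where batch structure remains.
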