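# stabmap

Mosaic single-cell data integration: embedding datasets whose feature panels
only partially overlap — or do not overlap at all — into one common
low-dimensional space.

## The problem

Single-cell experiments measure different things: one dataset captures gene
expression, another chromatin peaks, a third protein abundance or spatially
derived features. Horizontal integration assumes shared features; vertical
integration assumes shared cells. Mosaic integration assumes neither: each
pair of datasets may share only a sliver of its feature panel, and some
pairs may share nothing. Discarding everything outside the common feature
intersection throws away most of the signal — and fails completely when the
intersection is empty.

This package integrates such collections by exploiting the *mosaic data
topology* (MDT): a graph with one node per dataset and an edge wherever two
datasets share at least one feature, weighted by the number of shared
features. As long as this graph is connected, every dataset can be routed
into a common space.

## The method

For a reference dataset `D_r` (features × cells), a low-dimensional
decomposition gives scores `S_r = D_r^T A_r` — PCA by default (50
dimensions), LDA when cell labels are supplied, or a user-provided
decomposition. Every other dataset `D_i` is then placed in that space:

- if `D_i` contains every loading feature of `A_r`, it is projected
  directly: `S_i = (X_i − mean)^T A_r`;
- otherwise each score column is regressed (OLS with intercept) on the
  features shared between `D_r` and `D_i`, and the fitted coefficients
  `B` predict `S_i = [1, X_i^T] B` from `D_i`'s side of the shared panel;
- if `D_i` shares no features with `D_r`, projection chains along the
  weighted shortest path of the MDT (edge cost `1 / n_shared`), refitting a
  regression bridge at each hop — *multi-hop* integration through bridge
  datasets.

With several references (default: all datasets) the per-reference blocks
are rescaled to a common L1 norm, weighted by `w_j ∈ [0, 1]`, and
concatenated. The joint embedding supports k-NN label transfer, feature
imputation (neighbor averaging), integration-quality metrics (per-cell
neighborhood Jaccard, the "number of nearest cells" curve), spatial
neighbor-mean feature extraction, and a per-cell logistic enrichment test
with likelihood-ratio p-values and Benjamini–Hochberg FDR control.

## Worked example

```python
import stabmap as sm

# synthetic mosaic: 300-gene reference, query measuring only 60 of them
scenario = sm.MosaicScenario(
    n_features=300, latent_dim=8, n_types=3,
    cells_per_dataset=(400, 300),
    feature_panels=[list(range(300)), list(range(240, 300))],
    noise_sd=0.3, seed=7)
datasets, truth = sm.generate_mosaic(scenario)
ref, query = datasets

topology = sm.build_mdt(datasets)
print("shared features:", topology.edges[ref.name, query.name]["weight"])

emb = sm.stabmap(datasets, sm.StabMapConfig(reference_names=[ref.name], n_dims=50))
print("embedding:", emb.values.shape)

labels = {c: truth.labels[c] for c in ref.cells}
pred = sm.knn_classify(emb, labels, query.cells, k=5)
acc = sm.classification_accuracy(pred, {c: truth.labels[c] for c in query.cells})
print(f"query cell-type accuracy: {acc:.3f}")

imputed = sm.impute_embedding(emb, ref, query.cells, k=5)
print("imputed matrix:", imputed.shape)
```

prints

```
shared features: 60
embedding: (700, 50)
query cell-type accuracy: 1.000
imputed matrix: (300, 300)
```

The two datasets share only 60 feature names, so the query cells are
embedded through a regression bridge on that shared panel; all 700 cells
land in the reference's 50-dimensional PC space. Label transfer then
recovers the simulated cell types of the query cells perfectly, and the
240 genes the query never measured are imputed for each of its 300 cells
by averaging its five nearest reference cells.

The same operations are available from the shell:

```sh
stabmap simulate --n-datasets 2 --cells 200 --out sim/
stabmap mdt --dataset A=sim/dataset_0.tsv --dataset B=sim/dataset_1.tsv --out edges.tsv
stabmap embed --dataset A=sim/dataset_0.tsv --dataset B=sim/dataset_1.tsv --seed 1 --out run/
stabmap classify --embedding run/embedding.tsv --labels sim/labels.tsv --out pred.tsv
```

Matrix Market (with `features.tsv`/`barcodes.tsv` sidecars), dense CSV/TSV
and HDF5 inputs are accepted.

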