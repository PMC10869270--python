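"""Core mosaic embedding.

Each reference dataset defines a low-dimensional coordinate system via PCA
(default, 50 dimensions), LDA (when cell labels are supplied), or a
user-supplied decomposition. Every dataset in the collection is then placed
into that system:

* the reference itself keeps its own scores;
* a dataset containing every loading feature is projected directly,
  ``S = (X - mean)^T A``;
* a dataset with only a partial overlap gets its scores predicted by an
  ordinary-least-squares "bridge": the reference scores are regressed on the
  shared features (with intercept) and the fitted linear map is applied to
  the other dataset's shared-feature submatrix;
* a dataset sharing no features with the reference is reached by chaining
  bridges along the weighted shortest path of the mosaic data topology.

With several references the per-reference score blocks are rescaled to a
common norm (optionally weighted) and concatenated column-wise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA

from .dataset import Dataset, check_collection
from . import mdt as mdt_mod

logger = logging.getLogger("stabmap")

DEFAULT_N_DIMS = 50


@dataclass
class StabMapConfig:
    """Options controlling the joint embedding.

    ``reference_names`` defaults to all datasets. ``n_dims`` is the requested
    number of dimensions per reference (capped by data rank limits; 50 by
    default). ``labels`` maps cell id -> class; when a reference's cells are
    fully labeled, LDA is used for that reference instead of PCA.
    ``reference_weights`` are the per-reference w in [0, 1] applied after
    norm rescaling. ``reweight_norm`` is "l1" (default) or "l2".
    """

    reference_names: list[str] | None = None
    n_dims: int = DEFAULT_N_DIMS
    labels: Mapping[str, str] | None = None
    reference_weights: Mapping[str, float] | None = None
    reweight_norm: str = "l1"
    random_seed: int = 0


@dataclass
class ReferenceModel:
    """Fitted dimensionality reduction for one reference dataset."""

    reference_name: str
    mode: str  # "pca" | "lda" | "user_supplied"
    feature_names: list[str]
    loadings: np.ndarray        # (n loading features, n_dims)
    feature_means: np.ndarray   # (n loading features,)
    scores: np.ndarray          # (n reference cells, n_dims)
    cell_ids: list[str]
    dim_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.dim_names:
            tag = {"pca": "PC", "lda": "LD"}.get(self.mode, "DIM")
            self.dim_names = [f"{tag}{j + 1}" for j in range(self.loadings.shape[1])]

    @property
    def n_dims(self) -> int:
        return self.loadings.shape[1]


@dataclass
class RegressionBridge:
    """OLS map from a shared-feature panel to reference-space scores."""

    predictor_features: list[str]
    coefficients: np.ndarray  # (1 + n predictors, n_dims); row 0 = intercept
    fitted_on: str

    @property
    def n_dims(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class StabMapEmbedding:
    """Joint low-dimensional coordinates for all cells of all datasets."""

    cell_ids: list[str]
    cell_datasets: list[str]
    values: np.ndarray        # (total cells, total dims)
    dim_names: list[str]
    block_index: list[str]    # originating reference per column
    _row_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.dim_names)):
            raise ValueError("embedding shape inconsistent with labels")
        if len(self.block_index) != len(self.dim_names):
            raise ValueError("block_index length must equal number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite values")
        self._row_of = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_dims(self) -> int:
        return len(self.dim_names)

    def rows(self, cell_ids: Sequence[str]) -> np.ndarray:
        idx = [self._row_of[c] for c in cell_ids]
        return self.values[idx, :]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.dim_names)
        df.insert(0, "dataset", self.cell_datasets)
        df.insert(0, "cell_id", self.cell_ids)
        return df


def _cap_dims(requested: int, n_features: int, n_cells: int,
              n_classes: int | None = None) -> int:
    cap = min(requested, n_features, n_cells - 1)
    if n_classes is not None:
        cap = min(cap, n_classes - 1)
    if cap < requested:
        logger.warning("capping n_dims from %d to %d (data limits)", requested, cap)
    if cap < 1:
        raise ValueError("data cannot support even one embedding dimension")
    return cap


def fit_reference(dataset: Dataset, config: StabMapConfig | None = None) -> ReferenceModel:
    """Fit the reference decomposition for one dataset.

    PCA on feature-centered data unless ``config.labels`` covers every cell
    of the dataset, in which case LDA is used (dimensions capped at
    n_classes - 1). All of the dataset's features enter the fit.
    """
    config = config or StabMapConfig()
    if dataset.n_cells < 2:
        raise ValueError(f"reference {dataset.name!r} needs at least 2 cells")
    x = dataset.dense().T  # cells x features
    means = x.mean(axis=0)
    if not np.any(np.var(x, axis=0) > 0):
        raise ValueError(f"reference {dataset.name!r} has zero variance everywhere")

    labels = None
    if config.labels is not None:
        got = [config.labels.get(c) for c in dataset.cells]
        if all(v is not None for v in got):
            labels = np.asarray(got, dtype=object)

    if labels is not None:
        classes = np.unique(labels)
        if len(classes) < 2:
            raise ValueError(
                f"LDA on reference {dataset.name!r} requires >= 2 classes, "
                f"got {len(classes)}"
            )
        n_dims = _cap_dims(config.n_dims, dataset.n_features, dataset.n_cells,
                           n_classes=len(classes))
        loadings = _lda_loadings(x - means, labels, n_dims)
        scores = (x - means) @ loadings
        mode = "lda"
    else:
        n_dims = _cap_dims(config.n_dims, dataset.n_features, dataset.n_cells)
        solver = "full" if min(x.shape) <= 500 else "randomized"
        pca = PCA(n_components=n_dims, svd_solver=solver,
                  random_state=config.random_seed)
        scores = pca.fit_transform(x)
        loadings = pca.components_.T
        mode = "pca"

    return ReferenceModel(
        reference_name=dataset.name,
        mode=mode,
        feature_names=list(dataset.features),
        loadings=loadings,
        feature_means=means,
        scores=scores,
        cell_ids=list(dataset.cells),
    )


def _lda_loadings(xc: np.ndarray, labels: np.ndarray, n_dims: int) -> np.ndarray:
    """Fisher discriminant directions via generalized eigendecomposition.

    Within-class scatter gets a small ridge (1e-8 x mean diagonal) so that
    singular scatter (features > cells) still yields usable directions.
    """
    n, p = xc.shape
    classes = np.unique(labels)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    grand = xc.mean(axis=0)
    for c in classes:
        xg = xc[labels == c]
        mu = xg.mean(axis=0)
        dev = xg - mu
        sw += dev.T @ dev
        dm = (mu - grand)[:, None]
        sb += len(xg) * (dm @ dm.T)
    ridge = 1e-8 * (np.trace(sw) / p if np.trace(sw) > 0 else 1.0)
    sw[np.diag_indices_from(sw)] += ridge
    vals, vecs = linalg.eigh(sb, sw)
    order = np.argsort(vals)[::-1][:n_dims]
    w = vecs[:, order]
    # normalize each discriminant to unit length for scale stability
    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    return w / norms


def make_user_reference(name: str, feature_names: list[str], loadings: np.ndarray,
                        feature_means: np.ndarray, scores: np.ndarray,
                        cell_ids: list[str]) -> ReferenceModel:
    """Wrap a caller-provided decomposition (e.g. from a vertical-integration
    method) as a reference model usable in place of PCA/LDA."""
    return ReferenceModel(
        reference_name=name, mode="user_supplied",
        feature_names=list(feature_names), loadings=np.asarray(loadings, float),
        feature_means=np.asarray(feature_means, float),
        scores=np.asarray(scores, float), cell_ids=list(cell_ids),
    )


def project_direct(dataset: Dataset, model: ReferenceModel) -> np.ndarray:
    """Project a full-panel dataset onto the reference: (X - mean)^T A.

    Every loading feature of the model must be present; otherwise the
    regression bridge is the right tool.
    """
    try:
        x = dataset.submatrix(model.feature_names)  # features x cells
    except KeyError as err:
        raise KeyError(
            f"dataset {dataset.name!r} lacks loading features of reference "
            f"{model.reference_name!r}; use a regression bridge "
            f"(fit_bridge/apply_bridge) instead. {err}"
        ) from err
    return (x.T - model.feature_means) @ model.loadings


def fit_bridge(source_scores: np.ndarray, source_data: Dataset,
               shared_features: list[str]) -> RegressionBridge:
    """OLS regression of scores on a shared-feature panel, with intercept.

    One coefficient column per score dimension. Rank-deficient panels fall
    back to the minimum-norm least-squares solution with a warning.
    """
    if not shared_features:
        raise ValueError("shared_features must be nonempty")
    x = source_data.submatrix(shared_features).T  # cells x shared features
    if x.shape[0] != source_scores.shape[0]:
        raise ValueError("source_scores rows must match source_data cells")
    design = np.column_stack([np.ones(x.shape[0]), x])
    coef, _, rank, _ = np.linalg.lstsq(design, source_scores, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"bridge on {source_data.name!r}: predictor matrix rank {rank} < "
            f"{design.shape[1]} columns; using minimum-norm least squares",
            RuntimeWarning,
        )
    return RegressionBridge(
        predictor_features=list(shared_features),
        coefficients=coef,
        fitted_on=source_data.name,
    )


def apply_bridge(bridge: RegressionBridge, target_data: Dataset) -> np.ndarray:
    """Predicted scores for `target_data` from a fitted bridge."""
    x = target_data.submatrix(bridge.predictor_features).T
    design = np.column_stack([np.ones(x.shape[0]), x])
    return design @ bridge.coefficients


def project_along_path(path: Sequence[str], datasets: Mapping[str, Dataset],
                       model: ReferenceModel) -> np.ndarray:
    """Chain projections along an MDT path ending at the target dataset.

    At each hop the current node's (estimated) scores are regressed on the
    features it shares with the next node and the fit is applied to the next
    node's cells. A hop whose target holds the full loading panel is
    projected directly instead.
    """
    if path[0] != model.reference_name:
        raise ValueError(
            f"path must start at the reference {model.reference_name!r}, "
            f"got {path[0]!r}"
        )
    scores = model.scores
    loading_set = set(model.feature_names)
    for prev_name, next_name in zip(path[:-1], path[1:]):
        prev_d, next_d = datasets[prev_name], datasets[next_name]
        if loading_set <= next_d.feature_set:
            scores = project_direct(next_d, model)
            continue
        shared = mdt_mod.shared_features(prev_d, next_d)
        if not shared:
            raise ValueError(
                f"consecutive path datasets {prev_name!r} and {next_name!r} "
                "share no features"
            )
        bridge = fit_bridge(scores, prev_d, shared)
        scores = apply_bridge(bridge, next_d)
    return scores


def reweight_blocks(blocks: Sequence[np.ndarray], weights: Sequence[float],
                    norm: str = "l1") -> list[np.ndarray]:
    """Rescale per-reference score blocks to commensurate norms.

    Each block is divided by its own matrix norm (L1 = sum of absolute
    entries by default; "l2" = Frobenius) and multiplied by its weight in
    [0, 1], so with equal weights every block contributes equally to
    distances in the concatenated space.
    """
    if len(blocks) != len(weights):
        raise ValueError("one weight per block required")
    out = []
    for b, w in zip(blocks, weights):
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weights must lie in [0, 1], got {w}")
        if norm == "l1":
            denom = np.abs(b).sum()
        elif norm == "l2":
            denom = np.linalg.norm(b)
        else:
            raise ValueError(f"unknown norm {norm!r}")
        if denom == 0:
            raise ValueError("degenerate reference: score block has zero norm")
        out.append(b * (w / denom))
    return out


def scores_for_all(datasets: Sequence[Dataset], model: ReferenceModel,
                   topology) -> np.ndarray:
    """Stack every dataset's scores in the reference space, in input order."""
    by_name = {d.name: d for d in datasets}
    parts = []
    for d in datasets:
        if d.name == model.reference_name:
            parts.append(model.scores)
        elif set(model.feature_names) <= d.feature_set:
            parts.append(project_direct(d, model))
        else:
            path = mdt_mod.shortest_path(topology, model.reference_name, d.name)
            logger.info("projection path %s -> %s: %s",
                        model.reference_name, d.name, " -> ".join(path))
            parts.append(project_along_path(path, by_name, model))
    return np.vstack(parts)


def stabmap(datasets: Sequence[Dataset],
            config: StabMapConfig | None = None) -> StabMapEmbedding:
    """Joint mosaic embedding of a dataset collection.

    For each reference (default: every dataset) a decomposition is fitted
    and all cells are projected into its space via direct projection or
    chained regression bridges along the mosaic data topology. Blocks are
    norm-rescaled, weighted and concatenated column-wise.
    """
    datasets = list(datasets)
    config = config or StabMapConfig()
    check_collection(datasets)
    topology = mdt_mod.build_mdt(datasets)
    mdt_mod.assert_connected(topology)
    logger.info("%s", mdt_mod.mdt_summary(topology))

    ref_names = config.reference_names or [d.name for d in datasets]
    if not ref_names:
        raise ValueError("reference set must be nonempty")
    known = {d.name for d in datasets}
    unknown = [r for r in ref_names if r not in known]
    if unknown:
        raise KeyError(f"unknown reference names: {unknown}")

    by_name = {d.name: d for d in datasets}
    blocks, weights, dim_names, block_index = [], [], [], []
    for r in ref_names:
        model = fit_reference(by_name[r], config)
        blocks.append(scores_for_all(datasets, model, topology))
        w = 1.0
        if config.reference_weights is not None:
            w = float(config.reference_weights.get(r, 1.0))
        weights.append(w)
        dim_names.extend(f"{r}_{dn}" for dn in model.dim_names)
        block_index.extend([r] * model.n_dims)

    blocks = reweight_blocks(blocks, weights, norm=config.reweight_norm)
    values = np.hstack(blocks)
    cell_ids = [c for d in datasets for c in d.cells]
    cell_datasets = [d.name for d in datasets for _ in d.cells]
    return StabMapEmbedding(
        cell_ids=cell_ids,
        cell_datasets=cell_datasets,
        values=values,
        dim_names=dim_names,
        block_index=block_index,
    )
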