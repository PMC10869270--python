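"""Spatially aware features and the local enrichment test.

Two tools used together in spatial + dissociated integration analyses:

* neighbor-mean feature extraction: for each gene and cell, the mean
  expression among cells within a fixed number of hops in the spatial
  nearest-neighbor network, producing derived features that carry a cell's
  local tissue context into the integration;
* a per-query-cell logistic (binomial GLM) test for local enrichment of a
  perturbed lineage: among each biological sample's nearest cells in the
  joint embedding, the fraction of lineage-labeled (td-Tomato+) cells is
  modeled as logit(p) = b0 + b1*x1 + b2*x2, where x1 is the sample-wide
  labeled fraction (controls injection efficiency) and x2 indicates the
  perturbed genotype. b2 and its likelihood-ratio p-value measure local
  enrichment/depletion; Benjamini-Hochberg adjusts across query cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .dataset import Dataset
from .downstream import _knn_indices
from .embedding import StabMapEmbedding

logger = logging.getLogger("stabmap")

DEFAULT_ENRICHMENT_NEIGHBORS = 1000
DEFAULT_SPATIAL_K = 6
DEFAULT_MAX_STEPS = 2


@dataclass
class SpatialGraph:
    """Undirected spatial neighbor relation over cells with 2-D coordinates."""

    cell_ids: list[str]
    adjacency: sparse.csr_matrix  # boolean, symmetric, zero diagonal
    coordinates: np.ndarray | None = None
    _col_of: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        a = sparse.csr_matrix(self.adjacency, dtype=bool)
        a.setdiag(False)
        a.eliminate_zeros()
        if (a != a.T).nnz != 0:
            raise ValueError("spatial adjacency must be symmetric")
        self.adjacency = a
        self._col_of = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def knn_spatial_graph(cell_ids: Sequence[str], coordinates: np.ndarray,
                      k: int = DEFAULT_SPATIAL_K) -> SpatialGraph:
    """Symmetric k-nearest-neighbor graph from 2-D coordinates.

    An edge joins i and j if either is among the other's k nearest cells
    (Euclidean). k defaults to 6, a typical packing density for planar
    tissue sections.
    """
    coords = np.asarray(coordinates, float)
    n = coords.shape[0]
    if n != len(cell_ids):
        raise ValueError("one coordinate row per cell required")
    k = min(k, n - 1)
    rows, cols = [], []
    if k >= 1:
        nn = _knn_indices(coords, coords, k + 1)  # self comes first
        for i in range(n):
            for j in nn[i]:
                if j != i:
                    rows.append(i)
                    cols.append(j)
    adj = sparse.coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
    ).tocsr()
    adj = (adj + adj.T).astype(bool)
    return SpatialGraph(list(cell_ids), adj, coordinates=coords)


def graph_from_edges(cell_ids: Sequence[str],
                     edges: Sequence[tuple[str, str]]) -> SpatialGraph:
    idx = {c: i for i, c in enumerate(cell_ids)}
    rows = [idx[a] for a, b in edges] + [idx[b] for a, b in edges]
    cols = [idx[b] for a, b in edges] + [idx[a] for a, b in edges]
    n = len(cell_ids)
    adj = sparse.coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
    ).tocsr()
    return SpatialGraph(list(cell_ids), adj)


def neighbor_mean_features(expression: Dataset, graph: SpatialGraph,
                           max_steps: int = DEFAULT_MAX_STEPS,
                           suffix: str = "_nbr") -> Dataset:
    """Mean expression among cells within `max_steps` hops, per gene and cell.

    The cell itself is excluded from its neighborhood; an isolated cell
    falls back to its own value so the derived feature stays defined.
    Derived features are renamed with `suffix` so the caller can concatenate
    them with the originals.
    """
    missing = [c for c in expression.cells if c not in graph._col_of]
    if missing:
        raise KeyError(f"cells absent from spatial graph: {missing[:5]}")
    cols = [graph._col_of[c] for c in expression.cells]

    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    a = graph.adjacency.astype(bool)
    reach = a.copy()
    power = a.copy()
    for _ in range(max_steps - 1):
        power = (power @ a).astype(bool)
        reach = (reach + power).astype(bool)
    reach = sparse.lil_matrix(reach)
    reach.setdiag(False)
    reach = reach.tocsr()[np.ix_(cols, cols)]

    x = expression.dense()  # features x cells
    m = reach.astype(float)
    counts = np.asarray(m.sum(axis=1)).ravel()  # neighbors per cell
    sums = x @ m.T  # features x cells: sum over each cell's neighborhood
    out = x.copy()
    has_nbrs = counts > 0
    out[:, has_nbrs] = sums[:, has_nbrs] / counts[has_nbrs]
    return Dataset(
        name=f"{expression.name}{suffix}",
        features=[f + suffix for f in expression.features],
        cells=list(expression.cells),
        values=out,
    )


@dataclass
class EnrichmentInput:
    """Sample-level design for the local enrichment test.

    One biological sample per chimera replicate. ``sample_of_cell`` assigns
    every chimera cell (present in the embedding) to its sample;
    ``td_positive`` flags lineage-labeled cells; ``genotype`` gives the
    per-sample perturbation indicator x2 (1 = perturbed, 0 = control).
    The replicate-wide labeled fraction x1 is derived per sample.
    """

    sample_of_cell: Mapping[str, str]
    td_positive: Mapping[str, bool]
    genotype: Mapping[str, int]

    def __post_init__(self) -> None:
        for s, g in self.genotype.items():
            if g not in (0, 1):
                raise ValueError(f"genotype for sample {s!r} must be 0/1, got {g}")
        missing = [s for s in set(self.sample_of_cell.values())
                   if s not in self.genotype]
        if missing:
            raise ValueError(f"samples without genotype: {missing}")

    def baseline_fractions(self) -> dict[str, float]:
        """x1 per sample: the sample-wide td-positive fraction."""
        tot: dict[str, int] = {}
        pos: dict[str, int] = {}
        for c, s in self.sample_of_cell.items():
            tot[s] = tot.get(s, 0) + 1
            pos[s] = pos.get(s, 0) + int(bool(self.td_positive.get(c, False)))
        return {s: pos[s] / tot[s] for s in tot}


def fit_enrichment_glm(fractions: np.ndarray, trials: np.ndarray,
                       x1: np.ndarray, x2: np.ndarray) -> tuple[float, float, float]:
    """Weighted binomial GLM logit(p) = b0 + b1 x1 + b2 x2 with LRT on b2.

    `fractions` are observed proportions per sample, weighted by `trials`
    (neighborhood sizes). Returns (beta2_hat, LRT statistic, p-value); NaNs
    on non-convergence or separation.
    """
    full_design = np.column_stack([np.ones_like(x1), x1, x2])
    null_design = full_design[:, :2]
    try:
        full = sm.GLM(fractions, full_design, family=sm.families.Binomial(),
                      var_weights=trials).fit()
        null = sm.GLM(fractions, null_design, family=sm.families.Binomial(),
                      var_weights=trials).fit()
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return float("nan"), float("nan"), float("nan")
    if not (full.converged and null.converged):
        return float("nan"), float("nan"), float("nan")
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    pval = float(stats.chi2.sf(lrt, df=1))
    return float(full.params[2]), float(lrt), pval


def local_enrichment_test(embedding: StabMapEmbedding,
                          query_cells: Sequence[str],
                          samples: EnrichmentInput,
                          n_neighbors: int = DEFAULT_ENRICHMENT_NEIGHBORS) -> pd.DataFrame:
    """Per-query-cell local enrichment of the perturbed lineage.

    For each query cell, the n nearest cells of every sample (Euclidean in
    the embedding) define a neighborhood; the td-positive fraction in each
    neighborhood is the response of a counts-weighted binomial regression on
    (sample-wide baseline fraction, genotype). Reports the genotype
    coefficient, its likelihood-ratio statistic and p-value, and BH-adjusted
    p-values across all query cells. Cells whose fit fails carry NaN and are
    excluded from the FDR ranking.
    """
    sample_names = sorted(set(samples.sample_of_cell.values()))
    baselines = samples.baseline_fractions()
    x1 = np.array([baselines[s] for s in sample_names])
    x2 = np.array([float(samples.genotype[s]) for s in sample_names])
    if len(set(x2.tolist())) < 2:
        raise ValueError("need both perturbed and control samples")

    query = embedding.rows(list(query_cells))
    frac = np.empty((len(query_cells), len(sample_names)))
    trials = np.empty(len(sample_names))
    for j, s in enumerate(sample_names):
        cells_s = [c for c in embedding.cell_ids
                   if samples.sample_of_cell.get(c) == s]
        if len(cells_s) < n_neighbors:
            raise ValueError(
                f"sample {s!r} has {len(cells_s)} cells in the embedding, "
                f"fewer than n_neighbors={n_neighbors}"
            )
        pos = embedding.rows(cells_s)
        td = np.array([bool(samples.td_positive.get(c, False)) for c in cells_s])
        nn = _knn_indices(pos, query, n_neighbors)
        frac[:, j] = td[nn].mean(axis=1)
        trials[j] = n_neighbors

    rows = []
    for i, cell in enumerate(query_cells):
        beta2, lrt, p = fit_enrichment_glm(frac[i], trials, x1, x2)
        rows.append((cell, beta2, lrt, p))
    res = pd.DataFrame(rows, columns=["cell_id", "beta2", "stat", "p"]).set_index("cell_id")
    res["fdr"] = benjamini_hochberg(res["p"].to_numpy())
    return res


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment; NaN entries propagate as NaN."""
    p = np.asarray(p_values, float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum() > 0:
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
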