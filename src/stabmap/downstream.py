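"""Downstream use of a joint embedding: imputation and label transfer.

Both operations are k-nearest-neighbor lookups in the embedding space under
Euclidean distance. Neighbor order is made fully deterministic by breaking
distance ties on the training cell's position in the embedding's cell order
(i.e. cell-id order as recorded there).
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import Dataset
from .embedding import StabMapEmbedding

DEFAULT_K = 5


def _knn_indices(train: np.ndarray, query: np.ndarray, k: int,
                 chunk: int = 2048) -> np.ndarray:
    """Indices of the k nearest training rows per query row.

    Brute-force squared Euclidean distances, evaluated per query chunk to
    bound memory; ties broken by training-row index for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > train.shape[0]:
        raise ValueError(f"k={k} exceeds training set size {train.shape[0]}")
    tt = (train ** 2).sum(axis=1)
    out = np.empty((query.shape[0], k), dtype=np.int64)
    train_idx = np.arange(train.shape[0])
    for start in range(0, query.shape[0], chunk):
        q = query[start:start + chunk]
        d2 = (q ** 2).sum(axis=1)[:, None] - 2.0 * (q @ train.T) + tt[None, :]
        np.maximum(d2, 0.0, out=d2)
        for i in range(q.shape[0]):
            order = np.lexsort((train_idx, d2[i]))
            out[start + i] = order[:k]
    return out


def impute_embedding(embedding: StabMapEmbedding, reference: Dataset,
                     query_cells: Sequence[str], k: int = DEFAULT_K,
                     chunk: int = 2048) -> pd.DataFrame:
    """Impute the reference's original features for query cells.

    For each query cell, the unweighted mean of the original feature vectors
    of its k nearest reference cells in embedding space. Returns a features x
    query-cells frame.
    """
    train = embedding.rows(reference.cells)
    query = embedding.rows(list(query_cells))
    nn = _knn_indices(train, query, k, chunk=chunk)
    ref_vals = reference.dense()  # features x reference cells
    out = np.empty((reference.n_features, len(query_cells)))
    for i in range(nn.shape[0]):
        out[:, i] = ref_vals[:, nn[i]].mean(axis=1)
    return pd.DataFrame(out, index=reference.features, columns=list(query_cells))


def knn_classify(embedding: StabMapEmbedding, labels: Mapping[str, str],
                 query_cells: Sequence[str], k: int = DEFAULT_K) -> pd.Series:
    """Majority-vote label transfer in the embedding space.

    Training cells are all labeled cells present in the embedding. Vote ties
    are broken by the label of the nearest neighbor among the tied classes.
    """
    train_cells = [c for c in embedding.cell_ids if c in labels]
    if not train_cells:
        raise ValueError("no labeled training cells present in the embedding")
    train = embedding.rows(train_cells)
    query = embedding.rows(list(query_cells))
    train_labels = np.asarray([labels[c] for c in train_cells], dtype=object)
    nn = _knn_indices(train, query, k)
    preds = []
    for row in nn:
        votes = Counter(train_labels[row])
        top = max(votes.values())
        tied = {lab for lab, n in votes.items() if n == top}
        if len(tied) == 1:
            preds.append(next(iter(tied)))
        else:
            # nearest neighbor whose label is among the tied classes
            preds.append(next(train_labels[j] for j in row if train_labels[j] in tied))
    return pd.Series(preds, index=list(query_cells), name="predicted_label")
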