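"""Quantitative evaluation of mosaic integration quality.

Three metrics, all operating on a joint embedding in which some cells are
measured on two omics layers and matched one-to-one across layers:

* cell-type classification accuracy of label transfer;
* per-cell Jaccard similarity of within-layer neighborhoods, comparing the
  k nearest same-layer cells around the two positions of a matched cell;
* the "number of nearest cells" statistic: how many opposite-layer cells
  sit at least as close as a cell's own matched partner, with its empirical
  cumulative curve M(x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_JACCARD_K = 100


@dataclass
class PairedEmbedding:
    """Matched two-layer embedding positions.

    ``positions1[i]`` and ``positions2[i]`` are the two coordinates of the
    same underlying cell in layers 1 and 2; ``ids`` names the matched cells.
    """

    ids: list[str]
    positions1: np.ndarray  # (n matched cells, n dims)
    positions2: np.ndarray

    def __post_init__(self) -> None:
        self.positions1 = np.asarray(self.positions1, float)
        self.positions2 = np.asarray(self.positions2, float)
        if self.positions1.shape != self.positions2.shape:
            raise ValueError("layer position matrices must have equal shape")
        if self.positions1.shape[0] != len(self.ids):
            raise ValueError("one id per matched cell required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("matched cell ids must be unique")

    @property
    def n(self) -> int:
        return len(self.ids)


def classification_accuracy(predicted: Mapping[str, str] | pd.Series,
                            truth: Mapping[str, str] | pd.Series) -> float:
    """Fraction of cells whose predicted label equals the true label."""
    pred = pd.Series(dict(predicted) if not isinstance(predicted, pd.Series) else predicted)
    true = pd.Series(dict(truth) if not isinstance(truth, pd.Series) else truth)
    if len(pred) == 0 or len(true) == 0:
        raise ValueError("empty label input")
    joined = pd.concat([pred.rename("pred"), true.rename("true")], axis=1, join="inner")
    if len(joined) == 0:
        raise ValueError("predicted and truth share no cell ids")
    return float((joined["pred"] == joined["true"]).mean())


def _knn_sets(points: np.ndarray, k: int) -> list[frozenset[int]]:
    """k-nearest-neighbor index sets per row, excluding the row itself.

    Ties at the k-th neighbor keep the lowest row index.
    """
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the layer size {n}")
    d2 = (
        (points ** 2).sum(axis=1)[:, None]
        - 2.0 * (points @ points.T)
        + (points ** 2).sum(axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    idx = np.arange(n)
    sets = []
    for i in range(n):
        row = d2[i].copy()
        row[i] = np.inf  # self excluded
        order = np.lexsort((idx, row))
        sets.append(frozenset(order[:k].tolist()))
    return sets


def jaccard_neighborhood(paired: PairedEmbedding,
                         k: int = DEFAULT_JACCARD_K) -> pd.Series:
    """Per matched cell, Jaccard overlap of its two within-layer k-NN sets.

    Neighbor identities from layer 2 are translated to layer-1 identities via
    the matching before comparison; values near 1 mean the two layers place
    the same cells nearby.
    """
    sets1 = _knn_sets(paired.positions1, k)
    sets2 = _knn_sets(paired.positions2, k)
    vals = []
    for s1, s2 in zip(sets1, sets2):
        vals.append(len(s1 & s2) / len(s1 | s2))
    return pd.Series(vals, index=paired.ids, name="jaccard")


def nearest_cells_curve(paired: PairedEmbedding) -> tuple[pd.Series, pd.Series]:
    """Number-of-nearest-cells statistic N_i2 and its cumulative curve M(x).

    N_i2 counts opposite-layer cells whose distance to cell i's layer-1
    position is <= the distance to i's own layer-2 position (so the matched
    partner always counts itself, making N_i2 >= 1). M(x) counts cells with
    N_i2 <= x for each integer x up to the maximum.
    """
    if paired.n == 0:
        raise ValueError("empty matching")
    p1, p2 = paired.positions1, paired.positions2
    d2 = (
        (p1 ** 2).sum(axis=1)[:, None]
        - 2.0 * (p1 @ p2.T)
        + (p2 ** 2).sum(axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    own = np.diag(d2)
    n_i2 = (d2 <= own[:, None] + 1e-12).sum(axis=1)
    counts = pd.Series(n_i2.astype(int), index=paired.ids, name="n_nearest_cells")
    xs = np.arange(1, int(counts.max()) + 1)
    curve = pd.Series([(counts <= x).sum() for x in xs], index=xs, name="M")
    return counts, curve


def metrics_table(jaccard: pd.Series | None = None,
                  nearest: pd.Series | None = None) -> pd.DataFrame:
    """Tidy (cell_id, metric, value) table for export."""
    frames = []
    if jaccard is not None:
        frames.append(pd.DataFrame({
            "cell_id": jaccard.index, "metric": "jaccard", "value": jaccard.values
        }))
    if nearest is not None:
        frames.append(pd.DataFrame({
            "cell_id": nearest.index, "metric": "n_nearest_cells",
            "value": nearest.values,
        }))
    if not frames:
        return pd.DataFrame(columns=["cell_id", "metric", "value"])
    return pd.concat(frames, ignore_index=True)


def metrics_summary(table: pd.DataFrame) -> dict:
    out: dict = {}
    for metric, grp in table.groupby("metric"):
        v = grp["value"].astype(float)
        out[metric] = {
            "mean": float(v.mean()),
            "q25": float(v.quantile(0.25)),
            "median": float(v.median()),
            "q75": float(v.quantile(0.75)),
        }
    return out
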