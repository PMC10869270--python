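"""Named feature-by-cell matrix container.

All integration operates on :class:`Dataset` objects: a real matrix whose
rows are named features (genes, peaks, proteins, derived spatial features)
and whose columns are named cells. Values are assumed already normalized on
a roughly linear scale (e.g. log counts); no normalization happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class Dataset:
    """One input data matrix for mosaic integration.

    Parameters
    ----------
    name
        Unique identifier of the dataset within a collection.
    features
        Ordered, unique feature names (matrix rows).
    cells
        Ordered, unique cell identifiers (matrix columns).
    values
        Real matrix of shape ``(len(features), len(cells))``; dense ndarray
        or scipy sparse.
    """

    name: str
    features: list[str]
    cells: list[str]
    values: np.ndarray | sparse.spmatrix
    _feature_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.features = [str(f) for f in self.features]
        self.cells = [str(c) for c in self.cells]
        if len(set(self.features)) != len(self.features):
            dupes = _duplicates(self.features)
            raise ValueError(
                f"dataset {self.name!r}: duplicate feature names: {dupes[:10]}"
            )
        if len(set(self.cells)) != len(self.cells):
            dupes = _duplicates(self.cells)
            raise ValueError(
                f"dataset {self.name!r}: duplicate cell identifiers: {dupes[:10]}"
            )
        if self.values.shape != (len(self.features), len(self.cells)):
            raise ValueError(
                f"dataset {self.name!r}: values shape {self.values.shape} does not "
                f"match ({len(self.features)} features, {len(self.cells)} cells)"
            )
        self._feature_index = {f: i for i, f in enumerate(self.features)}

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def feature_set(self) -> frozenset[str]:
        return frozenset(self.features)

    def dense(self) -> np.ndarray:
        """Values as a dense float array (features x cells)."""
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def submatrix(self, feature_names: list[str]) -> np.ndarray:
        """Dense submatrix restricted to `feature_names`, in the given order."""
        missing = [f for f in feature_names if f not in self._feature_index]
        if missing:
            raise KeyError(
                f"dataset {self.name!r} lacks {len(missing)} requested features, "
                f"e.g. {missing[:5]}"
            )
        idx = [self._feature_index[f] for f in feature_names]
        if sparse.issparse(self.values):
            return np.asarray(self.values.tocsr()[idx, :].todense(), dtype=float)
        return np.asarray(self.values, dtype=float)[idx, :]

    def subset_cells(self, cell_ids: list[str], name: str | None = None) -> "Dataset":
        pos = {c: i for i, c in enumerate(self.cells)}
        idx = [pos[c] for c in cell_ids]
        vals = self.values.tocsc()[:, idx] if sparse.issparse(self.values) else self.values[:, idx]
        return Dataset(name or self.name, list(self.features), list(cell_ids), vals)

    def subset_features(self, feature_names: list[str], name: str | None = None) -> "Dataset":
        idx = [self._feature_index[f] for f in feature_names]
        vals = self.values.tocsr()[idx, :] if sparse.issparse(self.values) else self.values[idx, :]
        return Dataset(name or self.name, list(feature_names), list(self.cells), vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.features, columns=self.cells)


def _duplicates(names: list[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for n in names:
        if n in seen and n not in out:
            out.append(n)
        seen.add(n)
    return out


def check_collection(datasets: list[Dataset]) -> None:
    """Validate a collection passed to integration.

    Dataset names must be unique and cell identifiers must be unique across
    the whole collection (cells in two datasets are distinct observations).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    names = [d.name for d in datasets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate dataset names: {_duplicates(names)}")
    seen: dict[str, str] = {}
    clashes: list[str] = []
    for d in datasets:
        for c in d.cells:
            if c in seen:
                clashes.append(f"{c} (in {seen[c]} and {d.name})")
            else:
                seen[c] = d.name
    if clashes:
        raise ValueError(
            f"cell identifiers repeated across datasets: {clashes[:10]}"
        )
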