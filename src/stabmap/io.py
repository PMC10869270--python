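"""Readers, writers and normalization plumbing.

Supported on-disk formats for a feature x cell matrix:

* Matrix Market triplet (``matrix.mtx``) with ``features.tsv`` and
  ``barcodes.tsv`` sidecars (one name per line), the 10x-style layout;
* dense delimited CSV/TSV with feature names as the index column and cell
  ids as the header (``transpose=True`` accepts cells x features);
* an HDF5 container with datasets ``values`` (features x cells),
  ``features`` and ``cells``.

Sparse input stays sparse in memory.
"""

from __future__ import annotations

import logging
import os
import warnings

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .dataset import Dataset

logger = logging.getLogger("stabmap")


def _read_names(path: str, expected: int, what: str) -> list[str]:
    with open(path) as fh:
        names = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if len(names) != expected:
        raise ValueError(
            f"sidecar {path} lists {len(names)} {what} but the matrix has {expected}"
        )
    return names


def read_dataset(path: str, fmt: str | None = None, name: str | None = None,
                 transpose: bool = False) -> Dataset:
    """Read a dataset from disk; `fmt` in {"mtx", "csv", "tsv", "h5"}.

    For "mtx", `path` is the .mtx file; features.tsv and barcodes.tsv are
    expected alongside it. `fmt` is inferred from the extension when omitted.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = {"mtx": "mtx", "csv": "csv", "tsv": "tsv", "txt": "tsv",
               "h5": "h5", "hdf5": "h5"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path!r}")
    name = name or os.path.splitext(os.path.basename(path))[0]

    if fmt == "mtx":
        mat = spio.mmread(path)
        base = os.path.dirname(path)
        feats = _read_names(os.path.join(base, "features.tsv"), mat.shape[0], "features")
        cells = _read_names(os.path.join(base, "barcodes.tsv"), mat.shape[1], "cells")
        values = mat.tocsr() if sparse.issparse(mat) else np.asarray(mat)
        return Dataset(name, feats, cells, values)

    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if transpose:
            df = df.T
        return Dataset(name, [str(i) for i in df.index],
                       [str(c) for c in df.columns], df.to_numpy(dtype=float))

    if fmt == "h5":
        with h5py.File(path, "r") as fh:
            values = fh["values"][:]
            feats = [f.decode() if isinstance(f, bytes) else str(f)
                     for f in fh["features"][:]]
            cells = [c.decode() if isinstance(c, bytes) else str(c)
                     for c in fh["cells"][:]]
        return Dataset(name, feats, cells, values)

    raise ValueError(f"unknown format {fmt!r}")


def write_dataset(dataset: Dataset, path: str, fmt: str | None = None) -> None:
    """Write a dataset; format inferred from extension when omitted."""
    if fmt is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = {"mtx": "mtx", "csv": "csv", "tsv": "tsv",
               "h5": "h5", "hdf5": "h5"}.get(ext, "tsv")
    if fmt == "mtx":
        vals = dataset.values if sparse.issparse(dataset.values) \
            else sparse.coo_matrix(dataset.dense())
        spio.mmwrite(path, vals)
        base = os.path.dirname(path)
        with open(os.path.join(base, "features.tsv"), "w") as fh:
            fh.write("\n".join(dataset.features) + "\n")
        with open(os.path.join(base, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(dataset.cells) + "\n")
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        dataset.to_frame().to_csv(path, sep=sep)
    elif fmt == "h5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=dataset.dense())
            fh.create_dataset("features", data=np.array(dataset.features, dtype="S"))
            fh.create_dataset("cells", data=np.array(dataset.cells, dtype="S"))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(path: str) -> dict[str, str]:
    """Two-column TSV (cell_id, label), header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if str(df.iloc[0, 0]).lower() in ("cell_id", "cell", "barcode"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_coordinates(path: str) -> tuple[list[str], np.ndarray]:
    """TSV (cell_id, x, y) with header."""
    df = pd.read_csv(path, sep="\t")
    cells = [str(c) for c in df.iloc[:, 0]]
    return cells, df.iloc[:, 1:3].to_numpy(dtype=float)


def log_normalize(counts: Dataset, size_factor_target: float | None = None) -> Dataset:
    """Library-size normalization followed by log1p.

    Each cell's counts are scaled so its column sum equals
    `size_factor_target` (default: the mean library size), then log1p is
    applied. All-zero cells are left at zero with a warning.
    """
    x = counts.dense()
    if np.any(x < 0):
        raise ValueError("log_normalize expects nonnegative counts")
    lib = x.sum(axis=0)
    zero = lib == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} cell(s) have zero total counts; left as zeros",
            RuntimeWarning,
        )
    target = size_factor_target if size_factor_target is not None \
        else float(lib[~zero].mean()) if np.any(~zero) else 1.0
    scale = np.ones_like(lib)
    scale[~zero] = target / lib[~zero]
    return Dataset(counts.name, list(counts.features), list(counts.cells),
                   np.log1p(x * scale[None, :]))


def select_hvg(dataset: Dataset, n: int) -> list[str]:
    """Top-n features by variance of the (normalized) values.

    Deterministic: variance ties are broken by feature name.
    """
    if n > dataset.n_features:
        raise ValueError(f"requested {n} features but only {dataset.n_features} exist")
    var = dataset.dense().var(axis=1)
    order = sorted(range(dataset.n_features),
                   key=lambda i: (-var[i], dataset.features[i]))
    return [dataset.features[i] for i in order[:n]]


def write_embedding(embedding, path: str, fmt: str = "tsv") -> None:
    """Embedding as TSV/CSV (cell_id, dataset, dims...) or HDF5."""
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        embedding.to_frame().to_csv(path, sep=sep, index=False)
    elif fmt == "h5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=embedding.values)
            fh.create_dataset("cell_ids", data=np.array(embedding.cell_ids, dtype="S"))
            fh.create_dataset("cell_datasets",
                              data=np.array(embedding.cell_datasets, dtype="S"))
            fh.create_dataset("dim_names", data=np.array(embedding.dim_names, dtype="S"))
            fh.create_dataset("block_index",
                              data=np.array(embedding.block_index, dtype="S"))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_block_index(embedding, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("dim_name\treference\n")
        for dn, ref in zip(embedding.dim_names, embedding.block_index):
            fh.write(f"{dn}\t{ref}\n")
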