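"""Synthetic mosaic scenarios with known ground truth.

Cells live in a low-dimensional latent space: each cell type is a Gaussian
component, observed features are a fixed linear image of the latent position
plus Gaussian noise. Because the generative map is linear, the projection
algebra of the embedding is exactly recoverable at zero noise, which gives
sharp oracles for tests. A negative-binomial count option with subsequent
log-normalization is available for more realistic marginals.

Scenario builders reproduce the structural designs used to stress mosaic
integration: a query dataset keeping only a feature subset, a three-way
modality split with a multi-modal bridge, and a sequential chain of datasets
with ~50% feature overlap between neighbors only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset

DEFAULT_CHAIN_LENGTH = 8
DEFAULT_CHAIN_OVERLAP = 0.5


@dataclass
class MosaicScenario:
    """Parameters of one synthetic mosaic draw.

    ``feature_panels`` lists, per dataset, the indices (into the global
    feature pool) each dataset observes. ``type_separation`` scales the
    spread of cell-type centers in latent space relative to the unit
    within-type spread. ``informative_fraction`` < 1 zeroes the loadings of
    the remaining features, emulating uninformative probes.
    """

    n_features: int = 500
    latent_dim: int = 10
    n_types: int = 3
    cells_per_dataset: tuple[int, ...] = (500,)
    feature_panels: list[list[int]] | None = None
    type_proportions: tuple[float, ...] | None = None
    type_separation: float = 3.0
    noise_sd: float = 0.3
    informative_fraction: float = 1.0
    count_model: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_panels is None:
            self.feature_panels = [list(range(self.n_features))
                                   for _ in self.cells_per_dataset]
        if len(self.feature_panels) != len(self.cells_per_dataset):
            raise ValueError("one feature panel per dataset required")
        for panel in self.feature_panels:
            if len(panel) == 0 or max(panel) >= self.n_features:
                raise ValueError("feature panel indices out of range or empty")


@dataclass
class GroundTruth:
    latent: np.ndarray              # (latent_dim, total cells)
    labels: dict[str, str]          # cell id -> type name
    loadings: np.ndarray            # (n_features, latent_dim)
    cell_datasets: dict[str, str]   # cell id -> dataset name


def generate_mosaic(scenario: MosaicScenario) -> tuple[list[Dataset], GroundTruth]:
    """Draw one mosaic collection from the latent linear model.

    Cell latent positions come from a mixture of spherical Gaussians (one
    component per cell type, centers scaled by ``type_separation``); the
    observed matrix is loadings @ latent + noise, and each dataset keeps
    only its feature panel. Fully deterministic under the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    feats = [f"gene_{i}" for i in range(scenario.n_features)]

    w = rng.normal(size=(scenario.n_features, scenario.latent_dim))
    w /= np.sqrt(scenario.latent_dim)
    if scenario.informative_fraction < 1.0:
        n_info = max(1, int(round(scenario.informative_fraction * scenario.n_features)))
        silent = rng.permutation(scenario.n_features)[n_info:]
        w[silent, :] *= 1e-3

    centers = rng.normal(size=(scenario.n_types, scenario.latent_dim))
    centers *= scenario.type_separation

    props = scenario.type_proportions or tuple(
        1.0 / scenario.n_types for _ in range(scenario.n_types))
    props = np.asarray(props, float)
    props /= props.sum()

    datasets: list[Dataset] = []
    latents, labels, origin = [], {}, {}
    cell_counter = 0
    for d_idx, (n_cells, panel) in enumerate(
            zip(scenario.cells_per_dataset, scenario.feature_panels)):
        dname = f"dataset_{d_idx}"
        types = rng.choice(scenario.n_types, size=n_cells, p=props)
        z = centers[types].T + rng.normal(size=(scenario.latent_dim, n_cells))
        clean = w @ z
        if scenario.count_model:
            # NB counts around exp-scaled means, then library normalization + log1p
            mu = np.exp(clean / max(1.0, np.abs(clean).max()) * 2.0 + 1.0)
            theta = 10.0
            lam = rng.gamma(theta, mu / theta)
            counts = rng.poisson(lam).astype(float)
            lib = counts.sum(axis=0)
            lib[lib == 0] = 1.0
            x = np.log1p(counts / lib * np.median(lib))
        else:
            x = clean + scenario.noise_sd * rng.normal(
                size=(scenario.n_features, n_cells))
        cells = [f"cell_{cell_counter + i}" for i in range(n_cells)]
        cell_counter += n_cells
        for c, t in zip(cells, types):
            labels[c] = f"type_{t}"
            origin[c] = dname
        latents.append(z)
        datasets.append(Dataset(
            name=dname,
            features=[feats[i] for i in panel],
            cells=cells,
            values=x[panel, :],
        ))
    truth = GroundTruth(
        latent=np.hstack(latents), labels=labels, loadings=w, cell_datasets=origin,
    )
    return datasets, truth


def feature_subset_scenario(full_dataset: Dataset, n_query_features: int,
                            seed: int = 0) -> tuple[Dataset, Dataset]:
    """Reference/query split where the query keeps a random feature subset.

    Cells are split into two disjoint halves; the query half retains
    ``n_query_features`` randomly chosen features, the reference half keeps
    the full panel.
    """
    if n_query_features > full_dataset.n_features:
        raise ValueError(
            f"n_query_features={n_query_features} exceeds panel size "
            f"{full_dataset.n_features}"
        )
    rng = np.random.default_rng(seed)
    n = full_dataset.n_cells
    perm = rng.permutation(n)
    ref_cells = [full_dataset.cells[i] for i in sorted(perm[: n // 2])]
    qry_cells = [full_dataset.cells[i] for i in sorted(perm[n // 2:])]
    keep = sorted(rng.permutation(full_dataset.n_features)[:n_query_features])
    qry_feats = [full_dataset.features[i] for i in keep]
    ref = full_dataset.subset_cells(ref_cells, name=f"{full_dataset.name}_ref")
    qry = full_dataset.subset_cells(qry_cells, name=f"{full_dataset.name}_query")
    qry = qry.subset_features(qry_feats, name=qry.name)
    return ref, qry


def multihop_split_scenario(modality1: Dataset, modality2: Dataset,
                            fraction_bridge: float, seed: int = 0,
                            ) -> tuple[Dataset, Dataset, Dataset]:
    """Three-way split: modality-1 only, multi-modal bridge, modality-2 only.

    The two modality datasets must cover the same cells (and share no
    features). Cells are allocated to the three groups; the end datasets then
    share no features and can only be integrated through the bridge.
    """
    if set(modality1.cells) != set(modality2.cells):
        raise ValueError("the two modalities must cover the same cells")
    if not 0.0 <= fraction_bridge <= 1.0:
        raise ValueError("fraction_bridge must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cells = list(modality1.cells)
    n = len(cells)
    n_bridge = int(round(fraction_bridge * n))
    if n_bridge == 0:
        import warnings
        warnings.warn("empty bridge: the mosaic topology will be disconnected",
                      RuntimeWarning)
    perm = rng.permutation(n)
    bridge_idx = set(perm[:n_bridge].tolist())
    rest = perm[n_bridge:]
    half = len(rest) // 2
    m1_idx = set(rest[:half].tolist())
    m2_idx = set(rest[half:].tolist())

    m1_cells = [c for i, c in enumerate(cells) if i in m1_idx]
    m2_cells = [c for i, c in enumerate(cells) if i in m2_idx]
    br_cells = [c for i, c in enumerate(cells) if i in bridge_idx]

    d1 = modality1.subset_cells(m1_cells, name="modality1_only")
    d2 = modality2.subset_cells(m2_cells, name="modality2_only")
    b1 = modality1.subset_cells(br_cells)
    b2 = modality2.subset_cells(br_cells)
    bridge = Dataset(
        name="bridge",
        features=list(b1.features) + list(b2.features),
        cells=br_cells,
        values=np.vstack([b1.dense(), b2.dense()]),
    ) if br_cells else Dataset("bridge",
                               list(modality1.features) + list(modality2.features),
                               [], np.empty((modality1.n_features
                                             + modality2.n_features, 0)))
    return d1, bridge, d2


def sequential_chain_scenario(full_dataset: Dataset,
                              n_chain: int = DEFAULT_CHAIN_LENGTH,
                              overlap_fraction: float = DEFAULT_CHAIN_OVERLAP,
                              n_features: int | None = None,
                              cells_per_dataset: int | None = None,
                              seed: int = 0) -> list[Dataset]:
    """Chain of datasets where each shares features only with its neighbors.

    Features are laid out in overlapping windows: dataset i shares
    ``overlap_fraction`` of its panel with dataset i+1 and nothing with any
    non-adjacent dataset, so the mosaic topology is a path graph — the
    hardest routing case. Cells are split evenly (disjointly) across the
    chain.
    """
    rng = np.random.default_rng(seed)
    if not 0.0 < overlap_fraction <= 0.5:
        raise ValueError(
            "overlap_fraction must lie in (0, 0.5]; larger overlaps would "
            "make non-adjacent datasets share features"
        )
    pool = n_features if n_features is not None else full_dataset.n_features
    if pool > full_dataset.n_features:
        raise ValueError("n_features exceeds the available panel")
    # window size m with step m*(1-overlap): pool = m + (n_chain-1)*step
    step_ratio = 1.0 - overlap_fraction
    m = int(pool / (1.0 + (n_chain - 1) * step_ratio))
    step = int(round(m * step_ratio))
    if m < 2 or step < 1:
        raise ValueError("not enough features for the requested chain")
    feat_perm = rng.permutation(full_dataset.n_features)[:pool]

    per = cells_per_dataset if cells_per_dataset is not None \
        else full_dataset.n_cells // n_chain
    if per * n_chain > full_dataset.n_cells:
        raise ValueError("not enough cells for the requested chain")
    cell_perm = rng.permutation(full_dataset.n_cells)

    out = []
    for i in range(n_chain):
        lo = i * step
        hi = min(lo + m, pool)
        feats = [full_dataset.features[j] for j in sorted(feat_perm[lo:hi])]
        cidx = sorted(cell_perm[i * per:(i + 1) * per].tolist())
        cells = [full_dataset.cells[j] for j in cidx]
        d = full_dataset.subset_cells(cells, name=f"chain_{i + 1}")
        out.append(d.subset_features(feats, name=d.name))
    return out
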