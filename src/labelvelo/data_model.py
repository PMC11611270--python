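"""Container, I/O, size factors and kNN preprocessing.

A :class:`LabelingExperiment` holds integer count layers (cells x genes) from a
metabolic-labeling scRNA-seq experiment together with the per-cell labeling
duration (hours) and size factor.  Recognized layers:

====  =============================
new   new / labeled mRNA  (l)
total total mRNA          (r)
uu    unspliced unlabeled
ul    unspliced labeled
su    spliced unlabeled
sl    spliced labeled
====  =============================

All smoothing and neighborhood operations are stratified by labeling duration:
cells are only ever compared with cells labeled for the same length of time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LAYER_NAMES",
    "LabelingExperiment",
    "Neighborhoods",
    "compute_size_factors",
    "build_knn",
    "knn_smooth",
    "pca_representation",
    "load_config",
]

LAYER_NAMES = ("new", "total", "uu", "ul", "su", "sl")

#: layer pairs (small, large) that must satisfy small <= large entrywise
_ORDER_CONSTRAINTS = (("new", "total"), ("ul", "new"), ("sl", "new"))

DEFAULT_CONFIG = {
    "time_unit": "hours",
    "knn": {"k": 30, "n_pcs": 30},
    "size_factor": {"reference": "median"},
}


def load_config(path) -> dict:
    """Read a YAML config and fill in defaults (time_unit, knn.*, size_factor.*)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def compute_size_factors(total_counts, reference: str = "median") -> np.ndarray:
    """Per-cell size factors ``p_j = n_j / n_0``.

    ``n_j`` is the cell's total molecule count and ``n_0`` the median (default)
    or max of the ``n_j``.  Under the median convention values above 1 are
    permitted; switching to ``max`` rescales every ``p_j`` by a common constant
    (which rescales transcription-rate estimates but nothing else downstream).
    """
    counts = np.asarray(total_counts)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("total_counts must be a non-empty cells x genes matrix")
    n_j = counts.sum(axis=1).astype(float)
    zero = np.flatnonzero(n_j == 0)
    if zero.size:
        raise ValueError(f"cells with zero total counts: {zero.tolist()}")
    if reference == "median":
        n_0 = np.median(n_j)
    elif reference == "max":
        n_0 = n_j.max()
    else:
        raise ValueError("reference must be 'median' or 'max'")
    return n_j / n_0


@dataclass
class Neighborhoods:
    """Duration-stratified kNN sets: ``indices[j]`` lists cell j's neighborhood
    (cell j itself first), never crossing labeling durations."""

    indices: list  # list of 1-D int arrays, one per cell

    def __len__(self) -> int:
        return len(self.indices)

    def __getitem__(self, j: int) -> np.ndarray:
        return self.indices[j]


def build_knn(representation, k: int, durations=None) -> Neighborhoods:
    """k nearest neighbors (including self) by Euclidean distance.

    Neighborhoods are restricted to cells with the same labeling duration
    (``durations`` per cell; ``None`` treats all cells as one stratum).  If a
    stratum holds fewer than ``k`` cells, ``k`` is clipped with a warning.
    Ties are broken deterministically by cell index.
    """
    X = np.asarray(representation, dtype=float)
    if X.ndim != 2:
        raise ValueError("representation must be cells x d")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if durations is None:
        durations = np.zeros(n)
    durations = np.asarray(durations)
    indices: list = [None] * n
    for value in np.unique(durations):
        members = np.flatnonzero(durations == value)
        if members.size == 0:
            continue
        k_eff = k
        if members.size < k:
            warnings.warn(
                f"duration {value!r} has {members.size} cells < k={k}; clipping",
                stacklevel=2,
            )
            k_eff = members.size
        sub = X[members]
        from scipy.spatial.distance import cdist

        d2 = cdist(sub, sub, metric="sqeuclidean")
        for row, j in enumerate(members):
            order = np.lexsort((members, d2[row]))  # distance, then index
            neigh = members[order[:k_eff]]
            # guarantee self first (distance 0 ties broken by index)
            neigh = np.concatenate(([j], neigh[neigh != j]))[:k_eff]
            indices[j] = neigh
    return Neighborhoods(indices=indices)


def knn_smooth(experiment: "LabelingExperiment", neighborhoods: Neighborhoods, layers=None) -> dict:
    """Neighborhood mean of depth-normalized counts.

    For each requested layer x returns ``x_bar_j = mean_{i in N_j} x_i / p_i``.
    With k = 1 this is exactly per-cell depth normalization.
    """
    if layers is None:
        layers = [name for name in LAYER_NAMES if name in experiment.layers]
    n = experiment.n_cells
    if len(neighborhoods) != n:
        raise ValueError("neighborhoods do not match the experiment")
    p = experiment.size_factor
    out = {}
    for name in layers:
        x = experiment.layers[name] / p[:, None]
        sm = np.empty_like(x, dtype=float)
        for j in range(n):
            neigh = neighborhoods[j]
            if np.any(neigh >= n) or np.any(neigh < 0):
                raise ValueError("neighborhood references a cell outside the experiment")
            sm[j] = x[neigh].mean(axis=0)
        out[name] = sm
    return out


def pca_representation(experiment: "LabelingExperiment", n_pcs: int = 30, layer: str = "total") -> np.ndarray:
    """Default kNN space: top principal components of log1p depth-normalized
    counts (deterministic full SVD)."""
    from sklearn.decomposition import PCA

    x = np.log1p(experiment.layers[layer] / experiment.size_factor[:, None])
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs < 1:
        return x - x.mean(axis=0)
    return PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)


@dataclass
class LabelingExperiment:
    """Count layers plus per-cell labeling duration and size factor."""

    layers: dict
    labeling_duration: np.ndarray  # hours, one per cell
    obs: pd.DataFrame = None
    var_names: np.ndarray = None
    size_factor: np.ndarray = None
    ground_truth: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        self.layers = {k: np.asarray(v) for k, v in self.layers.items()}
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError("all layers must share one cells x genes shape")
        n, g = shapes.pop()
        self.labeling_duration = np.asarray(self.labeling_duration, dtype=float)
        if self.labeling_duration.shape != (n,):
            raise ValueError("labeling_duration must have one entry per cell")
        if np.any(self.labeling_duration <= 0) or not np.all(np.isfinite(self.labeling_duration)):
            raise ValueError("labeling durations must be positive and finite")
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.RangeIndex(n).astype(str))
        if self.var_names is None:
            self.var_names = np.array([f"gene_{i}" for i in range(g)])
        else:
            self.var_names = np.asarray(self.var_names)
        if self.size_factor is not None:
            self.size_factor = np.asarray(self.size_factor, dtype=float)
        self.validate()

    # ---- basic facts -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    @property
    def n_genes(self) -> int:
        return next(iter(self.layers.values())).shape[1]

    @property
    def durations(self) -> np.ndarray:
        """The experiment's duration set {t_1 ... t_K}, sorted."""
        return np.unique(self.labeling_duration)

    def validate(self) -> None:
        for name, mat in self.layers.items():
            if not np.issubdtype(mat.dtype, np.number):
                raise ValueError(f"layer {name!r} is not numeric")
            if np.any(mat < 0):
                raise ValueError(f"layer {name!r} has negative entries")
            if np.any(np.asarray(mat, dtype=float) % 1 != 0):
                raise ValueError(f"layer {name!r} has non-integer entries")
        for small, large in _ORDER_CONSTRAINTS:
            if small in self.layers and large in self.layers:
                if np.any(self.layers[small] > self.layers[large]):
                    raise ValueError(f"layer {small!r} exceeds layer {large!r}")
        if self.size_factor is not None:
            if self.size_factor.shape != (self.n_cells,):
                raise ValueError("size_factor must have one entry per cell")
            if np.any(~np.isfinite(self.size_factor)) or np.any(self.size_factor <= 0):
                raise ValueError("size factors must be strictly positive and finite")

    # ---- preprocessing ---------------------------------------------------
    def attach_size_factors(self, reference: str = "median", strict: bool = True) -> "LabelingExperiment":
        """Compute and store size factors from the total layer.

        In strict mode cells with zero total count raise; otherwise they are
        dropped with a warning (pipeline mode).
        """
        total = self.layers["total"] if "total" in self.layers else sum(
            self.layers[k] for k in ("uu", "ul", "su", "sl") if k in self.layers
        )
        n_j = np.asarray(total).sum(axis=1)
        zero = np.flatnonzero(n_j == 0)
        if zero.size and not strict:
            warnings.warn(f"dropping {zero.size} cells with zero total counts", stacklevel=2)
            keep = n_j > 0
            return self.subset_cells(keep).attach_size_factors(reference, strict=True)
        self.size_factor = compute_size_factors(np.asarray(total), reference=reference)
        self.obs = self.obs.assign(size_factor=self.size_factor)
        return self

    def subset_cells(self, mask) -> "LabelingExperiment":
        mask = np.asarray(mask)
        return LabelingExperiment(
            layers={k: v[mask] for k, v in self.layers.items()},
            labeling_duration=self.labeling_duration[mask],
            obs=self.obs.iloc[mask] if mask.dtype == bool else self.obs.iloc[mask],
            var_names=self.var_names,
            size_factor=None if self.size_factor is None else self.size_factor[mask],
            ground_truth=self.ground_truth,
        )

    # ---- I/O -------------------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        obs = self.obs.copy()
        obs["labeling_duration"] = self.labeling_duration
        if self.size_factor is not None:
            obs["size_factor"] = self.size_factor
        X = self.layers.get("total", next(iter(self.layers.values())))
        adata = ad.AnnData(X=np.asarray(X, dtype=float), obs=obs)
        adata.var_names = [str(v) for v in self.var_names]
        for name, mat in self.layers.items():
            adata.layers[name] = np.asarray(mat)
        return adata

    @classmethod
    def from_anndata(cls, adata, time_unit: str = "hours") -> "LabelingExperiment":
        layers = {k: np.asarray(adata.layers[k]) for k in LAYER_NAMES if k in adata.layers}
        if not layers:
            raise ValueError(f"no recognized layers among {LAYER_NAMES}")
        dur = np.asarray(adata.obs["labeling_duration"], dtype=float)
        if time_unit == "minutes":
            dur = dur / 60.0
        elif time_unit != "hours":
            raise ValueError("time_unit must be 'hours' or 'minutes'")
        sf = np.asarray(adata.obs["size_factor"], dtype=float) if "size_factor" in adata.obs else None
        return cls(
            layers=layers,
            labeling_duration=dur,
            obs=adata.obs.drop(columns=[c for c in ("labeling_duration", "size_factor") if c in adata.obs]),
            var_names=np.asarray(adata.var_names),
            size_factor=sf,
        )

    def write_h5ad(self, path) -> None:
        self.to_anndata().write_h5ad(path)

    @classmethod
    def read_h5ad(cls, path, time_unit: str = "hours") -> "LabelingExperiment":
        import anndata as ad

        return cls.from_anndata(ad.read_h5ad(path), time_unit=time_unit)

    @classmethod
    def read_csv_dir(cls, directory, time_unit: str = "hours") -> "LabelingExperiment":
        """Read ``<layer>.csv`` matrices plus ``cells.csv`` metadata
        (columns ``cell_id``, ``labeling_duration``) from a directory."""
        from pathlib import Path

        directory = Path(directory)
        meta = pd.read_csv(directory / "cells.csv")
        layers = {}
        for name in LAYER_NAMES:
            f = directory / f"{name}.csv"
            if f.exists():
                layers[name] = pd.read_csv(f, index_col=0).to_numpy()
        if not layers:
            raise ValueError(f"no layer CSVs found in {directory}")
        dur = meta["labeling_duration"].to_numpy(dtype=float)
        if time_unit == "minutes":
            dur = dur / 60.0
        return cls(
            layers=layers,
            labeling_duration=dur,
            obs=meta.set_index("cell_id"),
        )
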