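"""Shared data containers, validation and array/table I/O for the MELD pipeline.

The pipeline operates on a trial-level design table (subject id, item id,
named covariates) aligned row-for-row with a trials x features numeric
matrix ``Y``.  Feature maps are stored flat (row-major, 0-based) with the
feature-space geometry carried alongside, so that cluster enhancement and
back-projection always agree on indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "FeatureSpace",
    "TfceParams",
    "MeldConfig",
    "MeldDataset",
    "MeldResult",
    "load_dataset",
    "save_result",
    "load_result",
]


@dataclass(frozen=True)
class FeatureSpace:
    """Geometry of the feature lattice: shape plus neighbor structure.

    ``adjacency`` is either a lattice rule ("lattice-orthogonal" /
    "lattice-diagonal") applied to ``shape``, or an explicit symmetric,
    irreflexive neighbor list over flattened (row-major, 0-based) feature
    indices, given as an (m, 2) integer array of index pairs.
    """

    shape: tuple[int, ...]
    adjacency: str | np.ndarray = "lattice-orthogonal"

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if not shape or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be positive integers, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        adj = self.adjacency
        if isinstance(adj, str):
            if adj not in ("lattice-orthogonal", "lattice-diagonal"):
                raise ValueError(f"unknown adjacency rule {adj!r}")
        else:
            pairs = np.asarray(adj, dtype=np.int64)
            if pairs.ndim != 2 or pairs.shape[1] != 2:
                raise ValueError("explicit adjacency must be an (m, 2) index array")
            n = self.n_features
            if pairs.size and (pairs.min() < 0 or pairs.max() >= n):
                raise ValueError("adjacency indices out of range")
            if np.any(pairs[:, 0] == pairs[:, 1]):
                raise ValueError("adjacency must be irreflexive (no self loops)")
            # canonicalize: undirected unique edges, sorted
            lo = np.minimum(pairs[:, 0], pairs[:, 1])
            hi = np.maximum(pairs[:, 0], pairs[:, 1])
            edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
            object.__setattr__(self, "adjacency", edges)

    @property
    def n_features(self) -> int:
        return int(np.prod(self.shape))

    @property
    def is_lattice(self) -> bool:
        return isinstance(self.adjacency, str)

    def edge_list(self) -> np.ndarray:
        """Undirected edge list (m, 2), materialized for lattice rules too."""
        if not self.is_lattice:
            return self.adjacency
        idx = np.arange(self.n_features).reshape(self.shape)
        edges = []
        ndim = len(self.shape)
        if self.adjacency == "lattice-orthogonal":
            offsets = [
                tuple(1 if d == a else 0 for d in range(ndim)) for a in range(ndim)
            ]
        else:
            from itertools import product

            offsets = [
                off
                for off in product((-1, 0, 1), repeat=ndim)
                if any(off) and off > tuple(0 for _ in off)
            ]
        for off in offsets:
            src = idx[tuple(slice(None, -o if o else None) for o in off)]
            dst = idx[tuple(slice(o if o else None, None) for o in off)]
            edges.append(np.stack([src.ravel(), dst.ravel()], axis=1))
        out = np.concatenate(edges, axis=0)
        lo = np.minimum(out[:, 0], out[:, 1])
        hi = np.maximum(out[:, 0], out[:, 1])
        return np.unique(np.stack([lo, hi], axis=1), axis=0)

    def adjacency_matrix(self) -> sparse.csr_matrix:
        e = self.edge_list()
        n = self.n_features
        data = np.ones(2 * len(e), dtype=np.int8)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


@dataclass(frozen=True)
class TfceParams:
    """Threshold-free cluster enhancement parameters.

    E and H are the extent and height exponents; dt is the threshold step in
    units of the statistic being enhanced.  Defaults are the values commonly
    recommended for 2-D statistic maps (E=2/3, H=2, dt=0.05).
    """

    E: float = 2.0 / 3.0
    H: float = 2.0
    dt: float = 0.05

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")


@dataclass(frozen=True)
class MeldConfig:
    """Run configuration for the full pipeline."""

    n_permutations: int = 500
    n_bootstraps: int = 1000
    stability_alpha: float = 0.05
    stability_reference: str = "normal"  # or "t" (Student, df = n_subjects-1)
    alpha: float = 0.05
    seed: int = 0
    tfce: TfceParams = field(default_factory=TfceParams)
    tfce_enabled: bool = True
    n_jobs: int = 1

    def __post_init__(self):
        if not (0 < self.stability_alpha < 1):
            raise ValueError("stability_alpha must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")


class MeldDataset:
    """Aligned design table and trials x features matrix.

    On construction the trials are stably sorted by subject label so subject
    blocks are contiguous; within a subject the original trial order is
    preserved.  Subjects are identified by string labels; integer codes
    follow sorted label order.
    """

    def __init__(
        self,
        design: pd.DataFrame,
        Y: np.ndarray,
        feature_space: FeatureSpace,
        subject_col: str = "subject",
    ):
        Y = np.asarray(Y, dtype=np.float64)
        if Y.ndim != 2:
            raise ValueError("Y must be 2-D (trials x features)")
        if len(design) != Y.shape[0]:
            raise ValueError(
                f"design has {len(design)} rows but Y has {Y.shape[0]} rows"
            )
        if subject_col not in design.columns:
            raise ValueError(f"design is missing required column {subject_col!r}")
        if Y.shape[1] != feature_space.n_features:
            raise ValueError(
                f"Y has {Y.shape[1]} features but feature space implies "
                f"{feature_space.n_features}"
            )
        if not np.all(np.isfinite(Y)):
            raise ValueError("Y contains non-finite values")
        if design[subject_col].isna().any():
            raise ValueError("missing subject ids in design")

        design = design.copy()
        design[subject_col] = design[subject_col].astype(str)
        order = np.argsort(design[subject_col].to_numpy(), kind="stable")
        self.design = design.iloc[order].reset_index(drop=True)
        self.Y = Y[order]
        self.feature_space = feature_space
        self.subject_col = subject_col

        labels = self.design[subject_col].to_numpy()
        self.subjects = np.unique(labels)  # sorted
        self.subject_codes = np.searchsorted(self.subjects, labels)

    @property
    def n_trials(self) -> int:
        return self.Y.shape[0]

    @property
    def n_features(self) -> int:
        return self.Y.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_slices(self) -> list[slice]:
        """Contiguous row slice for each subject, in sorted subject order."""
        bounds = np.searchsorted(
            self.design[self.subject_col].to_numpy(), self.subjects, side="left"
        )
        bounds = np.append(bounds, self.n_trials)
        return [slice(int(bounds[i]), int(bounds[i + 1])) for i in range(self.n_subjects)]


@dataclass
class MeldResult:
    """Output of a full MELD run.

    ``t_map`` is the back-projected t-value map for the true data
    (n_terms x n_features); ``perm_max_t`` the per-permutation, per-term
    max-|t| null; ``p_term`` the term-level empirical p maps; ``p`` the
    final (across-term corrected) p maps; ``mask`` significance at alpha.
    """

    terms: list[str]
    t_map: np.ndarray
    perm_max_t: np.ndarray
    p_term: np.ndarray
    min_p_null: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    feature_shape: tuple[int, ...]
    alpha: float
    seed: int
    n_permutations: int
    degenerate_perms: np.ndarray
    degenerate_true: bool = False


def load_dataset(
    design_path: str | Path,
    data_path: str | Path,
    feature_shape: tuple[int, ...],
    adjacency: str | np.ndarray = "lattice-orthogonal",
    subject_col: str = "subject",
) -> MeldDataset:
    """Load a design CSV and a feature matrix (HDF5 dataset "Y" or .npy).

    Validation (row counts, required columns, numeric Y, shape product)
    happens before any computation.
    """
    design_path, data_path = Path(design_path), Path(data_path)
    if not design_path.exists():
        raise FileNotFoundError(design_path)
    if not data_path.exists():
        raise FileNotFoundError(data_path)
    design = pd.read_csv(design_path)
    if data_path.suffix == ".npy":
        Y = np.load(data_path)
    else:
        with h5py.File(data_path, "r") as f:
            Y = f["Y"][()]
    if not np.issubdtype(np.asarray(Y).dtype, np.number):
        raise ValueError("Y must be numeric")
    fs = FeatureSpace(feature_shape, adjacency)
    return MeldDataset(design, Y, fs, subject_col=subject_col)


def save_dataset(dataset: MeldDataset, design_path: str | Path, data_path: str | Path):
    """Write the design as CSV and Y as an HDF5 file (dataset "Y")."""
    dataset.design.to_csv(design_path, index=False)
    with h5py.File(data_path, "w") as f:
        f.create_dataset("Y", data=dataset.Y)


_RESULT_ARRAYS = (
    "t_map",
    "perm_max_t",
    "p_term",
    "min_p_null",
    "p",
    "mask",
    "degenerate_perms",
)


def save_result(result: MeldResult, path: str | Path) -> None:
    """Serialize a MeldResult to HDF5; round-trips all numeric fields."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory {path.parent} does not exist")
    with h5py.File(path, "w") as f:
        for name in _RESULT_ARRAYS:
            f.create_dataset(name, data=np.asarray(getattr(result, name)))
        f.attrs["terms"] = [str(t) for t in result.terms]
        f.attrs["feature_shape"] = result.feature_shape
        f.attrs["alpha"] = result.alpha
        f.attrs["seed"] = result.seed
        f.attrs["n_permutations"] = result.n_permutations
        f.attrs["degenerate_true"] = result.degenerate_true


def load_result(path: str | Path) -> MeldResult:
    with h5py.File(path, "r") as f:
        arrays = {name: f[name][()] for name in _RESULT_ARRAYS}
        return MeldResult(
            terms=[str(t) for t in f.attrs["terms"]],
            feature_shape=tuple(int(s) for s in f.attrs["feature_shape"]),
            alpha=float(f.attrs["alpha"]),
            seed=int(f.attrs["seed"]),
            n_permutations=int(f.attrs["n_permutations"]),
            degenerate_true=bool(f.attrs["degenerate_true"]),
            **arrays,
        )
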