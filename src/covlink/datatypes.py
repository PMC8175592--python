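"""Core in-memory containers shared by the pipeline stages.

Volumes are stored masked: a ``(n_subjects, n_voxels)`` array plus the boolean
grid mask that maps columns back to 3-D voxel positions. All geometries are
isotropic; ``voxel_size`` is in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

REQUIRED_COVARIATES = ("subject_id", "group", "experience_years", "age", "sex")


@dataclass
class VolumeSet:
    """Per-subject gray-matter volume maps sharing one mask and geometry.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_voxels)
        Masked voxel values, one row per subject, columns ordered as
        ``np.flatnonzero(mask)`` (C order).
    mask : ndarray of bool, 3-D
        In-brain voxels.
    voxel_size : float
        Isotropic voxel edge length in mm.
    subject_ids : list of str
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size: float
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D boolean grid")
        if self.data.ndim != 2 or self.data.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with mask "
                f"({int(self.mask.sum())} voxels)"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids must match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def to_grid(self, subject: int, fill: float = 0.0) -> np.ndarray:
        """Scatter one subject's masked values back onto the 3-D grid."""
        grid = np.full(self.mask.shape, fill, dtype=float)
        grid[self.mask] = self.data[subject]
        return grid

    @classmethod
    def from_grids(
        cls,
        grids: np.ndarray,
        mask: np.ndarray,
        voxel_size: float,
        subject_ids: list[str] | None = None,
    ) -> "VolumeSet":
        grids = np.asarray(grids, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if subject_ids is None:
            subject_ids = [f"sub-{i + 1:03d}" for i in range(grids.shape[0])]
        return cls(grids[:, mask], mask, voxel_size, list(subject_ids))


def validate_covariates(covars: pd.DataFrame, volumes: VolumeSet | None = None) -> pd.DataFrame:
    """Check the covariate table schema and (optionally) subject alignment."""
    missing = [c for c in REQUIRED_COVARIATES if c not in covars.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    if covars["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in covariate table")
    if volumes is not None:
        if len(covars) != volumes.n_subjects:
            raise ValueError("covariate rows do not match number of volumes")
        if list(covars["subject_id"]) != list(volumes.subject_ids):
            raise ValueError("covariate subject order differs from volume order")
    return covars


@dataclass
class StatMap:
    """Per-voxel statistic map from a voxelwise GLM contrast."""

    t: np.ndarray  # (n_voxels,) within mask
    p: np.ndarray
    df: int
    mask: np.ndarray

    def t_grid(self) -> np.ndarray:
        grid = np.zeros(self.mask.shape)
        grid[self.mask] = self.t
        return grid


@dataclass
class ClusterSet:
    """Connected suprathreshold voxel clusters (26-neighbourhood, per sign)."""

    labels: np.ndarray  # int grid, 0 = background
    table: pd.DataFrame  # cluster_id, size_voxels, sign, peak_t, peak_x/y/z
    connectivity: int = 26

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class NodeSet:
    """Downsampled gray-matter nodes: block means of in-mask voxels."""

    coords: np.ndarray  # (n_nodes, 3) block indices at downsampled resolution
    values: np.ndarray  # (n_subjects, n_nodes)
    factor: int
    voxel_size: float  # of the *original* grid, mm
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def node_size_mm(self) -> float:
        return self.factor * self.voxel_size

    def world_centers(self) -> np.ndarray:
        """Node block centres in world mm (origin at grid corner)."""
        return (self.coords + 0.5) * self.node_size_mm


@dataclass
class LinkNetwork:
    """Symmetric node x node interaction-statistic network."""

    t: np.ndarray  # (n, n) symmetrized interaction t, zero diagonal
    p: np.ndarray | None  # two-sided p from t distribution, 1 on diagonal
    df: int
    coords: np.ndarray  # node coords, as in NodeSet
    moderator: str
    node_size_mm: float = 1.0

    @property
    def n_nodes(self) -> int:
        return self.t.shape[0]


@dataclass
class LinkClusterSet:
    """Clusters of suprathreshold links; size = number of links."""

    links: np.ndarray  # (n_links, 2) node index pairs, i < j
    cluster_id: np.ndarray  # (n_links,) component id per link
    table: pd.DataFrame  # cluster_id, size_links
    p_threshold: float

    def __len__(self) -> int:
        return len(self.table)

    def link_indices(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_id == cluster)


@dataclass
class DegreeMap:
    """Weighted degree per node: sum of |t| over significant incident links."""

    values: np.ndarray  # (n_nodes,)
    coords: np.ndarray
    node_size_mm: float
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass
class RegionAtlas:
    """Integer region parcellation plus a lookup table.

    ``labels`` uses 0 for background; region ids are 1..n_regions. The lookup
    has columns ``region_id``, ``region_name``, ``category``.
    """

    labels: np.ndarray
    lookup: pd.DataFrame
    voxel_size: float

    def __post_init__(self) -> None:
        if self.lookup["region_id"].duplicated().any():
            raise ValueError("duplicate region ids in atlas lookup")

    @property
    def region_ids(self) -> np.ndarray:
        return self.lookup["region_id"].to_numpy()

    @property
    def n_regions(self) -> int:
        return len(self.lookup)
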