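"""Link-level interaction networks over downsampled gray-matter nodes.

This is the core method: for every ordered node pair (i, j) a moderated
regression

    v_j = b0 + b1 * v_i + b2 * x + b3 * (v_i * x) [+ nuisance] + eps

asks whether the volume coupling between the pair changes with the moderator
x (group membership or years of experience). The link statistic is the t of
the interaction coefficient b3, symmetrized by averaging the two directions.
Family-wise correction adapts the Monte Carlo cluster idea to networks:
clusters are sets of suprathreshold links whose endpoints form spatially
contiguous node groups at both ends, and null link-cluster sizes come from
random networks built from cohorts of smooth noise with the analysis
smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import DegreeMap, LinkClusterSet, LinkNetwork, NodeSet, VolumeSet
from .vbm import cluster_extent_threshold, smoothed_noise


def downsample(volumes: VolumeSet, factor: int) -> NodeSet:
    """Block-mean downsampling to nodes of ``factor^3`` voxels.

    Node value = mean of in-mask voxels in the block; blocks with less than
    50% mask coverage are dropped so edge nodes are not dominated by
    background.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    shape = volumes.grid_shape
    if any(factor > s for s in shape):
        raise ValueError("factor larger than grid")
    pad = [(0, (-s) % factor) for s in shape]
    mask = np.pad(volumes.mask, pad, constant_values=False)
    bshape = tuple(s // factor for s in mask.shape)

    def block_sum(grid: np.ndarray) -> np.ndarray:
        return (
            grid.reshape(bshape[0], factor, bshape[1], factor, bshape[2], factor)
            .sum(axis=(1, 3, 5))
        )

    counts = block_sum(mask.astype(float))
    keep = counts >= 0.5 * factor**3
    coords = np.argwhere(keep)
    if len(coords) == 0:
        raise ValueError("no blocks reach 50% mask coverage")
    n = volumes.n_subjects
    grids = np.zeros((n, *mask.shape))
    grids[:, : shape[0], : shape[1], : shape[2]][:, volumes.mask] = volumes.data
    sums = grids.reshape(n, bshape[0], factor, bshape[1], factor, bshape[2], factor).sum(
        axis=(2, 4, 6)
    )
    values = sums[:, keep] / counts[keep]
    return NodeSet(
        coords=coords,
        values=values,
        factor=factor,
        voxel_size=volumes.voxel_size,
        subject_ids=list(volumes.subject_ids),
    )


def _moderator_vector(covars: pd.DataFrame, moderator: str) -> np.ndarray:
    x = covars[moderator].to_numpy()
    if x.dtype.kind not in "ifub":
        labels = sorted(pd.unique(x))
        if len(labels) > 2:
            raise ValueError(f"moderator {moderator!r} has more than two levels")
        x = np.array([labels.index(v) for v in x], dtype=float)
    x = x.astype(float)
    if np.ptp(x) == 0:
        raise ValueError("moderator is constant across subjects; interaction unidentifiable")
    return x


def fit_link_interaction(
    nodes: NodeSet,
    covars: pd.DataFrame | np.ndarray,
    moderator: str = "experience_years",
    adjust: tuple[str, ...] = (),
    p_values: bool = True,
) -> LinkNetwork:
    """Interaction GLM for every node pair, fully vectorized.

    ``covars`` may be a covariate table (the moderator column is named) or a
    raw moderator vector. Directed t statistics t(i->j) and t(j->i) are
    averaged into a symmetric link t with zero diagonal; p-values come from
    the t distribution at the regression df.
    """
    if isinstance(covars, pd.DataFrame):
        x = _moderator_vector(covars, moderator)
        Z = [covars[a].to_numpy(float) for a in adjust]
    else:
        x = np.asarray(covars, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("moderator is constant across subjects; interaction unidentifiable")
        Z = []
    V = nodes.values  # (n, N)
    n, N = V.shape
    p_base = 4 + len(Z)
    if n <= p_base:
        raise ValueError("fewer subjects than regressors")

    # Design stack: for each source i, columns [1, v_i, x, adjust..., v_i * x]
    D = np.empty((N, n, p_base))
    D[:, :, 0] = 1.0
    D[:, :, 1] = V.T
    D[:, :, 2] = x
    for a, z in enumerate(Z):
        D[:, :, 3 + a] = z
    kk = p_base - 1
    D[:, :, kk] = V.T * x

    Dt = D.transpose(0, 2, 1)  # (N, p, n)
    G = Dt @ D  # (N, p, p)
    # Guard against singular designs (e.g. a constant node) via pseudo-inverse
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        Ginv = np.linalg.pinv(G)
    DtV = Dt @ V  # (N, p, N)
    B = Ginv @ DtV  # coefficients, (N, p, N)
    vv = np.einsum("nj,nj->j", V, V)  # (N,)
    quad = np.einsum("ipj,ipj->ij", B, G @ B)
    df = n - p_base
    rss = np.maximum(vv[None, :] - quad, 0.0)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * Ginv[:, kk, kk][:, None])
        t_dir = np.where(se > 0, B[:, kk, :] / se, 0.0)
    np.fill_diagonal(t_dir, 0.0)
    t_sym = 0.5 * (t_dir + t_dir.T)
    np.fill_diagonal(t_sym, 0.0)
    if p_values:
        p = 2.0 * stats.t.sf(np.abs(t_sym), df)
        np.fill_diagonal(p, 1.0)
    else:
        p = None  # derivable from t and df when needed
    return LinkNetwork(
        t=t_sym,
        p=p,
        df=df,
        coords=nodes.coords,
        moderator=moderator if isinstance(covars, pd.DataFrame) else "moderator",
        node_size_mm=nodes.node_size_mm,
    )


def directed_interaction_coefficients(
    nodes: NodeSet, covars: pd.DataFrame | np.ndarray, moderator: str = "experience_years"
) -> np.ndarray:
    """Directed interaction coefficient b3(i->j) for every pair (diagnostic)."""
    if isinstance(covars, pd.DataFrame):
        x = _moderator_vector(covars, moderator)
    else:
        x = np.asarray(covars, dtype=float)
    V = nodes.values
    n, N = V.shape
    out = np.zeros((N, N))
    for i in range(N):
        X = np.column_stack([np.ones(n), V[:, i], x, V[:, i] * x])
        beta, *_ = np.linalg.lstsq(X, V, rcond=None)
        out[i] = beta[3]
    np.fill_diagonal(out, 0.0)
    return out


def link_cluster(
    network: LinkNetwork,
    link_p_threshold: float = 0.001,
) -> LinkClusterSet:
    """Cluster suprathreshold links into spatially contiguous link groups.

    Links (a, b) and (c, d) belong to the same cluster when their endpoints
    pair up as contiguous node groups: (a~c and b~d) or (a~d and b~c), where
    ~ means identical or 26-adjacent at node resolution. Cluster size is the
    number of links.
    """
    iu = np.triu_indices(network.n_nodes, k=1)
    if network.p is not None:
        supra = network.p[iu] < link_p_threshold
    else:  # equivalent thresholding on |t| at the two-sided critical value
        t_crit = stats.t.isf(link_p_threshold / 2.0, network.df)
        supra = np.abs(network.t[iu]) > t_crit
    links = np.column_stack([iu[0][supra], iu[1][supra]])
    L = len(links)
    if L == 0:
        return LinkClusterSet(
            links=links,
            cluster_id=np.empty(0, dtype=int),
            table=pd.DataFrame(columns=["cluster_id", "size_links"]),
            p_threshold=link_p_threshold,
        )
    A = network.coords[links[:, 0]]  # (L, 3)
    B = network.coords[links[:, 1]]

    def adj(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
        # Chebyshev distance <= 1: identical or 26-adjacent
        return np.abs(P[:, None, :] - Q[None, :, :]).max(axis=2) <= 1

    mates = (adj(A, A) & adj(B, B)) | (adj(A, B) & adj(B, A))
    n_comp, comp = connected_components(coo_matrix(mates), directed=False)
    sizes = np.bincount(comp)
    table = pd.DataFrame(
        {"cluster_id": np.arange(n_comp), "size_links": sizes}
    ).sort_values("size_links", ascending=False, ignore_index=True)
    return LinkClusterSet(links=links, cluster_id=comp, table=table, p_threshold=link_p_threshold)


@dataclass
class NetworkMonteCarloConfig:
    """Random-network null for link-cluster family-wise correction.

    Defaults follow the analysis conventions: 10,000 random networks and a
    link-forming threshold of p < 0.001.
    """

    n_networks: int = 10_000
    link_p_threshold: float = 0.001
    alpha_fwe: float = 0.05
    fwhm_mm: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        for name in ("link_p_threshold", "alpha_fwe"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def null_link_cluster_threshold(
    n_subjects: int,
    mask: np.ndarray,
    factor: int,
    voxel_size: float,
    moderator_values: np.ndarray,
    cfg: NetworkMonteCarloConfig,
    return_null: bool = False,
) -> int | tuple[int, np.ndarray]:
    """FWE link-cluster extent threshold from random networks.

    Each iteration regenerates a null cohort of smoothed noise volumes with
    the analysis smoothing, runs the full downsample + link-interaction fit
    with the real moderator values, and records the maximum link-cluster size
    at the link-forming threshold. Link clusters strictly larger than the
    returned threshold control family-wise error at ``alpha_fwe``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    moderator_values = np.asarray(moderator_values, dtype=float)
    if len(moderator_values) != n_subjects:
        raise ValueError("moderator length must equal n_subjects")
    rng = np.random.default_rng(cfg.seed)
    max_sizes = np.empty(cfg.n_networks, dtype=int)
    for it in range(cfg.n_networks):
        grids = smoothed_noise(mask.shape, cfg.fwhm_mm, voxel_size, rng, n=n_subjects)
        vols = VolumeSet.from_grids(grids, mask, voxel_size)
        nodes = downsample(vols, factor)
        net = fit_link_interaction(nodes, moderator_values, p_values=False)
        clusters = link_cluster(net, cfg.link_p_threshold)
        max_sizes[it] = int(clusters.table["size_links"].max()) if len(clusters) else 0
    thr = cluster_extent_threshold(max_sizes, cfg.alpha_fwe)
    return (thr, max_sizes) if return_null else thr


def significant_links(clusters: LinkClusterSet, threshold: int) -> np.ndarray:
    """Links in clusters strictly larger than ``threshold`` links, (L, 2)."""
    if len(clusters.table) == 0:
        return np.empty((0, 2), dtype=int)
    sizes = np.bincount(clusters.cluster_id)
    keep = sizes[clusters.cluster_id] > max(threshold, 0)
    return clusters.links[keep]


def weighted_degree(network: LinkNetwork, links: np.ndarray) -> DegreeMap:
    """Weighted degree: per node, the sum of |t| over significant links.

    ``links`` is an (L, 2) array of node index pairs (each undirected link
    listed once).
    """
    values = np.zeros(network.n_nodes)
    if len(links):
        links = np.asarray(links, dtype=int)
        w = np.abs(network.t[links[:, 0], links[:, 1]])
        np.add.at(values, links[:, 0], w)
        np.add.at(values, links[:, 1], w)
    return DegreeMap(
        values=values,
        coords=network.coords,
        node_size_mm=network.node_size_mm,
        provenance={"moderator": network.moderator, "n_links": int(len(links))},
    )


def degree_to_grid(degree: DegreeMap, grid_shape: tuple[int, int, int], factor: int) -> np.ndarray:
    """Paint node degrees back onto the original voxel grid for export."""
    grid = np.zeros(grid_shape)
    for (bx, by, bz), v in zip(degree.coords, degree.values):
        grid[
            bx * factor : min((bx + 1) * factor, grid_shape[0]),
            by * factor : min((by + 1) * factor, grid_shape[1]),
            bz * factor : min((bz + 1) * factor, grid_shape[2]),
        ] = v
    return grid
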