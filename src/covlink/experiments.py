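"""Validation experiments: null calibration, planted-effect recovery and
independent-oracle comparisons.

These drive the public pipeline operations on synthetic cohorts at desk
scale and are used both by the test suite and by the reproduction script.
All randomness flows from an explicit base seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import VolumeSet
from .genesets import GeneSetCollection, closeness_centrality, overrepresentation
from .linknet import (
    NetworkMonteCarloConfig,
    downsample,
    fit_link_interaction,
    link_cluster,
    null_link_cluster_threshold,
    significant_links,
)
from .simulate import (
    DEFAULT_ATLAS_COMPOSITION,
    CohortSpec,
    ExpressionBundleSpec,
    FieldSpec,
    PlantedInteraction,
    cube_baseline,
    make_toy_atlas,
    plant_interaction,
    simulate_cohort_volumes,
    simulate_expression_bundle,
)
from .transcriptomics import build_gene_region_matrix, select_genes, spatial_similarity
from .vbm import (
    MonteCarloConfig,
    extract_clusters,
    fit_voxelwise_glm,
    monte_carlo_cluster_threshold,
)


def _seed(base: int, offset: int) -> int:
    return (base * 100_003 + offset) % (2**31)


def vbm_fwe_calibration(
    n_cohorts: int = 100,
    n_iterations: int = 200,
    grid_shape: tuple[int, int, int] = (10, 10, 10),
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Family-wise error of the corrected voxelwise analysis on null cohorts.

    Each cohort is simulated with no group effect, analysed with the group
    contrast (age-adjusted), and corrected with its own Monte Carlo
    cluster-extent threshold; the event counted is "any significant cluster".
    """
    field = FieldSpec(grid_shape=grid_shape, baseline_map=cube_baseline(grid_shape))
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * field.smoothing_sigma
    hits = 0
    for c in range(n_cohorts):
        vols, covars = simulate_cohort_volumes(
            CohortSpec(seed=_seed(base_seed, c)), field, seed=_seed(base_seed, 10_000 + c)
        )
        statmap = fit_voxelwise_glm(vols, covars, contrast="group", adjust=("age",))
        cfg = MonteCarloConfig(
            n_iterations=n_iterations, fwhm_mm=fwhm, alpha_fwe=alpha,
            seed=_seed(base_seed, 20_000 + c),
        )
        thr = monte_carlo_cluster_threshold(vols.mask, fwhm, field.voxel_size, cfg)
        clusters = extract_clusters(statmap, cfg.cluster_forming_p, min_size=thr + 1)
        hits += len(clusters) > 0
    return {"fwe_rate": hits / n_cohorts, "n": n_cohorts}


def link_fwe_calibration(
    n_cohorts: int = 100,
    n_networks: int = 200,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    factor: int = 2,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Family-wise error of the corrected link-cluster analysis on null
    cohorts (6^3 node grid at the default factor)."""
    field = FieldSpec(grid_shape=grid_shape, baseline_map=cube_baseline(grid_shape))
    hits = 0
    for c in range(n_cohorts):
        vols, covars = simulate_cohort_volumes(
            CohortSpec(seed=_seed(base_seed, c)), field, seed=_seed(base_seed, 30_000 + c)
        )
        x = covars["experience_years"].to_numpy()
        cfg = NetworkMonteCarloConfig(
            n_networks=n_networks, alpha_fwe=alpha, seed=_seed(base_seed, 40_000 + c)
        )
        thr = null_link_cluster_threshold(
            vols.n_subjects, vols.mask, factor, field.voxel_size, x, cfg
        )
        net = fit_link_interaction(downsample(vols, factor), x, p_values=False)
        clusters = link_cluster(net, cfg.link_p_threshold)
        hits += len(significant_links(clusters, thr)) > 0
    return {"fwe_rate": hits / n_cohorts, "n": n_cohorts}


def interaction_recovery(
    n_seeds: int = 100,
    gamma: float = 0.8,
    n_networks: int = 100,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    base_seed: int = 0,
) -> dict:
    """Detection rate of a planted coupling x experience interaction.

    Success requires a family-wise-surviving link cluster whose endpoints
    overlap both planted node blocks. Volume noise and the interaction
    residual are kept low so detection is limited by the correction, not by
    measurement error.
    """
    field = FieldSpec(grid_shape=grid_shape, baseline_map=cube_baseline(grid_shape), noise_sd=0.02)
    src = np.array([(x, y, z) for x in (2, 3) for y in range(4, 8) for z in range(4, 8)])
    tgt = np.array([(x, y, z) for x in (8, 9) for y in range(4, 8) for z in range(4, 8)])
    src_nodes = {(1, y, z) for y in (2, 3) for z in (2, 3)}
    tgt_nodes = {(4, y, z) for y in (2, 3) for z in (2, 3)}
    hits = 0
    for c in range(n_seeds):
        vols, covars = simulate_cohort_volumes(
            CohortSpec(seed=_seed(base_seed, c)), field, seed=_seed(base_seed, 50_000 + c)
        )
        planted = plant_interaction(
            vols, covars, PlantedInteraction(src, tgt, gamma=gamma), eps_sd=0.01,
            seed=_seed(base_seed, 60_000 + c),
        )
        x = covars["experience_years"].to_numpy()
        cfg = NetworkMonteCarloConfig(n_networks=n_networks, seed=_seed(base_seed, 70_000 + c))
        thr = null_link_cluster_threshold(
            vols.n_subjects, vols.mask, 2, field.voxel_size, x, cfg
        )
        net = fit_link_interaction(downsample(planted, 2), x, p_values=False)
        clusters = link_cluster(net, cfg.link_p_threshold)
        sig = significant_links(clusters, thr)
        if len(sig):
            nodes = downsample(planted, 2)
            endpoints = {tuple(nodes.coords[i]) for l in sig for i in l}
            hits += bool(endpoints & src_nodes) and bool(endpoints & tgt_nodes)
    return {"recovery_rate": hits / n_seeds, "n": n_seeds}


def gene_recovery(
    n_seeds: int = 20,
    n_genes: int = 200,
    n_targets: int = 10,
    target_r: float = 0.6,
    base_seed: int = 0,
) -> dict:
    """Sensitivity and false positives of the 2-SD similarity selection on
    planted expression bundles over the default 89-region toy atlas."""
    field = FieldSpec()
    atlas = make_toy_atlas(field, DEFAULT_ATLAS_COMPOSITION)
    sens, fps = [], []
    for c in range(n_seeds):
        rng = np.random.default_rng(_seed(base_seed, 80_000 + c))
        degree = rng.uniform(0.0, 10.0, atlas.n_regions)
        spec = ExpressionBundleSpec(
            n_genes=n_genes, n_target_genes=n_targets, target_r=target_r,
            seed=_seed(base_seed, 90_000 + c),
        )
        bundle = simulate_expression_bundle(spec, atlas, degree)
        matrix = build_gene_region_matrix(
            bundle["expression"], bundle["probe_map"], bundle["samples"], atlas
        )
        table = spatial_similarity(matrix, pd.Series(degree, index=atlas.region_ids))
        selected = set(select_genes(table))
        targets = set(bundle["target_genes"])
        sens.append(len(selected & targets) / n_targets)
        fps.append(len(selected - targets))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_positives": float(np.mean(fps)),
        "n": n_seeds,
    }


def oracle_deviations(base_seed: int = 0) -> dict:
    """Max absolute deviation of each statistic from an independent
    brute-force oracle on randomized small instances."""
    import networkx as nx
    from math import comb

    rng = np.random.default_rng(_seed(base_seed, 1))
    out: dict[str, float] = {}

    # Voxelwise GLM t vs per-voxel normal-equation refit
    n, v = 14, 9
    Y = rng.standard_normal((n, v))
    covars = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": rng.integers(0, 2, n),
            "experience_years": rng.uniform(0, 10, n),
            "age": rng.uniform(25, 55, n),
            "sex": rng.integers(0, 2, n),
        }
    )
    if covars["group"].nunique() == 1:
        covars.loc[0, "group"] = 1 - covars.loc[0, "group"]
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask.ravel()[:v] = True
    vols = VolumeSet(Y, mask, 2.0, list(covars["subject_id"]))
    statmap = fit_voxelwise_glm(vols, covars, contrast="group", adjust=("age",))
    X = np.column_stack([np.ones(n), covars["group"], covars["age"]])
    dev = 0.0
    for j in range(v):
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ Y[:, j]
        resid = Y[:, j] - X @ beta
        s2 = resid @ resid / (n - X.shape[1])
        t_ref = beta[1] / np.sqrt(s2 * XtX_inv[1, 1])
        dev = max(dev, abs(statmap.t[j] - t_ref))
    out["glm_t"] = dev

    # Link interaction t vs directed normal-equation refits
    from .datatypes import NodeSet

    N = 6
    V = rng.standard_normal((n, N))
    x = rng.uniform(0, 10, n)
    nodes = NodeSet(coords=np.array([(i, 0, 0) for i in range(N)]), values=V, factor=1,
                    voxel_size=2.0)
    net = fit_link_interaction(nodes, x)

    def directed_t(i, j):
        Xd = np.column_stack([np.ones(n), V[:, i], x, V[:, i] * x])
        XtX_inv = np.linalg.inv(Xd.T @ Xd)
        beta = XtX_inv @ Xd.T @ V[:, j]
        resid = V[:, j] - Xd @ beta
        s2 = resid @ resid / (n - 4)
        return beta[3] / np.sqrt(s2 * XtX_inv[3, 3])

    dev = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            dev = max(dev, abs(net.t[i, j] - 0.5 * (directed_t(i, j) + directed_t(j, i))))
    out["link_t"] = dev

    # Pearson r vs explicit formula
    b = rng.standard_normal(30)
    M = pd.DataFrame(rng.standard_normal((5, 30)), index=list("ABCDE"), columns=range(1, 31))
    tab = spatial_similarity(M, pd.Series(b, index=range(1, 31)))
    dev = 0.0
    for g, row in zip(tab["gene"], M.to_numpy()):
        num = ((row - row.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((row - row.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        dev = max(dev, abs(float(tab.set_index("gene").loc[g, "r"]) - num / den))
    out["pearson_r"] = dev

    # Binomial tail and BH q vs manual summation
    universe = {f"g{i}" for i in range(60)}
    sets = {f"S{i}": {f"g{j}" for j in range(i * 7, i * 7 + 15)} for i in range(4)}
    coll = GeneSetCollection(sets=sets, universe=universe)
    selected = [f"g{i}" for i in rng.choice(60, size=12, replace=False)]
    res = overrepresentation(selected, coll)
    dev_p, dev_q = 0.0, 0.0
    m = len(res)
    p_arr = res["p"].to_numpy()
    order = np.argsort(p_arr, kind="stable")
    manual_q = np.empty(m)
    prev = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        prev = min(prev, p_arr[i] * m / (pos + 1))
        manual_q[i] = prev
    for idx, row in res.iterrows():
        k, nn, p0 = int(row["k"]), int(row["n"]), float(row["p0"])
        manual_p = sum(comb(nn, i) * p0**i * (1 - p0) ** (nn - i) for i in range(k, nn + 1))
        dev_p = max(dev_p, abs(row["p"] - manual_p))
        dev_q = max(dev_q, abs(row["q"] - manual_q[idx]))
    out["binomial_p"] = dev_p
    out["bh_q"] = dev_q

    # Link-cluster partition vs brute-force union-find
    from .datatypes import LinkNetwork

    coords = np.array([(xx, yy, 0) for xx in range(4) for yy in range(4)])
    nn = len(coords)
    t = np.zeros((nn, nn))
    iu = np.triu_indices(nn, 1)
    pick = rng.choice(len(iu[0]), size=15, replace=False)
    for k in pick:
        t[iu[0][k], iu[1][k]] = t[iu[1][k], iu[0][k]] = 6.0
    p = np.where(np.abs(t) > 0, 1e-6, 1.0)
    lnet = LinkNetwork(t=t, p=p, df=27, coords=coords, moderator="x")
    clusters = link_cluster(lnet, 0.001)
    links = [tuple(l) for l in clusters.links]
    parent = list(range(len(links)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    def adj(u, w):
        return np.abs(coords[u] - coords[w]).max() <= 1

    for i in range(len(links)):
        for j in range(i + 1, len(links)):
            (aa, bb), (cc, dd) = links[i], links[j]
            if (adj(aa, cc) and adj(bb, dd)) or (adj(aa, dd) and adj(bb, cc)):
                parent[find(i)] = find(j)
    oracle_parts = {}
    for i in range(len(links)):
        oracle_parts.setdefault(find(i), set()).add(i)
    ours = {}
    for i, cid in enumerate(clusters.cluster_id):
        ours.setdefault(int(cid), set()).add(i)
    same = sorted(map(sorted, oracle_parts.values())) == sorted(map(sorted, ours.values()))
    out["link_cluster_partition"] = 0.0 if same else 1.0

    # Closeness vs Floyd-Warshall
    g = nx.gnp_random_graph(12, 0.3, seed=int(_seed(base_seed, 2) % 10_000))
    cc_table = closeness_centrality(g).set_index("gene")["closeness"]
    INF = float("inf")
    dist = [[0 if i == j else INF for j in range(12)] for i in range(12)]
    for u, w in g.edges:
        dist[u][w] = dist[w][u] = 1
    for k in range(12):
        for i in range(12):
            for j in range(12):
                dist[i][j] = min(dist[i][j], dist[i][k] + dist[k][j])
    dev = 0.0
    for vtx in range(12):
        reach = [dist[vtx][u] for u in range(12) if u != vtx and dist[vtx][u] < INF]
        expected = len(reach) / sum(reach) if reach else 0.0
        dev = max(dev, abs(cc_table[vtx] - expected))
    out["closeness"] = dev

    out["max_deviation"] = max(
        out["glm_t"], out["link_t"], out["pearson_r"], out["binomial_p"], out["bh_q"],
        out["link_cluster_partition"], out["closeness"],
    )
    return out
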