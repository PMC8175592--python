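"""Downsampling, link-interaction networks, link clustering and degree maps."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from covlink.datatypes import LinkNetwork, NodeSet, VolumeSet
from covlink.linknet import (
    NetworkMonteCarloConfig,
    downsample,
    fit_link_interaction,
    link_cluster,
    null_link_cluster_threshold,
    significant_links,
    weighted_degree,
)
from covlink.simulate import (
    CohortSpec,
    FieldSpec,
    PlantedInteraction,
    cube_baseline,
    plant_interaction,
    simulate_cohort_volumes,
)


def _volumes_from_grids(grids, voxel_size=2.0):
    grids = np.asarray(grids, dtype=float)
    mask = np.ones(grids.shape[1:], dtype=bool)
    return VolumeSet.from_grids(grids, mask, voxel_size)


class TestDownsample:
    def test_constant_volume_gives_constant_nodes(self):
        vols = _volumes_from_grids(np.full((3, 6, 6, 6), 2.5))
        nodes = downsample(vols, 2)
        np.testing.assert_allclose(nodes.values, 2.5)
        assert nodes.n_nodes == 27

    def test_block_mean_of_1_to_27(self):
        grid = np.arange(1.0, 28.0).reshape(3, 3, 3)
        nodes = downsample(_volumes_from_grids(grid[None]), 3)
        assert nodes.values[0, 0] == pytest.approx(14.0)

    def test_matches_brute_force_block_means(self, rng):
        grids = rng.standard_normal((4, 6, 6, 6))
        nodes = downsample(_volumes_from_grids(grids), 2)
        for k, (bx, by, bz) in enumerate(nodes.coords):
            expected = grids[
                :, 2 * bx : 2 * bx + 2, 2 * by : 2 * by + 2, 2 * bz : 2 * bz + 2
            ].mean(axis=(1, 2, 3))
            np.testing.assert_allclose(nodes.values[:, k], expected, atol=1e-12)

    def test_low_coverage_blocks_dropped(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2, :2, :2] = True  # one full block
        mask[2, 2, 2] = True  # 1/8 coverage block
        grids = np.ones((2, 4, 4, 4))
        vols = VolumeSet.from_grids(grids, mask, 2.0)
        nodes = downsample(vols, 2)
        assert nodes.n_nodes == 1
        np.testing.assert_array_equal(nodes.coords, [[0, 0, 0]])

    def test_factor_larger_than_grid_rejected(self):
        vols = _volumes_from_grids(np.ones((1, 4, 4, 4)))
        with pytest.raises(ValueError):
            downsample(vols, 5)


class TestLinkInteraction:
    def test_symmetric_with_zero_diagonal(self, cohort31):
        vols, covars = cohort31
        net = fit_link_interaction(downsample(vols, 4), covars)
        np.testing.assert_array_equal(net.t, net.t.T)
        assert np.all(np.diag(net.t) == 0)
        assert np.all(np.diag(net.p) == 1)
        assert np.all((net.p >= 0) & (net.p <= 1))

    def test_noiseless_planted_gamma_recovered(self):
        """Fitting the generating pair with eps = 0 returns gamma exactly."""
        field = FieldSpec(grid_shape=(8, 8, 8), baseline_map=cube_baseline((8, 8, 8)))
        vols, covars = simulate_cohort_volumes(CohortSpec(seed=5), field, seed=6)
        src = np.array([(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)])
        tgt = np.array([(x, y, z) for x in (4, 5) for y in (0, 1) for z in (0, 1)])
        spec = PlantedInteraction(src, tgt, gamma=0.7, alpha=0.2, beta=1.1)
        planted = plant_interaction(vols, covars, spec, eps_sd=0.0)
        nodes = downsample(planted, 2)
        x = covars["experience_years"].to_numpy()
        x = (x - x.mean()) / x.std()
        i = int(np.flatnonzero((nodes.coords == (0, 0, 0)).all(axis=1))[0])
        j = int(np.flatnonzero((nodes.coords == (2, 0, 0)).all(axis=1))[0])
        V = nodes.values
        X = np.column_stack([np.ones(len(x)), V[:, i], x, V[:, i] * x])
        beta = np.linalg.lstsq(X, V[:, j], rcond=None)[0]
        assert beta[3] == pytest.approx(spec.gamma, abs=1e-9)

    def test_matches_statsmodels_on_all_pairs(self, rng):
        """Symmetrized link t equals the mean of the two directed OLS t's."""
        n, N = 31, 6
        values = rng.standard_normal((n, N))
        x = rng.uniform(0, 10, n)
        nodes = NodeSet(
            coords=np.array([(i, 0, 0) for i in range(N)]), values=values, factor=1,
            voxel_size=2.0,
        )
        net = fit_link_interaction(nodes, x)

        def directed_t(i, j):
            X = np.column_stack([np.ones(n), values[:, i], x, values[:, i] * x])
            return sm.OLS(values[:, j], X).fit().tvalues[3]

        for i in range(N):
            for j in range(i + 1, N):
                expected = 0.5 * (directed_t(i, j) + directed_t(j, i))
                assert net.t[i, j] == pytest.approx(expected, abs=1e-10)

    def test_constant_moderator_rejected(self, cohort31):
        vols, covars = cohort31
        nodes = downsample(vols, 4)
        with pytest.raises(ValueError, match="constant"):
            fit_link_interaction(nodes, np.full(vols.n_subjects, 3.0))


class TestLinkCluster:
    @staticmethod
    def _network(coords, t_pairs, n=None, df=27):
        """Build a LinkNetwork with the given suprathreshold t values."""
        coords = np.asarray(coords)
        n = n or len(coords)
        t = np.zeros((n, n))
        p = np.ones((n, n))
        for (i, j), tv in t_pairs.items():
            t[i, j] = t[j, i] = tv
            p[i, j] = p[j, i] = 1e-6
        return LinkNetwork(t=t, p=p, df=df, coords=coords, moderator="x")

    def test_single_link_single_cluster(self):
        net = self._network([(0, 0, 0), (5, 5, 5)], {(0, 1): 4.0})
        clusters = link_cluster(net, 0.001)
        assert len(clusters) == 1
        assert clusters.table.loc[0, "size_links"] == 1

    def test_adjacent_endpoint_links_merge(self):
        """(a,b) and (a',b') with a'~a and b'~b form one cluster of 2."""
        coords = [(0, 0, 0), (1, 0, 0), (5, 5, 5), (5, 5, 6)]
        net = self._network(coords, {(0, 2): 4.0, (1, 3): 4.0})
        clusters = link_cluster(net, 0.001)
        assert len(clusters) == 1
        assert clusters.table.loc[0, "size_links"] == 2

    def test_crossed_endpoint_links_merge(self):
        """The (a~d and b~c) orientation also makes cluster-mates."""
        coords = [(0, 0, 0), (1, 0, 0), (5, 5, 5), (5, 5, 6)]
        net = self._network(coords, {(0, 2): 4.0, (3, 1): 4.0})
        clusters = link_cluster(net, 0.001)
        assert len(clusters) == 1

    def test_disjoint_endpoint_groups_stay_separate(self):
        coords = [(0, 0, 0), (5, 0, 0), (0, 5, 5), (5, 5, 5)]
        net = self._network(coords, {(0, 1): 4.0, (2, 3): 4.0})
        clusters = link_cluster(net, 0.001)
        assert len(clusters) == 2
        assert set(clusters.table["size_links"]) == {1}

    def test_matches_brute_force_union_find(self, rng):
        """Random sparse networks partition exactly as a brute-force oracle."""
        coords = np.array([(x, y, 0) for x in range(4) for y in range(4)])
        n = len(coords)
        t = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        pick = rng.choice(len(iu[0]), size=18, replace=False)
        for k in pick:
            i, j = iu[0][k], iu[1][k]
            t[i, j] = t[j, i] = 5.0
        p = np.where(np.abs(t) > 0, 1e-6, 1.0)
        net = LinkNetwork(t=t, p=p, df=27, coords=coords, moderator="x")
        clusters = link_cluster(net, 0.001)

        links = [tuple(l) for l in clusters.links]

        def mates(l1, l2):
            (a, b), (c, d) = l1, l2
            adj = lambda u, v: np.abs(coords[u] - coords[v]).max() <= 1
            return (adj(a, c) and adj(b, d)) or (adj(a, d) and adj(b, c))

        parent = list(range(len(links)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(links)):
            for j in range(i + 1, len(links)):
                if mates(links[i], links[j]):
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(len(links)):
            oracle.setdefault(find(i), set()).add(i)
        ours = {}
        for i, c in enumerate(clusters.cluster_id):
            ours.setdefault(int(c), set()).add(i)
        assert sorted(map(sorted, oracle.values())) == sorted(map(sorted, ours.values()))


class TestWeightedDegree:
    def test_hand_example(self):
        coords = np.array([(i, 0, 0) for i in range(4)])
        t = np.zeros((4, 4))
        t[1, 2] = t[2, 1] = 2.0
        t[1, 3] = t[3, 1] = -3.0
        net = LinkNetwork(t=t, p=None, df=27, coords=coords, moderator="x")
        deg = weighted_degree(net, np.array([(1, 2), (1, 3)]))
        np.testing.assert_allclose(deg.values, [0.0, 5.0, 2.0, 3.0])

    def test_empty_links_all_zero(self):
        coords = np.array([(i, 0, 0) for i in range(3)])
        net = LinkNetwork(t=np.zeros((3, 3)), p=None, df=27, coords=coords, moderator="x")
        deg = weighted_degree(net, np.empty((0, 2), dtype=int))
        np.testing.assert_array_equal(deg.values, 0.0)

    def test_matches_incident_sum_oracle(self, rng):
        n = 10
        t = rng.standard_normal((n, n))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 0)
        coords = np.array([(i, 0, 0) for i in range(n)])
        net = LinkNetwork(t=t, p=None, df=27, coords=coords, moderator="x")
        iu = np.triu_indices(n, 1)
        pick = rng.choice(len(iu[0]), size=12, replace=False)
        links = np.array([(iu[0][k], iu[1][k]) for k in pick])
        deg = weighted_degree(net, links)
        for v in range(n):
            expected = sum(abs(t[a, b]) for a, b in links if v in (a, b))
            assert deg.values[v] == pytest.approx(expected, abs=1e-12)

    @given(st.permutations(list(range(6))))
    def test_permutation_equivariance(self, perm):
        """Relabeling nodes permutes degree values without changing them."""
        rng = np.random.default_rng(99)
        t = rng.standard_normal((6, 6))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 0)
        coords = np.array([(i, 0, 0) for i in range(6)])
        links = np.array([(0, 1), (1, 2), (3, 4)])
        net = LinkNetwork(t=t, p=None, df=27, coords=coords, moderator="x")
        deg = weighted_degree(net, links)

        perm = np.asarray(perm)
        t2 = t[np.ix_(perm, perm)]
        links2 = np.array([(np.flatnonzero(perm == a)[0], np.flatnonzero(perm == b)[0])
                           for a, b in links])
        net2 = LinkNetwork(t=t2, p=None, df=27, coords=coords[perm], moderator="x")
        deg2 = weighted_degree(net2, links2)
        np.testing.assert_allclose(deg2.values, deg.values[perm], atol=1e-12)


class TestNullThreshold:
    def test_single_network_threshold_is_that_max(self, cube_field):
        x = np.linspace(0, 10, 31)
        cfg = NetworkMonteCarloConfig(n_networks=1, seed=3)
        thr, null = null_link_cluster_threshold(
            31, cube_field.mask(), 2, 2.0, x, cfg, return_null=True
        )
        assert thr == null[0]

    def test_threshold_nondecreasing_in_fwhm(self, cube_field):
        x = np.linspace(0, 10, 31)
        thresholds = []
        for fwhm in (0.0, 4.0):
            cfg = NetworkMonteCarloConfig(n_networks=100, fwhm_mm=fwhm, seed=21)
            thresholds.append(
                null_link_cluster_threshold(31, cube_field.mask(), 2, 2.0, x, cfg)
            )
        assert thresholds[0] <= thresholds[1]

    def test_planted_cluster_recovered_over_null(self):
        """gamma = 0.8 between two node blocks survives the null threshold and
        its endpoints overlap the planted blocks."""
        field = FieldSpec(
            grid_shape=(12, 12, 12), baseline_map=cube_baseline((12, 12, 12)), noise_sd=0.02
        )
        vols, covars = simulate_cohort_volumes(CohortSpec(seed=42), field, seed=43)
        src = np.array([(x, y, z) for x in (2, 3) for y in range(4, 8) for z in range(4, 8)])
        tgt = np.array([(x, y, z) for x in (8, 9) for y in range(4, 8) for z in range(4, 8)])
        planted = plant_interaction(
            vols, covars, PlantedInteraction(src, tgt, gamma=0.8), eps_sd=0.01, seed=44
        )
        x = covars["experience_years"].to_numpy()
        cfg = NetworkMonteCarloConfig(n_networks=100, seed=45)
        thr = null_link_cluster_threshold(31, vols.mask, 2, 2.0, x, cfg)
        nodes = downsample(planted, 2)
        net = fit_link_interaction(nodes, x)
        clusters = link_cluster(net, cfg.link_p_threshold)
        sig = significant_links(clusters, thr)
        assert len(sig) > 0
        src_nodes = {(1, 2, 2)}
        tgt_nodes = {(4, 2, 2)}
        endpoints = {tuple(nodes.coords[i]) for l in sig for i in l}
        assert endpoints & src_nodes and endpoints & tgt_nodes
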