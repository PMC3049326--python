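import numpy as np
import pytest
from scipy import stats

from erpglm import (NeighbourhoodGraph, StatMap, SubjectStack,
                    cluster_sum_correct, connected_components_spacetime,
                    h0_resample_maps, max_cluster_sum, max_stat_correct,
                    one_sided_critical_index, spacetime_edges)


def flood_fill_oracle(mask, adjacency):
    """Brute-force BFS labelling: same-channel |df|=1 or neighbour-channel
    df=0 connectivity, labels in scan order of first appearance."""
    n_ch, n_fr = mask.shape
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for c0 in range(n_ch):
        for f0 in range(n_fr):
            if not mask[c0, f0] or labels[c0, f0]:
                continue
            nxt += 1
            queue = [(c0, f0)]
            labels[c0, f0] = nxt
            while queue:
                c, f = queue.pop()
                for cc, ff in [(c, f - 1), (c, f + 1)] + \
                        [(k, f) for k in range(n_ch) if adjacency[c, k]]:
                    if 0 <= cc < n_ch and 0 <= ff < n_fr and \
                            mask[cc, ff] and not labels[cc, ff]:
                        labels[cc, ff] = nxt
                        queue.append((cc, ff))
    return labels


def _f_statmap(stat, df=(1.0, 19.0)):
    stat = np.asarray(stat, dtype=float)
    return StatMap(stat=stat, kind="F", df=df,
                   p_uncorrected=stats.f.sf(stat, *df))


class TestConnectedComponents:
    def test_single_channel_two_runs(self):
        mask = np.zeros((1, 12), dtype=bool)
        mask[0, [4, 5, 6, 9]] = True
        labels = connected_components_spacetime(mask, NeighbourhoodGraph.empty(1))
        assert labels.max() == 2
        assert (labels == 1).sum() == 3 and (labels == 2).sum() == 1

    def test_adjacent_channels_same_frame_merge(self):
        mask = np.zeros((2, 5), dtype=bool)
        mask[0, 2] = mask[1, 2] = True
        chain = NeighbourhoodGraph.chain(2)
        assert connected_components_spacetime(mask, chain).max() == 1
        # without a spatial edge they stay separate
        assert connected_components_spacetime(
            mask, NeighbourhoodGraph.empty(2)).max() == 2

    def test_diagonal_excluded_by_default(self):
        mask = np.zeros((2, 4), dtype=bool)
        mask[0, 1] = mask[1, 2] = True
        chain = NeighbourhoodGraph.chain(2)
        assert connected_components_spacetime(mask, chain).max() == 2
        assert connected_components_spacetime(
            mask, chain, include_diagonal=True).max() == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_ch, n_fr = rng.integers(2, 7), rng.integers(3, 15)
        mask = rng.random((n_ch, n_fr)) < 0.4
        A = np.triu(rng.random((n_ch, n_ch)) < 0.4, k=1)
        graph = NeighbourhoodGraph(A | A.T)
        got = connected_components_spacetime(mask, graph)
        ref = flood_fill_oracle(mask, graph.adjacency)
        assert np.array_equal(got, ref)

    def test_max_cluster_sum_consistent_with_labels(self, rng):
        mask = rng.random((4, 10)) < 0.35
        stat = rng.random((4, 10)) + 1.0
        graph = NeighbourhoodGraph.chain(4)
        labels = connected_components_spacetime(mask, graph)
        sums = [stat[labels == i].sum() for i in range(1, labels.max() + 1)]
        edges = spacetime_edges(graph, 4, 10)
        got = max_cluster_sum(stat.ravel(), mask.ravel(), edges)
        assert got == pytest.approx(max(sums) if sums else 0.0)


class TestMaxStat:
    def test_threshold_rule(self):
        null = np.full((200, 2, 3), 1.0)
        null[:, 0, 0] = 10.0        # every resample's max is 10
        obs = _f_statmap(np.array([[11.0, 9.0, 0.5], [0.2, 0.1, 0.3]]))
        res = max_stat_correct(obs, null, alpha=0.05)
        assert res.critical == 10.0
        assert res.significant[0, 0] and not res.significant[0, 1]

    def test_alpha_one_everything_significant(self):
        null = np.ones((50, 2, 2))
        obs = _f_statmap(np.zeros((2, 2)))
        res = max_stat_correct(obs, null, alpha=1.0)
        assert res.significant.all()

    def test_too_few_null_maps_rejected(self):
        with pytest.raises(ValueError, match="null maps"):
            max_stat_correct(_f_statmap(np.ones((1, 1))), np.ones((10, 1, 1)),
                             alpha=0.05)

    def test_critical_exceeds_single_cell_parametric(self, gaussian_stack):
        null = h0_resample_maps("one_sample", gaussian_stack, 400, seed=0)
        obs = _f_statmap(np.zeros(gaussian_stack.cell_shape),
                         df=(1.0, gaussian_stack.n_subjects - 1.0))
        res = max_stat_correct(obs, null, alpha=0.05)
        assert res.critical >= stats.f.ppf(0.95, 1, gaussian_stack.n_subjects - 1)


class TestClusterSumCorrect:
    def test_sum_and_threshold_rule(self):
        # one channel; two suprathreshold runs with sums 15 and 30
        stat = np.zeros((1, 20))
        stat[0, 2:5] = [5.0, 4.5, 5.5]           # sum 15
        stat[0, 10:13] = [10.0, 10.0, 10.0]      # sum 30
        df = (1.0, 19.0)
        crit = stats.f.ppf(0.95, *df)
        assert stat[0, 2:5].min() > crit         # both runs fully suprathreshold
        obs = _f_statmap(stat, df)
        null = np.zeros((100, 1, 20))
        null[:, 0, 0] = 20.0                     # every null max cluster sum = 20
        cs = cluster_sum_correct(obs, null, graph=NeighbourhoodGraph.empty(1),
                                 alpha=0.05, mode="spatiotemporal")
        assert sorted(cs.sums.tolist()) == [15.0, 30.0]
        assert cs.significant.tolist() == [sorted(cs.sums.tolist()).index(s) == 1
                                           for s in cs.sums]
        i30 = int(np.argmax(cs.sums))
        assert cs.significant[i30] and not cs.significant[1 - i30]

    def test_no_suprathreshold_cells_empty_clusterset(self):
        obs = _f_statmap(np.zeros((2, 5)))
        null = np.zeros((60, 2, 5))
        cs = cluster_sum_correct(obs, null, graph=NeighbourhoodGraph.chain(2))
        assert cs.n_clusters == 0 and cs.labels.max() == 0

    def test_temporal_equals_spatiotemporal_with_edgeless_graph(self, rng):
        stack = SubjectStack(rng.normal(0.6, 1.0, size=(12, 4, 15)))
        from erpglm import one_sample_bootstrap_t
        res = one_sample_bootstrap_t(stack, n_boot=200, seed=1)
        null = h0_resample_maps("one_sample", stack, 200, seed=2)
        a = cluster_sum_correct(res.statmap, null,
                                graph=NeighbourhoodGraph.empty(4),
                                mode="spatiotemporal")
        b = cluster_sum_correct(res.statmap, null, mode="temporal")
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.sums, b.sums)
        assert np.array_equal(a.significant, b.significant)

    def test_corrected_p_monotone_in_sum(self, rng):
        stack = SubjectStack(rng.normal(0.8, 1.0, size=(14, 3, 20)))
        from erpglm import one_sample_bootstrap_t
        res = one_sample_bootstrap_t(stack, n_boot=200, seed=3)
        null = h0_resample_maps("one_sample", stack, 300, seed=4)
        cs = cluster_sum_correct(res.statmap, null,
                                 graph=NeighbourhoodGraph.chain(3))
        if cs.n_clusters >= 2:
            order = np.argsort(cs.sums)
            assert np.all(np.diff(cs.p_corrected[order]) <= 0)

    def test_spatiotemporal_requires_graph(self):
        with pytest.raises(ValueError, match="graph"):
            cluster_sum_correct(_f_statmap(np.ones((2, 3))),
                                np.ones((30, 2, 3)))


class TestH0Schemes:
    def test_one_sample_scheme_centres_before_resampling(self, rng):
        """Data with a huge mean must yield a central t^2 stream: the
        scheme is centre-then-resample, not resample-raw."""
        stack = SubjectStack(1000.0 + rng.normal(size=(12, 2, 4)))
        null = h0_resample_maps("one_sample", stack, 500, seed=0)
        # raw (uncentred) t^2 would be ~(1000*sqrt(12))^2; centred is O(1)
        assert null.mean() < 10.0
        assert null.max() < 1000.0

    def test_two_sample_scheme_centres_per_group(self, rng):
        s1 = SubjectStack(500.0 + rng.normal(size=(10, 2, 3)))
        s2 = SubjectStack(-500.0 + rng.normal(size=(12, 2, 3)))
        null = h0_resample_maps("two_sample", (s1, s2), 400, seed=1)
        assert null.mean() < 10.0

    def test_regression_scheme_breaks_data_design_link(self, rng):
        # maps perfectly aligned with the predictor: under row-resampling
        # against the fixed design the association must collapse
        x = rng.normal(size=20)
        maps = 5.0 * x[:, None, None] + 0.1 * rng.normal(size=(20, 2, 3))
        stack = SubjectStack(maps)
        X = np.column_stack([x, np.ones(20)])
        null = h0_resample_maps("regression", (stack, X), 300, seed=2)
        f_obs = 25.0 * (x ** 2).sum() / (0.1 ** 2)   # enormous observed F
        assert np.median(null) < stats.f.ppf(0.999, 1, 18) < f_obs

    def test_centred_resample_means_vanish(self, rng):
        """Monte-Carlo sanity: the grand mean of H0 bootstrap means is
        within 3 standard errors of zero."""
        stack = SubjectStack(rng.normal(3.0, 1.0, size=(10, 1, 1)))
        centred = stack.maps - stack.maps.mean(axis=0)
        from erpglm.level2_robust import draw_bootstrap_indices
        idx = draw_bootstrap_indices(np.random.default_rng(5), 10, 2000)
        boot_means = centred[idx, 0, 0].mean(axis=1)
        se = boot_means.std(ddof=1) / np.sqrt(2000)
        assert abs(boot_means.mean()) < 3 * se

    def test_fixed_seed_identical_stream(self, gaussian_stack):
        a = h0_resample_maps("one_sample", gaussian_stack, 100, seed=9)
        b = h0_resample_maps("one_sample", gaussian_stack, 100, seed=9)
        assert np.array_equal(a, b)

    def test_unknown_scheme_rejected(self, gaussian_stack):
        with pytest.raises(ValueError, match="scheme"):
            h0_resample_maps("wurst", gaussian_stack, 10, seed=0)


class TestFamilywiseErrorSimulation:
    def test_fwer_controlled_for_all_corrections(self):
        """Gaussian-null Monte-Carlo at the group level: the max statistic
        is near nominal and both cluster modes control the familywise
        error.  The centred bootstrap-t null has heavier tails than the
        true sampling distribution at small n, so the cluster corrections
        run conservative here; near-nominal behaviour is a trial-level
        (large-n) property, measured by the validation harness."""
        rng = np.random.default_rng(314)
        n_mc, B, n, n_ch, n_fr = 500, 800, 40, 8, 50
        graph = NeighbourhoodGraph.chain(n_ch)
        edges_st = spacetime_edges(graph, n_ch, n_fr)
        edges_t = spacetime_edges(None, n_ch, n_fr)
        crit_form = stats.f.ppf(0.95, 1, n - 1)
        pos_idx = one_sided_critical_index(0.05, B)
        hits = {"max": 0, "st": 0, "t": 0}
        for _ in range(n_mc):
            maps = rng.standard_normal((n, n_ch, n_fr))
            m = maps.mean(axis=0)
            s = maps.std(axis=0, ddof=1)
            t2_obs = (m / (s / np.sqrt(n))) ** 2
            null = h0_resample_maps("one_sample", SubjectStack(maps), B,
                                    seed=rng.integers(2 ** 31))
            flat_null = null.reshape(B, -1)
            # max statistic
            crit = np.sort(flat_null.max(axis=1))[pos_idx - 1]
            hits["max"] += int(t2_obs.max() >= crit)
            # cluster sums, both modes
            obs_mask = (t2_obs >= crit_form).ravel()
            null_masks = flat_null >= crit_form
            for key, edges in (("st", edges_st), ("t", edges_t)):
                obs_max = max_cluster_sum(t2_obs.ravel(), obs_mask, edges)
                nm = np.sort([max_cluster_sum(flat_null[b], null_masks[b],
                                              edges) for b in range(B)])
                c = nm[pos_idx - 1]
                hits[key] += int(obs_max > 0 and obs_max >= c)
        assert 0.03 <= hits["max"] / n_mc <= 0.07, hits
        for key in ("st", "t"):
            rate = hits[key] / n_mc
            assert 0.002 <= rate <= 0.07, (key, rate)
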