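import numpy as np
import pytest
from scipy import stats as sps

from erpstats.cluster import (
    ClusterConfig,
    PermutationNull,
    SubjectConditionMaps,
    cluster_p_values,
    condition_maps,
    find_clusters,
    permutation_null,
    pointwise_paired_t,
    pointwise_rm_anova,
    run_cluster_test,
)
from erpstats.cluster import _Clusterer
from erpstats.montage import build_adjacency
from erpstats.preprocess import BaselineWindow


def make_maps(data, layout, sfreq=100.0):
    k = data.shape[1]
    conds = tuple(f"c{i}" for i in range(k))
    ids = layout.ids[: data.shape[2]]
    return SubjectConditionMaps(data, conds, ids, np.arange(data.shape[3]) / sfreq)


def brute_force_F(y):
    """Definitional sums-of-squares RM-ANOVA for one (n, k) table."""
    n, k = y.shape
    grand = y.mean()
    ss_cond = n * sum((y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_int = sum(
        (y[i, j] - y[i, :].mean() - y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return (ss_cond / (k - 1)) / (ss_int / ((k - 1) * (n - 1)))


class TestPointwiseStats:
    def test_f_matches_brute_force(self, layout16, rng):
        data = rng.standard_normal((6, 3, 4, 5))
        sm = pointwise_rm_anova(make_maps(data, layout16))
        for e in range(4):
            for t in range(5):
                assert sm.stat[e, t] == pytest.approx(brute_force_F(data[:, :, e, t]), abs=1e-10)
        assert sm.df == (2, 10)
        assert np.all(sm.stat >= 0)

    def test_identical_conditions_give_zero_F(self, layout16, rng):
        one = rng.standard_normal((5, 1, 4, 5))
        data = np.repeat(one, 3, axis=1)
        sm = pointwise_rm_anova(make_maps(data, layout16))
        assert np.allclose(sm.stat, 0.0)

    def test_zero_error_variance_warns_inf(self, layout16):
        n, k = 4, 3
        subj = np.arange(n)[:, None]
        cond = np.array([0.0, 1.0, 2.0])[None, :]
        data = np.tile((subj + cond)[:, :, None, None], (1, 1, 4, 5))
        with pytest.warns(RuntimeWarning, match="zero error variance"):
            sm = pointwise_rm_anova(make_maps(data, layout16))
        assert np.all(np.isinf(sm.stat))
        assert np.all(sm.p == 0.0)

    def test_k2_F_equals_t_squared(self, layout16, rng):
        data = rng.standard_normal((8, 2, 4, 6))
        f = pointwise_rm_anova(make_maps(data, layout16)).stat
        t = pointwise_paired_t(make_maps(data, layout16)).stat
        assert np.allclose(f, t**2, atol=1e-10)

    def test_paired_t_matches_textbook_formula(self, layout16, rng):
        data = rng.standard_normal((7, 2, 3, 4))
        sm = pointwise_paired_t(make_maps(data, layout16))
        d = data[:, 0] - data[:, 1]
        t_exp = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(7))
        assert np.allclose(sm.stat, t_exp, atol=1e-12)
        assert np.allclose(sm.p, 2 * sps.t.sf(np.abs(t_exp), 6), atol=1e-12)

    def test_identical_conditions_t_zero_p_one(self, layout16, rng):
        one = rng.standard_normal((5, 1, 4, 5))
        data = np.repeat(one, 2, axis=1)
        sm = pointwise_paired_t(make_maps(data, layout16))
        assert np.allclose(sm.stat, 0.0)
        assert np.allclose(sm.p, 1.0)

    def test_constant_nonzero_difference_warns(self, layout16, rng):
        base = rng.standard_normal((5, 1, 4, 5))
        data = np.concatenate([base + 1.0, base], axis=1)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            sm = pointwise_paired_t(make_maps(data, layout16))
        assert np.all(np.isposinf(sm.stat))

    def test_too_few_conditions_or_subjects(self, layout16, rng):
        with pytest.raises(ValueError):
            pointwise_rm_anova(make_maps(rng.standard_normal((1, 3, 4, 5)), layout16))
        with pytest.raises(ValueError):
            pointwise_paired_t(make_maps(rng.standard_normal((5, 3, 4, 5)), layout16))


def flood_fill_clusters(mask, adj):
    """Independent connected-components oracle (depth-first flood fill)."""
    E, T = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for e in range(E):
        for t in range(T):
            if mask[e, t] and not seen[e, t]:
                stack, comp = [(e, t)], set()
                seen[e, t] = True
                while stack:
                    a, b = stack.pop()
                    comp.add((a, b))
                    nbrs = [(a, b - 1), (a, b + 1)] + [(c, b) for c in range(E) if adj[a, c]]
                    for x, y in nbrs:
                        if 0 <= y < T and mask[x, y] and not seen[x, y]:
                            seen[x, y] = True
                            stack.append((x, y))
                comps.append(frozenset(comp))
    return comps


class TestFindClusters:
    def test_no_suprathreshold_empty(self, layout16, adjacency16, rng):
        data = rng.standard_normal((6, 3, 16, 10)) * 1e-3
        data += rng.standard_normal((6, 1, 1, 1))  # subject offsets, no condition effect
        sm = pointwise_rm_anova(make_maps(data, layout16))
        sm.p[:] = 0.5  # force no point below threshold
        assert find_clusters(sm, 0.05, adjacency16) == []

    def test_isolated_point_single_cluster(self, layout16, adjacency16, rng):
        data = rng.standard_normal((6, 3, 16, 10)) * 0.1
        sm = pointwise_rm_anova(make_maps(data, layout16))
        crit = sps.f.isf(0.05, *sm.df)
        sm.stat[:] = 0.0
        sm.stat[5, 5] = crit * 2
        sm.p = sps.f.sf(sm.stat, *sm.df)
        clusters = find_clusters(sm, 0.05, adjacency16)
        assert len(clusters) == 1
        assert clusters[0].members() == {(5, 5)}
        assert clusters[0].sum == pytest.approx(crit * 2)

    def test_flood_fill_equivalence(self, layout16, rng):
        lay5 = layout16.subset([1, 2, 3, 4, 5])
        adj5 = build_adjacency(lay5, 1.5)
        cl = _Clusterer(adj5, 10)
        for _ in range(200):
            mask = rng.random((5, 10)) < 0.35
            stat = rng.random((5, 10))
            mine = cl.clusters(stat, mask, +1)
            assert sorted((frozenset(c.members()) for c in mine), key=sorted) == sorted(
                flood_fill_clusters(mask, adj5.matrix), key=sorted
            )
            for c in mine:
                assert c.sum == pytest.approx(
                    sum(stat[e, t] for e, t in c.members()), abs=1e-12
                )

    def test_t_clusters_split_by_sign(self, layout16, adjacency16, rng):
        data = rng.standard_normal((8, 2, 16, 10)) * 0.1
        sm = pointwise_paired_t(make_maps(data, layout16))
        crit = sps.t.isf(0.025, 7)
        sm.stat[:] = 0.0
        sm.stat[2, 2:5] = crit + 1
        sm.stat[2, 6:8] = -(crit + 2)
        sm.p = 2 * sps.t.sf(np.abs(sm.stat), 7)
        clusters = find_clusters(sm, 0.05, adjacency16)
        signs = sorted(c.sign for c in clusters)
        assert signs == [-1, 1]
        neg = next(c for c in clusters if c.sign == -1)
        assert neg.sum == pytest.approx(-2 * (crit + 2))


class TestPermutationNull:
    def test_all_zero_data_null_all_zeros(self, layout16, adjacency16):
        data = np.zeros((5, 3, 16, 8))
        null = permutation_null(make_maps(data, layout16), "F", adjacency16, 50, seed=1)
        assert np.all(null.values == 0.0)

    def test_deterministic_given_seed(self, layout16, adjacency16, rng):
        maps = make_maps(rng.standard_normal((6, 3, 16, 8)), layout16)
        a = permutation_null(maps, "F", adjacency16, 100, seed=7)
        b = permutation_null(maps, "F", adjacency16, 100, seed=7)
        assert np.array_equal(a.values, b.values)
        c = permutation_null(maps, "F", adjacency16, 100, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_exhaustive_sign_flip_oracle(self, layout16, rng):
        """MC permutation p vs the 2^n exhaustive relabeling for k=2, n=5."""
        lay3 = layout16.subset([1, 2, 3])
        adj3 = build_adjacency(lay3, 1.5)
        cl = _Clusterer(adj3, 4)
        crit = sps.t.isf(0.025, 4)
        checked = 0
        for i in range(10):
            data = rng.standard_normal((5, 2, 3, 4))
            data[:, 0] += 1.2
            maps = SubjectConditionMaps(data, ("a", "b"), lay3.ids, np.arange(4) / 100)
            sm = pointwise_paired_t(maps)
            obs_clusters = find_clusters(sm, 0.05, adj3)
            if not obs_clusters:
                continue
            obs = max(abs(c.sum) for c in obs_clusters)
            vals = []
            for bits in range(32):
                d = data.copy()
                for s in range(5):
                    if bits >> s & 1:
                        d[s] = d[s, ::-1]
                t = pointwise_paired_t(
                    SubjectConditionMaps(d, ("a", "b"), lay3.ids, np.arange(4) / 100)
                ).stat
                vals.append(
                    max(cl.max_cluster_sum(t, t > crit), cl.max_cluster_sum(-t, t < -crit))
                )
            p_exh = np.mean(np.asarray(vals) >= obs - 1e-12)
            null = permutation_null(maps, "t", adj3, n_permutations=4000, seed=90 + i)
            p_mc = np.mean(null.values >= obs - 1e-12)
            assert abs(p_exh - p_mc) < 0.03
            checked += 1
        assert checked >= 3

    def test_t_requires_two_conditions(self, layout16, adjacency16, rng):
        maps = make_maps(rng.standard_normal((5, 3, 16, 8)), layout16)
        with pytest.raises(ValueError):
            permutation_null(maps, "t", adjacency16, 10, seed=0)


class TestClusterPValues:
    def _cluster(self, s):
        from erpstats.cluster import Cluster

        return Cluster(np.array([0]), np.array([0]), float(s), 1)

    def test_formula_extremes(self):
        null = PermutationNull(np.arange(1000.0) + 1.0, seed=0)
        res = cluster_p_values([self._cluster(2000.0)], null)
        assert res.clusters[0].p_corrected == pytest.approx(1 / 1001)
        res = cluster_p_values([self._cluster(-0.5)], null)
        assert res.clusters[0].p_corrected == pytest.approx(1.0)

    def test_median_cluster_p_half(self, rng):
        null = PermutationNull(rng.random(10001), seed=0)
        res = cluster_p_values([self._cluster(float(np.median(null.values)))], null)
        assert res.clusters[0].p_corrected == pytest.approx(0.5, abs=0.01)

    def test_p_nonincreasing_in_sum(self, rng):
        null = PermutationNull(rng.random(500), seed=0)
        sums = np.sort(rng.random(20))
        res = cluster_p_values([self._cluster(s) for s in sums], null)
        ps = [c.p_corrected for c in res.clusters]
        assert np.all(np.diff(ps) <= 0)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            cluster_p_values([], PermutationNull(np.empty(0), seed=0))

    def test_min_p_defaults_to_one(self):
        null = PermutationNull(np.arange(100.0), seed=0)
        res = cluster_p_values([], null)
        assert res.min_p == 1.0
        assert not res.any_significant


class TestRunClusterTest:
    def test_single_condition_rejected(self, small_epochs):
        with pytest.raises(ValueError, match="2 conditions"):
            run_cluster_test(small_epochs, ["a"], config=ClusterConfig(n_permutations=10))

    def test_f_and_t_flag_identical_clusters_for_k2(self, small_epochs, adjacency16):
        cfg_t = ClusterConfig(stat="t", n_permutations=50, seed=3)
        cfg_f = ClusterConfig(stat="F", n_permutations=50, seed=3)
        res_t = run_cluster_test(small_epochs, ["a", "b"], config=cfg_t, adjacency=adjacency16)
        res_f = run_cluster_test(small_epochs, ["a", "b"], config=cfg_f, adjacency=adjacency16)
        members_t = sorted((frozenset(c.members()) for c in res_t.clusters), key=sorted)
        members_f = sorted((frozenset(c.members()) for c in res_f.clusters), key=sorted)
        assert members_t == members_f

    def test_large_effect_detected(self, layout16, adjacency16):
        from erpstats.synth import ComponentSpec, NoiseSpec, StudyDesign, add_component, simulate_noise_epochs

        design = StudyDesign(
            n_subjects=14, trials_per_condition=10, sfreq=100.0,
            epoch_window=(-0.1, 0.5), conditions=("a", "b", "c"),
        )
        ep = simulate_noise_epochs(design, NoiseSpec(sd_broadband=8.0), layout16, seed=5)
        comp = ComponentSpec(
            "big", 6.0, (0.1, 0.4), tuple(range(1, 9)), ("a",), envelope="boxcar"
        )
        ep = add_component(ep, comp, seed=6)
        res = run_cluster_test(
            ep, ["a", "b", "c"],
            baseline=BaselineWindow(-0.1, 0.0),
            config=ClusterConfig(n_permutations=200, seed=11),
            adjacency=adjacency16,
        )
        assert res.any_significant
        assert res.min_p < 0.01

    def test_report_round_trip(self, small_epochs, adjacency16, tmp_path):
        res = run_cluster_test(
            small_epochs, ["a", "b", "c"],
            config=ClusterConfig(n_permutations=30, seed=2),
            adjacency=adjacency16,
        )
        path = tmp_path / "result.json"
        res.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["n_clusters"] == len(res.clusters)
        assert payload["min_p"] == res.min_p
        tab = res.to_table()
        assert list(tab.columns) == ["size", "sum", "sign", "p", "electrodes", "time_range_s"]


class TestConditionMaps:
    def test_maps_shape_and_baseline(self, small_epochs):
        maps = condition_maps(
            small_epochs, ("a", "b"), electrode_scope=[1, 2, 3],
            time_window=(0.0, 0.3), baseline=BaselineWindow(-0.2, -0.1),
        )
        assert maps.data.shape == (4, 2, 3, 31)
        assert maps.electrode_ids == (1, 2, 3)

    def test_trial_average_matches_manual(self, small_epochs):
        maps = condition_maps(small_epochs)
        assert np.allclose(maps.data, small_epochs.data.mean(axis=2))
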