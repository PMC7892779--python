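import numpy as np
import pytest

from erpstats.cluster import ClusterConfig
from erpstats.power import (
    InjectionSpec,
    PowerGrid,
    estimate_sigma,
    inject_effect,
    partition_trials,
    power_grid,
    run_simulation_cell,
)
from erpstats.synth import NoiseSpec, StudyDesign, simulate_noise_epochs


@pytest.fixture(scope="module")
def pool(layout16):
    """24 trials per subject pooled in one condition; 0.4 s @ 100 Hz."""
    design = StudyDesign(
        n_subjects=8, trials_per_condition=24, sfreq=100.0,
        epoch_window=(0.0, 0.4), conditions=("pool",),
    )
    return simulate_noise_epochs(design, NoiseSpec(sd_broadband=8.0), layout16, seed=42)


# conftest fixtures are function-scoped only through the session layout,
# re-expose layout16 for the module-scoped pool
@pytest.fixture(scope="module")
def layout16():
    from erpstats.montage import build_default_layout

    return build_default_layout().subset(list(range(1, 17)))


class TestPartition:
    def test_nine_trials_equal_split(self, layout16):
        design = StudyDesign(n_subjects=1, trials_per_condition=9, sfreq=100.0,
                             epoch_window=(0.0, 0.1), conditions=("x",))
        ep = simulate_noise_epochs(design, NoiseSpec(sd_broadband=0.0), layout16, seed=0)
        parts = partition_trials(ep, 0, seed=1)
        assert sorted(len(p) for p in parts) == [3, 3, 3]

    def test_ten_trials_near_equal_split(self, layout16):
        design = StudyDesign(n_subjects=1, trials_per_condition=5, sfreq=100.0,
                             epoch_window=(0.0, 0.1), conditions=("x", "y"))
        ep = simulate_noise_epochs(design, NoiseSpec(sd_broadband=0.0), layout16, seed=0)
        parts = partition_trials(ep, 0, seed=1)
        assert sorted(len(p) for p in parts) == [3, 3, 4]

    def test_union_is_exact_trial_set(self, pool, rng):
        for seed in rng.integers(0, 2**31, size=5):
            parts = partition_trials(pool, 2, seed=int(seed))
            combined = np.vstack(parts)
            assert len(combined) == pool.n_conditions * pool.n_trials
            as_tuples = {tuple(row) for row in combined}
            assert len(as_tuples) == len(combined)  # no duplicates
            assert as_tuples == {
                (c, t) for c in range(pool.n_conditions) for t in range(pool.n_trials)
            }

    def test_deterministic(self, pool):
        a = partition_trials(pool, 1, seed=9)
        b = partition_trials(pool, 1, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_too_few_trials_rejected(self, layout16):
        design = StudyDesign(n_subjects=1, trials_per_condition=2, sfreq=100.0,
                             epoch_window=(0.0, 0.1), conditions=("x",))
        ep = simulate_noise_epochs(design, NoiseSpec(sd_broadband=0.0), layout16, seed=0)
        with pytest.raises(ValueError, match="trials"):
            partition_trials(ep, 0, k=3, seed=0)


class TestEstimateSigma:
    def test_identical_trials_zero(self, layout16):
        design = StudyDesign(n_subjects=1, trials_per_condition=6, sfreq=100.0,
                             epoch_window=(0.0, 0.4), conditions=("x",))
        ep = simulate_noise_epochs(design, NoiseSpec(sd_broadband=0.0), layout16, seed=0)
        assert estimate_sigma(ep, 0, 1, 0.25) == 0.0

    def test_two_point_sample_sd(self, layout16):
        design = StudyDesign(n_subjects=1, trials_per_condition=2, sfreq=100.0,
                             epoch_window=(0.0, 0.4), conditions=("x",))
        ep = simulate_noise_epochs(design, NoiseSpec(sd_broadband=0.0), layout16, seed=0)
        ei, ti = ep.layout.index_of(1), ep.time_index(0.25)
        ep.data[0, 0, 0, ei, ti] = 0.0
        ep.data[0, 0, 1, ei, ti] = 2.0
        assert estimate_sigma(ep, 0, 1, 0.25) == pytest.approx(np.sqrt(2.0))

    def test_matches_independent_recomputation(self, pool):
        ei, ti = pool.layout.index_of(5), pool.time_index(0.25)
        expected = np.std(pool.data[3, :, :, ei, ti].ravel(), ddof=1)
        assert estimate_sigma(pool, 3, 5, 0.25) == pytest.approx(expected, abs=1e-12)

    def test_single_trial_rejected(self, layout16):
        design = StudyDesign(n_subjects=1, trials_per_condition=1, sfreq=100.0,
                             epoch_window=(0.0, 0.4), conditions=("x",))
        ep = simulate_noise_epochs(design, NoiseSpec(sd_broadband=0.0), layout16, seed=0)
        with pytest.raises(ValueError, match="2 trials"):
            estimate_sigma(ep, 0, 1, 0.25)


class TestInjectEffect:
    def _spec(self, mu, sign=1, level="per_trial"):
        return InjectionSpec("test", mu, (1, 2, 3), (0.1, 0.3), sign=sign, draw_level=level)

    def test_zero_mu_zero_sigma_unchanged(self, rng):
        trials = rng.standard_normal((10, 16, 41))
        times = np.arange(41) / 100.0
        out = inject_effect(trials, times, np.array([0, 1, 2]), self._spec(0.0), 0.0, seed=1)
        assert np.array_equal(out, trials)

    def test_exact_shift_sigma_zero(self, rng):
        trials = rng.standard_normal((10, 16, 41))
        times = np.arange(41) / 100.0
        for sign in (1, -1):
            out = inject_effect(
                trials, times, np.array([0, 1, 2]), self._spec(2.0, sign=sign), 0.0, seed=1
            )
            window = (times >= 0.1) & (times <= 0.3)
            shift = out - trials
            assert shift[:, :3][:, :, window] == pytest.approx(sign * 2.0)
            assert not shift[:, 3:].any()
            assert not shift[:, :3][:, :, ~window].any()

    def test_per_trial_mean_shift_clt_bound(self, rng):
        n_tr = 48
        trials = np.zeros((n_tr, 16, 41))
        times = np.arange(41) / 100.0
        out = inject_effect(trials, times, np.array([0]), self._spec(2.0), 1.0, seed=7)
        window = (times >= 0.1) & (times <= 0.3)
        shift = out[:, 0][:, window].mean()
        assert abs(shift - 2.0) < 3.0 / np.sqrt(n_tr)

    def test_per_subject_draw_constant_across_trials(self, rng):
        trials = np.zeros((6, 16, 41))
        times = np.arange(41) / 100.0
        out = inject_effect(
            trials, times, np.array([0]), self._spec(2.0, level="per_subject"), 1.0, seed=3
        )
        window = (times >= 0.1) & (times <= 0.3)
        per_trial = out[:, 0][:, window].mean(axis=1)
        assert np.ptp(per_trial) == pytest.approx(0.0, abs=1e-12)

    def test_window_outside_epoch_rejected(self, rng):
        trials = np.zeros((3, 16, 21))
        times = np.arange(21) / 100.0  # 0 - 0.2 s
        with pytest.raises(ValueError, match="outside"):
            inject_effect(trials, times, np.array([0]), self._spec(1.0), 0.0, seed=0)

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            InjectionSpec("x", -1.0, (1,), (0.0, 0.1))


class TestSimulationCell:
    CFG = ClusterConfig(n_permutations=100, seed=0)

    def test_deterministic(self, pool):
        spec = InjectionSpec("t", 1.0, (1, 2, 3), (0.1, 0.3), sign=-1)
        a = run_simulation_cell(pool, spec, 6, repetitions=5, analysis_config=self.CFG, seed=4)
        b = run_simulation_cell(pool, spec, 6, repetitions=5, analysis_config=self.CFG, seed=4)
        assert a.detections == b.detections

    def test_too_many_subjects_rejected(self, pool):
        spec = InjectionSpec("t", 1.0, (1, 2, 3), (0.1, 0.3))
        with pytest.raises(ValueError, match="subjects"):
            run_simulation_cell(pool, spec, 99, repetitions=1, analysis_config=self.CFG, seed=0)

    def test_disjoint_scope_rejected(self, pool):
        spec = InjectionSpec("t", 1.0, (1, 2), (0.1, 0.3))
        with pytest.raises(ValueError, match="disjoint"):
            run_simulation_cell(
                pool, spec, 4, repetitions=1, analysis_config=self.CFG, seed=0,
                electrode_scope=[9, 10, 11],
            )

    def test_partition_label_exchangeability(self, pool):
        """Under mu=0 the pseudo-conditions are exchangeable: the F map is
        invariant to relabeling the partitions."""
        from erpstats.cluster import pointwise_rm_anova
        from erpstats.power import _pseudo_condition_maps

        spec = InjectionSpec("t", 0.0, (1, 2, 3), (0.1, 0.3))
        sigma = np.zeros(pool.n_subjects)
        rng = np.random.default_rng(11)
        maps = _pseudo_condition_maps(
            pool, np.arange(6), spec, sigma, np.arange(16), np.array([0, 1, 2]), rng
        )
        f1 = pointwise_rm_anova(maps).stat
        shuffled = maps
        shuffled.data = maps.data[:, [2, 0, 1]]
        f2 = pointwise_rm_anova(shuffled).stat
        assert np.allclose(f1, f2, atol=1e-10)


class TestPowerGrid:
    def test_single_cell_grid_reduces_to_cell(self, pool):
        cfg = ClusterConfig(n_permutations=60)
        template = InjectionSpec("t", 0.0, (1, 2, 3), (0.1, 0.3), sign=-1)
        grid = power_grid(pool, template, [1.5], [6], analysis_config=cfg, seed=5, repetitions=4)
        assert grid.rate_matrix().shape == (1, 1)
        cell_seed = int(np.random.SeedSequence(5).spawn(1)[0].generate_state(1)[0])
        direct = run_simulation_cell(
            pool,
            InjectionSpec("t", 1.5, (1, 2, 3), (0.1, 0.3), sign=-1),
            6, repetitions=4, analysis_config=cfg, seed=cell_seed,
        )
        assert grid.cells[0].detections == direct.detections

    def test_empty_grid_rejected(self, pool):
        template = InjectionSpec("t", 0.0, (1,), (0.1, 0.3))
        with pytest.raises(ValueError, match="non-empty"):
            power_grid(pool, template, [], [6], repetitions=1)

    def test_round_trip_exports(self, pool, tmp_path):
        cfg = ClusterConfig(n_permutations=40)
        template = InjectionSpec("t", 0.0, (1, 2, 3), (0.1, 0.3))
        grid = power_grid(pool, template, [0.5, 4.0], [4], analysis_config=cfg, seed=1,
                          repetitions=3)
        import json

        payload = json.loads(grid.to_json())
        assert payload["mu_grid"] == [0.5, 4.0]
        tsv = tmp_path / "grid.tsv"
        grid.to_tsv(tsv)
        lines = tsv.read_text().splitlines()
        assert lines[0].startswith("component\tmu\tn")
        assert len(lines) == 1 + 2
        png = tmp_path / "grid.png"
        grid.plot(png)
        assert png.stat().st_size > 0

    def test_region_templates(self, region_map):
        san = InjectionSpec.san(region_map, mu=1.0)
        assert san.sign == -1 and len(san.electrode_set) == 24
        p600 = InjectionSpec.p600(region_map, mu=1.0)
        assert p600.sign == 1 and len(p600.electrode_set) == 20
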