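import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import ttest_ind

from dynmodnet.connectivity import WindowSpec, connectivity_stack
from dynmodnet.simulate import (
    ConditionEffect,
    ModuleSchedule,
    ROITimeSeriesSet,
    SimConfig,
    SimulationError,
    make_condition_pair,
    make_schedule,
    synthesize,
)


class TestMakeSchedule:
    def test_no_switching_gives_zero_planted_flexibility(self, mini_map):
        s = make_schedule(12, 12, 3, 0.0, mini_map, seed=0)
        assert np.all(s.planted_flexibility() == 0.0)

    def test_full_resampling_two_modules_switch_rate_half(self):
        # resampling uniform over 2 modules changes the label half the time
        n_nodes, n_windows = 100, 101
        s = make_schedule(n_nodes, n_windows, 2, 1.0, seed=1)
        changes = (s.assignment[:, 1:] != s.assignment[:, :-1]).mean()
        n_obs = n_nodes * (n_windows - 1)
        se = np.sqrt(0.25 / n_obs)
        assert abs(changes - 0.5) < 3 * se

    def test_single_forced_switch_gives_one_twelfth(self):
        a = np.ones((3, 12), dtype=int)
        a[0, 6:] = 2
        s = ModuleSchedule(a)
        assert s.planted_flexibility().tolist() == [1 / 12, 0.0, 0.0]

    def test_first_window_is_balanced(self):
        s = make_schedule(12, 5, 3, 0.5, seed=2)
        counts = np.bincount(s.assignment[:, 0])[1:]
        assert counts.tolist() == [4, 4, 4]

    def test_more_modules_than_nodes_rejected(self):
        with pytest.raises(SimulationError, match="exceeds"):
            make_schedule(3, 5, 4, 0.1)

    def test_per_system_probabilities(self, mini_map):
        s = make_schedule(12, 200, 3, {"DMN": 0.9}, mini_map, seed=3)
        flex = s.planted_flexibility()
        dmn = sorted(mini_map.members("DMN"))
        rest = sorted(set(range(12)) - set(dmn))
        assert flex[dmn].mean() > 0.3
        assert np.all(flex[rest] == 0.0)

    def test_co_module_boost_raises_planted_cross_allegiance(self, mini_map):
        base = make_schedule(12, 50, 3, 0.3, mini_map, seed=4)
        boosted = make_schedule(
            12, 50, 3, 0.3, mini_map, seed=4, co_module_prob={("SMN", "VN"): 0.8}
        )
        smn, vn = sorted(mini_map.members("SMN")), sorted(mini_map.members("VN"))
        cross = lambda s: s.planted_allegiance()[np.ix_(smn, vn)].mean()
        assert cross(boosted) > cross(base) + 0.1


class TestSynthesize:
    def test_seeded_determinism(self, mini_map):
        cfg = SimConfig(n_nodes=12, n_trials=2, n_modules=2, seed=5)
        sched = make_schedule(12, 12, 2, 0.3, mini_map, seed=5)
        a = synthesize(cfg, sched)
        b = synthesize(cfg, sched)
        assert np.array_equal(a.data, b.data)
        assert a.config_hash == b.config_hash

    def test_zero_lag_coupling_rejected(self):
        with pytest.raises(SimulationError, match="zero-lag"):
            SimConfig(n_nodes=2, within_module_phase_lag=0.0)
        with pytest.raises(SimulationError, match="zero-lag"):
            SimConfig(n_nodes=2, within_module_phase_lag=np.pi)

    def test_spectral_power_concentrated_in_band(self):
        cfg = SimConfig(n_nodes=4, n_trials=1, n_modules=2, seed=6)
        sched = make_schedule(4, 12, 2, 0.3, seed=6)
        ts = synthesize(cfg, sched)
        f, p = periodogram(ts.trial(0), fs=cfg.fs, axis=-1)
        inband = (f >= 6.0) & (f <= 15.0)  # carrier band plus transition width
        frac = p[:, inband].sum(axis=1) / p.sum(axis=1)
        assert np.all(frac > 0.9)

    def test_noiseless_two_node_module_reaches_unit_wpli(self):
        cfg = SimConfig(
            n_nodes=2, n_trials=1, noise_sd=0.0, within_module_phase_lag=np.pi / 2, seed=7
        )
        ts = synthesize(cfg, ModuleSchedule(np.ones((2, 12), dtype=int)))
        stack = connectivity_stack(ts.trial(0), cfg.fs, WindowSpec(), band=(8.0, 13.0))
        assert np.all(stack.values[:, 0, 1] > 0.999)

    def test_zero_coupling_indistinguishable_from_pure_noise(self):
        # with coupling off, co-module pairs look like independent noise
        sched = ModuleSchedule(np.ones((4, 12), dtype=int))
        wpli_means = {}
        for name, coupling in [("off", 0.0), ("noise_only", None)]:
            if coupling is None:
                cfg = SimConfig(n_nodes=4, n_trials=20, n_modules=1, coupling_strength=0.0, seed=9)
            else:
                cfg = SimConfig(n_nodes=4, n_trials=20, n_modules=1, coupling_strength=coupling, seed=8)
            ts = synthesize(cfg, sched)
            off = ~np.eye(4, dtype=bool)
            vals = [
                connectivity_stack(ts.trial(t), cfg.fs, WindowSpec(), band=(8, 13)).values[:, off].mean()
                for t in range(ts.n_trials)
            ]
            wpli_means[name] = vals
        p = ttest_ind(wpli_means["off"], wpli_means["noise_only"]).pvalue
        assert p > 0.05

    def test_schedule_window_mismatch_rejected(self, mini_map):
        cfg = SimConfig(n_nodes=12, n_trials=1)
        with pytest.raises(SimulationError, match="windows"):
            synthesize(cfg, make_schedule(12, 5, 2, 0.3, mini_map, seed=1))

    def test_save_load_round_trip(self, tmp_path, mini_map):
        cfg = SimConfig(n_nodes=12, n_trials=2, n_modules=2, seed=11)
        scheds = [make_schedule(12, 12, 2, 0.3, mini_map, seed=k) for k in range(2)]
        ts = synthesize(cfg, scheds, mini_map, condition="Pre-Stim")
        ts.save(tmp_path / "bundle")
        back = ROITimeSeriesSet.load(tmp_path / "bundle")
        assert np.array_equal(back.data, ts.data)
        assert back.condition == "Pre-Stim"
        assert all(
            np.array_equal(a.assignment, b.assignment)
            for a, b in zip(back.schedules, ts.schedules)
        )


class TestConditionPair:
    def test_halved_dmn_switching_halves_planted_flexibility(self, mini_map):
        cfg = SimConfig(n_nodes=12, n_trials=50, n_modules=2, switch_prob=0.4, seed=13)
        a, b = make_condition_pair(cfg, ConditionEffect(switch_scale={"DMN": 0.5}), mini_map)
        dmn = sorted(mini_map.members("DMN"))
        f1 = np.mean([s.planted_flexibility()[dmn].mean() for s in a.schedules])
        f2 = np.mean([s.planted_flexibility()[dmn].mean() for s in b.schedules])
        assert f2 / f1 == pytest.approx(0.5, abs=0.12)

    def test_null_effect_gives_matched_planted_flexibility(self, mini_map):
        cfg = SimConfig(n_nodes=12, n_trials=60, n_modules=2, switch_prob=0.4, seed=14)
        a, b = make_condition_pair(cfg, ConditionEffect(), mini_map)
        f1 = np.mean([s.planted_flexibility().mean() for s in a.schedules])
        f2 = np.mean([s.planted_flexibility().mean() for s in b.schedules])
        assert abs(f1 - f2) < 0.03

    def test_effect_outside_unit_interval_rejected(self, mini_map):
        cfg = SimConfig(n_nodes=12, n_trials=3, switch_prob=0.6)
        with pytest.raises(SimulationError, match=r"\[0, 1\]"):
            make_condition_pair(cfg, ConditionEffect(switch_scale={"DMN": 2.0}), mini_map)

    def test_co_module_effect_raises_planted_integration(self, mini_map):
        cfg = SimConfig(n_nodes=12, n_trials=30, n_modules=3, switch_prob=0.3, seed=15)
        effect = ConditionEffect(co_module_prob={("SMN", "VN"): 0.8})
        a, b = make_condition_pair(cfg, effect, mini_map)
        smn, vn = sorted(mini_map.members("SMN")), sorted(mini_map.members("VN"))
        cross = lambda ts: np.mean(
            [s.planted_allegiance()[np.ix_(smn, vn)].mean() for s in ts.schedules]
        )
        assert cross(b) > cross(a) + 0.1

    def test_unknown_system_in_effect_rejected(self, mini_map):
        cfg = SimConfig(n_nodes=12, n_trials=3)
        with pytest.raises(SimulationError, match="unknown system"):
            make_condition_pair(cfg, ConditionEffect(switch_scale={"XXX": 0.5}), mini_map)
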