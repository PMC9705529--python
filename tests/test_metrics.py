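from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynmodnet.atlas import SystemMap
from dynmodnet.community import PartitionEnsemble
from dynmodnet.connectivity import ConnectivityStack, WindowSpec
from dynmodnet.metrics import (
    MetricError,
    allegiance,
    ensemble_flexibility,
    flexibility,
    integration,
    metric_frame,
    node_to_system_density,
    overall_integration,
    percent_change,
    recruitment,
)


def ens_of(labels: np.ndarray) -> PartitionEnsemble:
    labels = np.asarray(labels)
    return PartitionEnsemble(labels=labels, qs=np.zeros(labels.shape[0]))


class TestFlexibility:
    def test_worked_examples(self):
        assert flexibility(np.array([[1, 1, 2, 2]]))[0] == pytest.approx(0.25)
        assert flexibility(np.array([[3, 3, 3, 3]]))[0] == 0.0
        alternating = np.array([[1, 2] * 6])
        assert flexibility(alternating)[0] == pytest.approx(11 / 12)

    def test_single_layer_rejected(self):
        with pytest.raises(MetricError, match="T<2"):
            flexibility(np.array([[1], [2]]))

    def test_bounded_by_tminus1_over_t(self, rng):
        labels = rng.integers(1, 4, size=(10, 12))
        f = flexibility(labels)
        assert np.all((f >= 0) & (f <= 11 / 12))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_label_permutation(self, seed):
        r = np.random.default_rng(seed)
        labels = r.integers(1, 5, size=(6, 8))
        perm = r.permutation(np.arange(1, 5))
        relabelled = perm[labels - 1]
        assert np.array_equal(flexibility(labels), flexibility(relabelled))

    def test_ensemble_mean_over_repetitions(self):
        rep1 = np.array([[1, 1, 2, 2]])   # F = 1/4
        rep2 = np.array([[1, 2, 1, 2]])   # F = 3/4
        ens = ens_of(np.stack([rep1, rep2]))
        assert ensemble_flexibility(ens)[0] == pytest.approx(0.5)


class TestAllegiance:
    def test_all_in_one_module_gives_ones(self):
        ens = ens_of(np.ones((3, 4, 5), dtype=int))
        assert np.all(allegiance(ens) == 1.0)

    def test_fixed_disjoint_modules_give_block_matrix(self):
        labels = np.array([[1, 1], [1, 1], [2, 2], [2, 2]])  # (nodes, layers)
        ens = ens_of(np.stack([labels, labels]))
        P = allegiance(ens)
        expected = np.kron(np.eye(2), np.ones((2, 2)))
        assert np.array_equal(P, expected)

    def test_hand_ensemble_matches_pair_counting(self):
        # R=2 repetitions, T=2 layers, 3 nodes
        rep1 = np.array([[1, 1], [1, 2], [2, 2]])
        rep2 = np.array([[1, 2], [1, 2], [1, 1]])
        ens = ens_of(np.stack([rep1, rep2]))
        P = allegiance(ens)
        n_obs = 4  # (rep, layer) observations
        # brute force over observations
        expected = np.zeros((3, 3))
        for rep in (rep1, rep2):
            for l in range(2):
                for i in range(3):
                    for j in range(3):
                        expected[i, j] += rep[i, l] == rep[j, l]
        expected /= n_obs
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(P, expected)


@pytest.fixture(scope="module")
def small_map() -> SystemMap:
    return SystemMap(("SMN", "SMN", "DMN", "DMN"), named_systems=("SMN", "DMN"))


class TestRecruitmentIntegration:
    def test_uniform_allegiance_gives_unit_metrics(self, small_map):
        P = np.ones((4, 4))
        assert recruitment(P, small_map, "SMN") == 1.0
        assert integration(P, small_map, "SMN", "DMN") == 1.0

    def test_system_aligned_blocks(self, small_map):
        P = np.kron(np.eye(2), np.ones((2, 2)))
        assert recruitment(P, small_map, "SMN") == 1.0
        assert recruitment(P, small_map, "DMN") == 1.0
        assert integration(P, small_map, "SMN", "DMN") == 0.0

    def test_hand_fixture_matches_brute_force(self, small_map, rng):
        P = rng.random((4, 4))
        P = 0.5 * (P + P.T)
        np.fill_diagonal(P, 1.0)
        smn, dmn = [0, 1], [2, 3]
        brute_int = np.mean([P[i, j] for i in smn for j in dmn])
        assert integration(P, small_map, "SMN", "DMN") == pytest.approx(brute_int)
        brute_rec = np.mean([P[0, 1], P[1, 0]])
        assert recruitment(P, small_map, "SMN") == pytest.approx(brute_rec)

    def test_singleton_system_rejected(self):
        m = SystemMap(("SMN", "DMN", "DMN"))
        with pytest.raises(MetricError, match="singleton"):
            recruitment(np.ones((3, 3)), m, "SMN")

    def test_same_system_pair_rejected(self, small_map):
        with pytest.raises(MetricError, match="different"):
            integration(np.ones((4, 4)), small_map, "SMN", "SMN")

    def test_overall_is_mean_of_pairwise(self, mini_map, rng):
        P = rng.random((12, 12))
        P = 0.5 * (P + P.T)
        np.fill_diagonal(P, 1.0)
        systems = ("SMN", "DMN", "VN", "ATN")
        pairwise = [integration(P, mini_map, a, b) for a, b in combinations(systems, 2)]
        assert overall_integration(P, mini_map) == pytest.approx(np.mean(pairwise), abs=1e-15)


class TestDensityAndPercentChange:
    def make_stack(self, values: np.ndarray) -> ConnectivityStack:
        return ConnectivityStack(values=values, spec=WindowSpec(), fs=500.0)

    def test_uniform_stack_density_equals_weight(self, mini_map):
        v = np.full((2, 12, 12), 0.37)
        for l in range(2):
            np.fill_diagonal(v[l], 0.0)
        stack = self.make_stack(v)
        assert node_to_system_density(stack, mini_map, 0, "DMN") == pytest.approx(0.37)

    def test_zero_stack_gives_zero(self, mini_map):
        stack = self.make_stack(np.zeros((2, 12, 12)))
        assert node_to_system_density(stack, mini_map, 5, "VN") == 0.0

    def test_random_fixture_matches_triple_mean(self, rng):
        m = SystemMap(("SMN", "SMN", "DMN", "DMN"))
        v = rng.random((2, 4, 4))
        stack = self.make_stack(v)
        brute = np.mean([v[w, 1, j] for w in range(2) for j in (2, 3)])
        assert node_to_system_density(stack, m, 1, "DMN") == pytest.approx(brute)

    def test_empty_target_after_exclusion_rejected(self):
        m = SystemMap(("SMN", "DMN"))
        stack = self.make_stack(np.zeros((1, 2, 2)))
        with pytest.raises(MetricError, match="no target"):
            node_to_system_density(stack, m, 0, "SMN")

    def test_percent_change_arithmetic(self):
        signed, mag = percent_change(0.4, 0.2)
        assert signed == pytest.approx(-50.0)
        assert mag == pytest.approx(50.0)
        assert percent_change(0.3, 0.3)[0] == 0.0

    def test_percent_change_vector(self, rng):
        pre = rng.uniform(0.1, 1.0, size=10)
        post = rng.uniform(0.1, 1.0, size=10)
        signed, mag = percent_change(pre, post)
        assert np.allclose(signed, 100 * (post - pre) / pre)
        assert np.allclose(mag, np.abs(signed))

    def test_zero_baseline_rejected(self):
        with pytest.raises(MetricError, match="zero baseline"):
            percent_change(0.0, 0.5)


class TestMetricFrame:
    def test_tidy_structure_and_values(self, mini_map, rng):
        labels = rng.integers(1, 3, size=(5, 12, 12))
        ens = [PartitionEnsemble(labels=labels, qs=np.zeros(5))]
        frame = metric_frame(ens, None, mini_map, condition="Pre-Stim")
        assert set(frame.columns) == {"condition", "trial", "unit", "metric", "value"}
        flex_units = set(frame[frame["metric"] == "flexibility"]["unit"])
        assert flex_units == {"SMN", "DMN", "VN", "ATN"}
        overall = frame[(frame["metric"] == "integration") & (frame["unit"] == "overall")]
        assert len(overall) == 1
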