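"""Phase extraction, phase-locking, and weighted graph metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mumse.io import Recording
from mumse.network import (
    ConnectivityGraph,
    aver_cc,
    build_network,
    clustering_coefficient,
    compute_metrics,
    global_efficiency,
    instantaneous_phase,
    percent_change_ge,
    rpc,
    shortest_lengths,
)
from mumse.spectral import DEFAULT_BANDS

from _oracles import (
    clustering_coefficient_bruteforce,
    global_efficiency_bruteforce,
    random_symmetric_weights,
    shortest_path_bruteforce,
)

ALPHA = DEFAULT_BANDS["alpha"]


def graph_from(W, labels=None):
    labels = labels or tuple(f"n{i}" for i in range(len(W)))
    return ConnectivityGraph(labels, np.asarray(W, dtype=float))


class TestInstantaneousPhase:
    def test_pure_sinusoid_phase_ramp(self):
        fs = 500.0
        f0 = 10.5  # alpha band center
        t = np.arange(int(20 * fs)) / fs
        x = np.cos(2 * np.pi * f0 * t)
        phases, trim = instantaneous_phase(x, ALPHA, fs)
        dphi = np.angle(np.exp(1j * np.diff(phases)))
        assert np.abs(dphi - 2 * np.pi * f0 / fs).max() < 1e-3

    def test_sign_flip_shifts_phase_by_pi(self):
        fs = 250.0
        rng = np.random.default_rng(0)
        t = np.arange(int(30 * fs)) / fs
        x = np.cos(2 * np.pi * 10 * t) + 0.1 * rng.standard_normal(len(t))
        pa, _ = instantaneous_phase(x, ALPHA, fs)
        pb, _ = instantaneous_phase(-x, ALPHA, fs)
        diff = np.angle(np.exp(1j * (pa - pb)))
        assert np.allclose(np.abs(diff), np.pi, atol=1e-6)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            instantaneous_phase(np.ones(10_000), ALPHA, 500.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.random.default_rng(0).standard_normal(200),
                                ALPHA, 500.0)


class TestRPC:
    def test_constant_lag_gives_one(self, rng):
        pa = rng.uniform(-np.pi, np.pi, 500)
        assert rpc(pa, pa + 0.7) == pytest.approx(1.0)

    def test_uniform_grid_of_differences_cancels(self):
        n = 360
        pa = np.linspace(-np.pi, np.pi, n, endpoint=False)
        pb = np.zeros(n)
        assert rpc(pa, pb) == pytest.approx(0.0, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rpc(np.zeros(5), np.zeros(6))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.floats(-10, 10))
    def test_bounded_and_offset_invariant(self, seed, offset):
        rng = np.random.default_rng(seed)
        pa = rng.uniform(-np.pi, np.pi, 200)
        pb = rng.uniform(-np.pi, np.pi, 200)
        v = rpc(pa, pb)
        assert 0.0 <= v <= 1.0
        assert rpc(pa + offset, pb + offset) == pytest.approx(v, abs=1e-9)


class TestBuildNetwork:
    def test_full_symmetric_graph_with_distinct_pairs(self):
        from mumse.filters import fir_bandpass
        from mumse.synthetic import SynthSpec, gen_recording

        labels = ("C3", "C4", "Cz", "O1", "O2")
        amps = {(ch, "rest", "alpha"): 10.0 for ch in labels}
        spec = SynthSpec(n_channels=5, fs=500.0, duration_rest=10.0,
                         duration_task=4.0, band_amplitudes=amps,
                         noise_amplitude=0.5, seed=3, labels=labels)
        rest, _ = gen_recording(spec)
        trim = len(fir_bandpass(500.0, ALPHA.low, ALPHA.high))
        g = build_network(rest, ALPHA, (trim, 1000))
        assert g.n == 5
        assert np.allclose(g.W, g.W.T)
        assert np.all(np.diag(g.W) == 0)
        off = g.W[np.triu_indices(5, 1)]
        assert len(off) == 10 and np.all((off >= 0) & (off <= 1))

    def test_identical_channels_weight_one(self):
        rng = np.random.default_rng(1)
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        x = np.cos(2 * np.pi * 10 * t) + 0.05 * rng.standard_normal(len(t))
        y = rng.standard_normal(len(t))
        rec = Recording(np.vstack([x, x, y]), fs, ("C3", "C4", "Cz"))
        from mumse.filters import fir_bandpass

        trim = len(fir_bandpass(fs, ALPHA.low, ALPHA.high))
        g = build_network(rec, ALPHA, (trim, int(2 * fs)))
        assert g.W[0, 1] == pytest.approx(1.0)

    def test_short_segment_rejected(self, small_recording):
        with pytest.raises(ValueError, match="2.0 s"):
            build_network(small_recording, ALPHA, (0, 100))

    def test_degenerate_channel_named_in_error(self):
        fs = 250.0
        rng = np.random.default_rng(2)
        data = rng.standard_normal((2, int(30 * fs)))
        data[1] = 5.0  # flat channel
        rec = Recording(data, fs, ("C3", "Pz"))
        with pytest.raises(ValueError, match="Pz"):
            build_network(rec, ALPHA, (2000, int(2 * fs)))


class TestClusteringCoefficient:
    def test_uniform_complete_graph_all_ones(self, uniform_graph):
        for j in range(uniform_graph.n):
            assert clustering_coefficient(uniform_graph, j) == pytest.approx(1.0)

    def test_triangle_closed_form(self):
        W = [[0.0, 0.8, 0.5], [0.8, 0.0, 0.2], [0.5, 0.2, 0.0]]
        g = graph_from(W)
        expected = 2 * (0.8 * 0.5 * 0.2) ** (1 / 3) / (1.3 * 0.3)
        assert clustering_coefficient(g, 0) == pytest.approx(expected)
        assert clustering_coefficient(g, 0) == pytest.approx(
            clustering_coefficient_bruteforce(W, 0))

    def test_zero_weight_edge_annihilates_its_triangle(self):
        # node 0's only candidate triangles all contain a zero edge, so the
        # numerator vanishes even though node 0 has positive weighted degree
        W = [[0.0, 0.9, 0.0, 0.8],
             [0.9, 0.0, 0.4, 0.0],
             [0.0, 0.4, 0.0, 0.0],
             [0.8, 0.0, 0.0, 0.0]]
        g = graph_from(W)
        assert clustering_coefficient(g, 0) == 0.0

    def test_weighted_degree_at_most_one_is_undefined(self):
        # k_j (k_j - 1) <= 0 when the weighted degree does not exceed 1
        W = [[0.0, 0.9, 0.0], [0.9, 0.0, 0.4], [0.0, 0.4, 0.0]]
        assert math.isnan(clustering_coefficient(graph_from(W), 0))

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            W = random_symmetric_weights(n, rng)
            g = graph_from(W)
            for j in range(n):
                got = clustering_coefficient(g, j)
                exp = clustering_coefficient_bruteforce(W.tolist(), j)
                if math.isnan(exp):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(exp, rel=1e-12)

    def test_isolated_node_undefined(self):
        W = np.zeros((3, 3))
        W[1, 2] = W[2, 1] = 0.5
        g = graph_from(W)
        assert math.isnan(clustering_coefficient(g, 0))

    def test_count_degree_variant_bounded_by_one(self, rng):
        for _ in range(10):
            W = random_symmetric_weights(6, rng, zero_frac=0.0)
            g = graph_from(W)
            for j in range(6):
                assert clustering_coefficient(g, j, degree="count") <= 1.0 + 1e-12


class TestAverCC:
    def test_uniform_graph_average_is_one(self, uniform_graph):
        assert aver_cc(uniform_graph) == pytest.approx(1.0)

    def test_relabeling_invariance(self, rng):
        W = random_symmetric_weights(7, rng, zero_frac=0.0)
        g = graph_from(W)
        perm = rng.permutation(7)
        Wp = W[np.ix_(perm, perm)]
        gp = graph_from(Wp)
        assert aver_cc(gp) == pytest.approx(aver_cc(g), rel=1e-12)

    def test_equals_mean_of_bruteforce(self, rng):
        W = random_symmetric_weights(8, rng, zero_frac=0.0)
        g = graph_from(W)
        exp = np.mean([clustering_coefficient_bruteforce(W.tolist(), j)
                       for j in range(8)])
        assert aver_cc(g) == pytest.approx(exp, rel=1e-12)

    def test_all_undefined_is_error(self):
        g = graph_from(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            aver_cc(g)


class TestShortestLengths:
    def test_uniform_complete_graph_all_distances_one(self, uniform_graph):
        D = shortest_lengths(uniform_graph)
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(D[off], 1.0)
        assert np.all(np.diag(D) == 0)

    def test_direct_edge_beats_detour(self):
        W = [[0.0, 1.0, 0.5], [1.0, 0.0, 0.5], [0.5, 0.5, 0.0]]
        D = shortest_lengths(graph_from(W))
        # direct 1/0.5 = 2 vs detour 1/1 + 1/0.5 = 3
        assert D[0, 2] == pytest.approx(2.0)

    def test_missing_edge_routed_through_intermediate(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        D = shortest_lengths(graph_from(W))
        assert D[0, 2] == pytest.approx(2.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            W = random_symmetric_weights(n, rng)
            D = shortest_lengths(graph_from(W))
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    exp = shortest_path_bruteforce(W.tolist(), i, j)
                    assert D[i, j] == pytest.approx(exp, rel=1e-9) or \
                        (math.isinf(D[i, j]) and math.isinf(exp))

    def test_shortest_no_longer_than_direct_edge(self, rng):
        W = random_symmetric_weights(7, rng, zero_frac=0.0)
        D = shortest_lengths(graph_from(W))
        direct = 1.0 / W[W > 0]
        assert np.all(D[W > 0] <= direct + 1e-12)


class TestGlobalEfficiency:
    def test_uniform_complete_graph_ge_one(self, uniform_graph):
        assert global_efficiency(uniform_graph) == pytest.approx(1.0)

    def test_three_node_hand_enumeration(self):
        W = [[0.0, 1.0, 0.5], [1.0, 0.0, 0.5], [0.5, 0.5, 0.0]]
        ge = global_efficiency(graph_from(W))
        assert ge == pytest.approx(2 * (1.0 + 0.5 + 0.5) / 6)

    def test_disconnected_graph_ge_zero(self):
        assert global_efficiency(graph_from(np.zeros((4, 4)))) == 0.0

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            W = random_symmetric_weights(n, rng)
            got = global_efficiency(graph_from(W))
            exp = global_efficiency_bruteforce(W.tolist())
            assert got == pytest.approx(exp, rel=1e-9)

    def test_monotone_in_single_weight_increase(self, rng):
        for _ in range(10):
            W = random_symmetric_weights(6, rng)
            g0 = global_efficiency(graph_from(W))
            i, j = 1, 3
            W2 = W.copy()
            W2[i, j] = W2[j, i] = min(1.0, W[i, j] + 0.3)
            assert global_efficiency(graph_from(W2)) >= g0 - 1e-12

    def test_relabeling_invariance(self, rng):
        W = random_symmetric_weights(7, rng)
        perm = rng.permutation(7)
        assert global_efficiency(graph_from(W[np.ix_(perm, perm)])) == \
            pytest.approx(global_efficiency(graph_from(W)), rel=1e-12)


class TestPercentChangeGE:
    def test_identity(self):
        assert percent_change_ge(0.5, 0.5) == 0.0

    def test_drop(self):
        assert percent_change_ge(0.4, 0.5) == pytest.approx(-20.0)

    def test_zero_rest_rejected(self):
        with pytest.raises(ValueError):
            percent_change_ge(0.4, 0.0)

    def test_coupling_reduction_lowers_efficiency(self):
        """Weaker task-phase coupling yields negative GE percent change."""
        from mumse.filters import fir_bandpass
        from mumse.synthetic import SynthSpec, gen_recording

        labels = ("C3", "C4", "Cz", "P3")
        amps = {(ch, cond, "alpha"): 10.0
                for ch in labels for cond in ("rest", "task")}
        coupling_rest = {("Cz", ch, "alpha"): 4.0 for ch in labels if ch != "Cz"}
        coupling_task = {("Cz", ch, "alpha"): 1.0 for ch in labels if ch != "Cz"}
        base = dict(n_channels=4, fs=500.0, duration_rest=10.0, duration_task=10.0,
                    band_amplitudes=amps, noise_amplitude=0.5, seed=17, labels=labels)
        rest, _ = gen_recording(SynthSpec(coupling=coupling_rest, **base))
        _, task = gen_recording(SynthSpec(coupling=coupling_task, **base))
        trim = len(fir_bandpass(500.0, ALPHA.low, ALPHA.high))
        seg = (trim, 1000)
        ge_rest = global_efficiency(build_network(rest, ALPHA, seg))
        ge_task = global_efficiency(build_network(task, ALPHA, seg))
        assert percent_change_ge(ge_task, ge_rest) < 0


def test_compute_metrics_bundle(uniform_graph):
    m = compute_metrics(uniform_graph)
    assert m.aver_cc == pytest.approx(1.0)
    assert m.ge == pytest.approx(1.0)
    assert set(m.cc_by_node) == set(uniform_graph.labels)
    assert m.D.shape == (6, 6)
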