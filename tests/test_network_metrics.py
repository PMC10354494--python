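import numpy as np
import pytest

from colonynet import network_metrics as nm
from colonynet.network_construction import DailyNetwork
from oracles import (oracle_cv_edge_weight, oracle_edge_density,
                     oracle_local_metrics, oracle_path_metrics,
                     random_symmetric_weights)


def net_of(W, net_type="interaction"):
    W = np.asarray(W, dtype=float)
    nodes = [f"B{i}" for i in range(W.shape[0])]
    return DailyNetwork("C1", "2020-01-01", net_type, nodes, W)


def complete(n, w):
    W = np.full((n, n), w, dtype=float)
    np.fill_diagonal(W, 0.0)
    return W


class TestLocalMetrics:
    def test_complete_graph_closed_form(self):
        mwd, mbd, mew = nm.local_metrics(net_of(complete(4, 0.5)))
        assert (mwd, mbd, mew) == (1.5, 3.0, 0.5)

    def test_empty_network_gives_zeros(self):
        assert nm.local_metrics(net_of(np.zeros((5, 5)))) == (0.0, 0.0, 0.0)

    def test_single_node_undefined(self):
        out = nm.local_metrics(net_of(np.zeros((1, 1))))
        assert all(np.isnan(v) for v in out)


class TestIntermediateMetrics:
    def test_equal_positive_weights_have_zero_cv(self):
        cv, density = nm.intermediate_metrics(net_of(complete(5, 0.3)))
        assert cv == 0.0 and density == 1.0

    def test_density_counts_present_pairs(self):
        W = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 4)]:
            W[i, j] = W[j, i] = 0.2
        _, density = nm.intermediate_metrics(net_of(W))
        assert density == pytest.approx(0.4)

    def test_isolated_individual_excluded_from_cv(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        cv, _ = nm.intermediate_metrics(net_of(W))
        # birds 0 and 1 each have weights (0.4, 0); bird 2 is all-zero
        expected = np.std([0.4, 0.0], ddof=1) / np.mean([0.4, 0.0])
        assert cv == pytest.approx(expected)


class TestGlobalMetrics:
    def test_three_node_chain_by_hand(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        mpl, diam = nm.weighted_global_metrics(net_of(W))
        assert mpl == pytest.approx((0.5 + 0.5 + 1.0) / 3)
        assert diam == pytest.approx(1.0)

    def test_complete_graph_paths_equal_the_weight(self):
        mpl, diam = nm.weighted_global_metrics(net_of(complete(6, 0.2)))
        assert mpl == pytest.approx(0.2) and diam == pytest.approx(0.2)

    def test_no_edges_flagged_undefined(self):
        mpl, diam = nm.weighted_global_metrics(net_of(np.zeros((4, 4))))
        assert np.isnan(mpl) and np.isnan(diam)

    def test_inverse_weight_mode_uses_reciprocal_costs(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.25
        mpl, diam = nm.weighted_global_metrics(net_of(W), weight_mode="inverse")
        assert mpl == diam == pytest.approx(4.0)


@pytest.mark.parametrize("seed", range(12))
def test_metrics_match_reference_implementations(seed):
    W = random_symmetric_weights(np.random.default_rng(seed))
    net = net_of(W)
    assert nm.local_metrics(net) == pytest.approx(oracle_local_metrics(W),
                                                  abs=1e-12)
    cv, density = nm.intermediate_metrics(net)
    assert density == pytest.approx(oracle_edge_density(W), abs=1e-12)
    ocv = oracle_cv_edge_weight(W)
    if np.isnan(ocv):
        assert np.isnan(cv)
    else:
        assert cv == pytest.approx(ocv, abs=1e-12)
    if np.any(W):
        assert nm.weighted_global_metrics(net) == pytest.approx(
            oracle_path_metrics(W), abs=1e-12)


def test_paths_also_agree_with_networkx():
    import networkx as nx

    rng = np.random.default_rng(99)
    checked = 0
    while checked < 10:
        W = random_symmetric_weights(rng, p_edge=0.7)
        if not np.any(W):
            continue
        G = nx.from_numpy_array(W)
        comps = sorted(nx.connected_components(G), key=len)
        comp = comps[-1]
        if len(comp) < 2 or (len(comps) > 1 and len(comps[-2]) == len(comp)):
            continue  # ties in largest-component size are resolved arbitrarily
        lengths = dict(nx.all_pairs_dijkstra_path_length(
            G.subgraph(comp), weight="weight"))
        dists = [lengths[a][b] for a in comp for b in comp if a < b]
        mpl, diam = nm.weighted_global_metrics(net_of(W))
        assert mpl == pytest.approx(np.mean(dists))
        assert diam == pytest.approx(np.max(dists))
        checked += 1


class TestSmallestEdgeWeight:
    def test_minimum_positive_weight_across_days(self):
        nets = [net_of(complete(3, w)) for w in (0.2, 0.05, 0.4)]
        assert nm.study_smallest_edge_weight(nets, "interaction") == 0.05

    def test_all_zero_network_does_not_change_the_minimum(self):
        nets = [net_of(complete(3, 0.2)), net_of(np.zeros((4, 4)))]
        assert nm.study_smallest_edge_weight(nets, "interaction") == 0.2

    def test_equals_flat_scan_over_edge_weights(self):
        rng = np.random.default_rng(4)
        nets = [net_of(random_symmetric_weights(rng)) for _ in range(6)]
        flat = np.concatenate([n.W[np.triu_indices(n.n_nodes, 1)] for n in nets])
        assert nm.study_smallest_edge_weight(nets, "interaction") == \
            pytest.approx(flat[flat > 0].min())

    def test_no_positive_weight_is_an_error(self):
        with pytest.raises(ValueError, match="no positive"):
            nm.study_smallest_edge_weight([net_of(np.zeros((3, 3)))],
                                          "interaction")


class TestCorrection:
    def ctx(self, s=0.1, n_reps=100, seed=0, join="chain"):
        return nm.CorrectionContext(smallest_edge_weight=s, n_reps=n_reps,
                                    seed=seed, join=join)

    def test_connected_network_needs_no_correction(self):
        net = net_of(complete(5, 0.3))
        raw = nm.weighted_global_metrics(net)
        assert nm.corrected_global_metrics(net, self.ctx()) == raw
        assert nm.correct_global_metric(net, self.ctx(), nm.diameter_of) == raw[1]

    def test_worked_example_isolated_third_bird(self):
        # A-B at 0.5 plus isolated C; every join adds a 0.1 edge to C,
        # so diameter becomes 0.6 for either choice of representative.
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        net = net_of(W)
        corrected = nm.correct_global_metric(net, self.ctx(), nm.diameter_of)
        assert corrected == pytest.approx(0.6)

    def test_degenerate_randomness_is_seed_invariant(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        net = net_of(W)
        vals = [nm.correct_global_metric(net, self.ctx(seed=s), nm.diameter_of)
                for s in range(5)]
        assert vals == pytest.approx([0.6] * 5)

    def test_same_seed_gives_identical_corrections(self):
        rng = np.random.default_rng(21)
        W = random_symmetric_weights(rng, max_nodes=8, p_edge=0.25)
        net = net_of(W)
        a = nm.corrected_global_metrics(net, self.ctx(seed=5, n_reps=30))
        b = nm.corrected_global_metrics(net, self.ctx(seed=5, n_reps=30))
        assert a == b

    def test_corrected_diameter_never_below_raw(self):
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(20):
            W = random_symmetric_weights(rng, p_edge=0.25)
            net = net_of(W)
            raw = nm.weighted_global_metrics(net)
            if np.isnan(raw[0]):
                continue
            mpl, diam = nm.corrected_global_metrics(net, self.ctx(n_reps=20))
            assert diam >= raw[1] - 1e-12
            checked += 1
        assert checked > 5

    def test_scaling_weights_scales_path_metrics(self):
        # weights-as-costs: multiplying all weights and the smallest edge
        # weight by k multiplies both corrected path metrics by k
        rng = np.random.default_rng(14)
        k = 0.5
        for _ in range(6):
            W = random_symmetric_weights(rng, p_edge=0.3)
            if not np.any(W):
                continue
            base = nm.corrected_global_metrics(
                net_of(W), self.ctx(s=0.02, seed=3, n_reps=25))
            scaled = nm.corrected_global_metrics(
                net_of(W * k), self.ctx(s=0.02 * k, seed=3, n_reps=25))
            assert scaled == pytest.approx(tuple(k * v for v in base))


def test_metrics_table_is_deterministic_and_complete(tiny_study):
    from colonynet import build_networks, metrics_table

    detections, _ = tiny_study
    nets = build_networks(detections)
    t1 = metrics_table(nets, n_reps=15, seed=3)
    t2 = metrics_table(nets, n_reps=15, seed=3)
    assert t1.equals(t2)
    assert len(t1) == len(nets)
    finite = t1[nm.METRIC_NAMES].notna().all(axis=None)
    assert finite  # every network in the tiny study is observed
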