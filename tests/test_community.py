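import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from netlayers import (
    CommunityAssignment,
    ResolutionParams,
    consensus_partition,
    grid_search,
    louvain_optimize,
    modularity_score,
    null_weight,
)
from oracle_utils import (
    brute_force_q,
    enumerate_max_q,
    rgs_partitions,
    to_network,
    two_block_instance,
)


class TestNullWeight:
    def test_unit_dyads_hand_value(self, dyad_network):
        """Two unit dyads: k=1 everywhere, 2m=4, so V_ab = 1*1/4."""
        assert null_weight(dyad_network, 0, 1, 0) == pytest.approx(0.25)

    def test_regular_graph_uniform_null(self):
        A = np.ones((4, 4)) - np.eye(4)  # 3-regular
        net = to_network([A])
        vals = [null_weight(net, i, j, 0) for i in range(4) for j in range(4)]
        assert vals == pytest.approx([9 / 12] * 16)  # k^2 / 2m = 9/12

    def test_homogeneous_in_layer_scale(self):
        layers, _ = two_block_instance(5, 1, seed=0)
        net1 = to_network(layers)
        net2 = to_network([3.0 * layers[0]])
        assert null_weight(net2, 0, 1, 0) == pytest.approx(3 * null_weight(net1, 0, 1, 0))


class TestModularityScore:
    def test_dyad_partition_q_half(self, dyad_network):
        labels = np.array([[0], [0], [1], [1]])
        q = modularity_score(dyad_network, labels, ResolutionParams(1.0, 0.0))
        assert q == pytest.approx(0.5, abs=1e-15)

    def test_single_community_q_zero(self):
        layers, _ = two_block_instance(6, 1, seed=1)
        net = to_network(layers)
        q = modularity_score(net, np.zeros((6, 1), dtype=int), ResolutionParams(1.0, 0.0))
        assert q == pytest.approx(0.0, abs=1e-14)

    def test_agrees_with_brute_force_on_all_partitions(self):
        """Every partition of a 3-node x 2-layer network scores identically
        under the vectorized evaluator and the quadruple-loop oracle."""
        layers, _ = two_block_instance(3, 2, seed=2)
        net = to_network(layers)
        params = ResolutionParams(1.1, 0.3)
        for flat in rgs_partitions(6):
            labels = np.asarray(flat).reshape(2, 3).T
            q = modularity_score(net, labels, params)
            q_oracle = brute_force_q(layers, labels, 1.1, 0.3)
            assert q == pytest.approx(q_oracle, abs=1e-12)

    def test_label_permutation_invariance(self):
        layers, _ = two_block_instance(6, 3, seed=3)
        net = to_network(layers)
        rng = np.random.default_rng(0)
        params = ResolutionParams(1.2, 0.1)
        labels = rng.integers(0, 4, size=(6, 3))
        q0 = modularity_score(net, labels, params)
        for _ in range(5):
            perm = rng.permutation(10)
            assert modularity_score(net, perm[labels], params) == pytest.approx(q0, abs=1e-14)

    def test_omega_zero_reduces_to_weighted_single_layer_combination(self):
        """At omega=0, gamma=1, Q is the 2m-weighted mix of per-layer
        Newman-Girvan modularities (cross-checked against networkx)."""
        import networkx as nx

        layers, blocks = two_block_instance(8, 3, seed=4)
        net = to_network(layers)
        labels = np.tile(blocks[:, None], (1, 3))
        q_multi = modularity_score(net, labels, ResolutionParams(1.0, 0.0))
        twoms, qs = [], []
        for W in layers:
            G = nx.from_numpy_array(np.maximum(W, 0.0))
            comms = [set(np.where(blocks == b)[0]) for b in (0, 1)]
            qs.append(nx.community.modularity(G, comms, weight="weight"))
            twoms.append(np.maximum(W, 0.0).sum())
        expected = float(np.average(qs, weights=twoms))
        assert q_multi == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self, dyad_network):
        with pytest.raises(ValueError, match="shape"):
            modularity_score(dyad_network, np.zeros((3, 1), int), ResolutionParams())


class TestLouvain:
    def test_recovers_planted_blocks(self):
        layers, blocks = two_block_instance(12, 4, seed=5, lo=0.0, hi=0.1)
        net = to_network(layers)
        for seed in (0, 1, 2):
            a = louvain_optimize(net, ResolutionParams(1.0, 0.1), seed=seed)
            for s in range(4):
                assert adjusted_rand_score(blocks, a.labels[:, s]) == 1.0

    def test_large_omega_forces_node_constant_labels(self):
        layers, _ = two_block_instance(8, 3, seed=6)
        net = to_network(layers)
        a = louvain_optimize(net, ResolutionParams(1.0, 10.0), seed=0)
        # every node keeps one label across all layers
        assert np.all(a.labels == a.labels[:, [0]])

    def test_achieved_q_beats_singletons(self):
        layers, _ = two_block_instance(7, 2, seed=7)
        net = to_network(layers)
        params = ResolutionParams(1.3, 0.2)
        singleton = np.arange(14).reshape(2, 7).T
        q_single = modularity_score(net, singleton, params)
        a = louvain_optimize(net, params, seed=0)
        assert a.q_value >= q_single

    def test_attains_enumerated_maximum_on_tiny_instance(self):
        layers, _ = two_block_instance(4, 2, seed=8)
        net = to_network(layers)
        qmax, _ = enumerate_max_q(layers, 1.0, 0.2)
        a = louvain_optimize(net, ResolutionParams(1.0, 0.2), seed=0)
        assert a.q_value == pytest.approx(qmax, abs=1e-12)

    def test_reported_q_matches_score_of_labels(self):
        layers, _ = two_block_instance(6, 2, seed=9)
        net = to_network(layers)
        params = ResolutionParams(1.2, 0.1)
        a = louvain_optimize(net, params, seed=3)
        assert a.q_value == pytest.approx(modularity_score(net, a.labels, params), abs=1e-12)

    def test_monotone_coupling_homogenizes_labels(self):
        layers, _ = two_block_instance(10, 4, seed=10, lo=0.0, hi=0.4)
        net = to_network(layers)
        distinct = []
        for omega in (0.0, 0.5, 10.0):
            a = louvain_optimize(net, ResolutionParams(1.0, omega), seed=1)
            per_node = np.mean([np.unique(a.labels[i]).size for i in range(10)])
            distinct.append(per_node)
        assert distinct[0] >= distinct[1] >= distinct[2]
        assert distinct[2] == 1.0


class TestConsensus:
    def test_single_iteration_equals_single_run(self):
        layers, _ = two_block_instance(8, 2, seed=11)
        net = to_network(layers)
        params = ResolutionParams(1.0, 0.1)
        cons = consensus_partition(net, params, n_iter=1, seed=5)
        # the consensus of one run is that run's partition
        single_ss = np.random.SeedSequence(5).spawn(102)[0]
        single = louvain_optimize(net, params, seed=np.random.default_rng(single_ss))
        assert adjusted_rand_score(cons.labels.ravel(), single.labels.ravel()) == 1.0

    def test_unanimous_runs_give_that_partition(self):
        """On a high-contrast instance every run finds the planted blocks,
        so the consensus must equal them too."""
        layers, blocks = two_block_instance(10, 3, seed=12, lo=0.0, hi=0.05)
        net = to_network(layers)
        cons = consensus_partition(net, ResolutionParams(1.0, 0.1), n_iter=8, seed=0)
        for s in range(3):
            assert adjusted_rand_score(blocks, cons.labels[:, s]) == 1.0

    def test_consensus_at_least_as_good_as_median_run(self, small_cohorts):
        import netlayers as nl

        spec, layers_a, _, truth = small_cohorts
        atlas = truth.atlas
        mats = [nl.build_connectivity(ts, atlas, k, "A") for k, ts in enumerate(layers_a)]
        net = nl.assemble_multilayer(mats, atlas)
        params = ResolutionParams(1.2, 0.1)
        run_aris = []
        for seed in range(8):
            a = louvain_optimize(net, params, seed=seed)
            run_aris.append(
                np.median(
                    [adjusted_rand_score(truth.true_labels["A"], a.labels[:, s]) for s in range(4)]
                )
            )
        cons = consensus_partition(net, params, n_iter=8, seed=99)
        cons_ari = min(
            adjusted_rand_score(truth.true_labels["A"], cons.labels[:, s]) for s in range(4)
        )
        assert cons_ari >= max(run_aris) - 1e-12

    def test_determinism(self):
        layers, _ = two_block_instance(8, 2, seed=13)
        net = to_network(layers)
        c1 = consensus_partition(net, ResolutionParams(1.2, 0.1), n_iter=5, seed=7)
        c2 = consensus_partition(net, ResolutionParams(1.2, 0.1), n_iter=5, seed=7)
        np.testing.assert_array_equal(c1.labels, c2.labels)
        assert c1.q_value == c2.q_value


class TestGridSearch:
    def test_singleton_grid_returns_that_cell(self):
        layers, _ = two_block_instance(6, 2, seed=14)
        net = to_network(layers)
        surf = grid_search(net, gamma_grid=(1.2,), omega_grid=(0.1,), repeats=2, seed=0)
        assert surf.best == ResolutionParams(1.2, 0.1)
        assert surf.mean_q.shape == (1, 1)

    def test_default_grids_include_reported_optimum(self):
        from netlayers.community import DEFAULT_GAMMA_GRID, DEFAULT_OMEGA_GRID

        assert 1.2 in DEFAULT_GAMMA_GRID
        assert 0.1 in DEFAULT_OMEGA_GRID

    def test_surface_reproducible_under_fixed_seed(self):
        layers, _ = two_block_instance(6, 2, seed=15)
        net = to_network(layers)
        s1 = grid_search(net, (1.0, 1.2), (0.0, 0.1), repeats=2, seed=3)
        s2 = grid_search(net, (1.0, 1.2), (0.0, 0.1), repeats=2, seed=3)
        np.testing.assert_array_equal(s1.mean_q, s2.mean_q)
        assert s1.best == s2.best

    def test_grid_validation(self):
        layers, _ = two_block_instance(4, 1, seed=16)
        net = to_network(layers)
        with pytest.raises(ValueError, match="monotone"):
            grid_search(net, (1.2, 1.0), (0.1,), repeats=1, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(net, (), (0.1,), repeats=1, seed=0)


class TestAssignmentContainer:
    def test_validation(self):
        with pytest.raises(ValueError, match="integer"):
            CommunityAssignment(np.zeros((2, 2)), ResolutionParams(), 0.0)
        with pytest.raises(ValueError, match="non-negative"):
            CommunityAssignment(-np.ones((2, 2), dtype=int), ResolutionParams(), 0.0)

    def test_tsv_roundtrip(self, tmp_path):
        labels = np.array([[0, 1], [2, 1], [0, 0]])
        a = CommunityAssignment(labels, ResolutionParams(), 0.5)
        a.to_tsv(tmp_path / "a.tsv")
        back = CommunityAssignment.from_tsv(tmp_path / "a.tsv")
        np.testing.assert_array_equal(back.labels, labels)

    def test_resolution_params_validation(self):
        with pytest.raises(ValueError):
            ResolutionParams(gamma=0.0)
        with pytest.raises(ValueError):
            ResolutionParams(omega=-0.1)
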