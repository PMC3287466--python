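import itertools

import networkx as nx
import numpy as np
import pytest

from rotamrf.fixtures import make_toy_mrf
from rotamrf.inference import (
    InferenceConfig,
    compute_edge_appearance,
    exact_marginals,
    gbp,
    lbp,
    mean_field,
    run_inference,
    trbp,
    uniform_edge_appearance,
)
from rotamrf.potentials import MarkovRandomField

TIGHT = InferenceConfig(max_iterations=500, tolerance=1e-12)


def max_diff(a, b, vertices):
    return max(float(np.max(np.abs(a[i] - b[i]))) for i in vertices)


def brute_force_rho(g: nx.Graph):
    """Spanning-tree edge-appearance by explicit enumeration (oracle)."""
    n = g.number_of_nodes()
    edges = list(g.edges)
    trees = [
        t for t in itertools.combinations(edges, n - 1)
        if nx.is_connected(nx.Graph(list(t))) and len(nx.Graph(list(t))) == n
    ]
    counts = {e: 0 for e in edges}
    for t in trees:
        for e in t:
            counts[e] += 1
    return {tuple(sorted(e)): c / len(trees) for e, c in counts.items()}


class TestExactMarginals:
    def test_flat_potentials_give_uniform(self):
        mrf = make_toy_mrf(4, "cycle", 3, 0)
        flat = MarkovRandomField(
            mrf.graph,
            {i: np.ones(3) for i in mrf.graph.vertices},
            {e: np.ones((3, 3)) for e in mrf.edge_potentials},
        )
        ms = exact_marginals(flat)
        for i in flat.graph.vertices:
            assert ms[i] == pytest.approx([1 / 3] * 3)

    def test_symmetric_two_vertex_chain(self):
        mrf = make_toy_mrf(2, "chain", 2, 0)
        sym = MarkovRandomField(
            mrf.graph,
            {0: np.ones(2), 1: np.ones(2)},
            {(0, 1): np.array([[2.0, 1.0], [1.0, 2.0]])},
        )
        ms = exact_marginals(sym)
        assert ms[0] == pytest.approx([0.5, 0.5])
        assert ms[1] == pytest.approx([0.5, 0.5])

    def test_single_vertex_normalizes_potential(self):
        mrf = make_toy_mrf(1, "chain", 4, 3)
        ms = exact_marginals(mrf)
        v = mrf.vertex_potentials[0]
        assert ms[0] == pytest.approx(v / v.sum())

    def test_refuses_oversized_state_space(self):
        mrf = make_toy_mrf(8, "chain", 4, 0)
        with pytest.raises(ValueError, match="cap"):
            exact_marginals(mrf, cap=1000)


class TestTreeExactness:
    @pytest.mark.parametrize("seed", range(25))
    def test_all_bp_variants_exact_on_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        states = int(rng.integers(2, 5))
        topo = "chain" if seed % 2 else "tree"
        mrf = make_toy_mrf(n, topo, states, seed)
        ex = exact_marginals(mrf)
        for ms in (
            lbp(mrf, TIGHT),
            trbp(mrf, uniform_edge_appearance(mrf.graph), TIGHT),
            gbp(mrf, TIGHT),
        ):
            assert ms.converged
            assert max_diff(ms, ex, mrf.graph.vertices) < 1e-8


class TestLBP:
    def test_single_vertex(self):
        mrf = make_toy_mrf(1, "chain", 3, 1)
        ms = lbp(mrf)
        v = mrf.vertex_potentials[0]
        assert ms[0] == pytest.approx(v / v.sum())
        assert ms.converged and ms.iterations_used == 1

    def test_weakly_coupled_cycle_near_exact(self):
        mrf = make_toy_mrf(4, "cycle", 3, 5)
        # weaken couplings towards the near-flat regime
        weak = MarkovRandomField(
            mrf.graph,
            mrf.vertex_potentials,
            {e: 1.0 + 0.01 * (m - 1.0) for e, m in mrf.edge_potentials.items()},
        )
        ms = lbp(weak, TIGHT)
        ex = exact_marginals(weak)
        assert max_diff(ms, ex, weak.graph.vertices) < 1e-3

    def test_beliefs_normalized(self):
        mrf = make_toy_mrf(6, "cycle", 3, 9)
        ms = lbp(mrf, InferenceConfig())
        for i in mrf.graph.vertices:
            assert ms[i].sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(ms[i] >= 0)

    def test_nonconvergence_is_reported_not_raised(self):
        mrf = make_toy_mrf(4, "cycle", 2, 2)
        ms = lbp(mrf, InferenceConfig(max_iterations=1, tolerance=1e-300))
        assert not ms.converged
        assert ms.iterations_used == 1
        assert ms.max_residual > 0

    def test_random_schedule_and_init_still_converge_to_fixed_point(self):
        mrf = make_toy_mrf(5, "tree", 3, 4)
        a = lbp(mrf, TIGHT)
        b = lbp(
            mrf,
            InferenceConfig(
                max_iterations=500, tolerance=1e-12, schedule="random",
                init="random", seed=7,
            ),
        )
        assert max_diff(a, b, mrf.graph.vertices) < 1e-8


class TestMeanField:
    def test_edgeless_mrf_is_exact(self):
        mrf = make_toy_mrf(3, "chain", 3, 6)
        edgeless = MarkovRandomField(
            type(mrf.graph)(vertices=mrf.graph.vertices, edges=set(),
                            candidates=mrf.graph.candidates),
            mrf.vertex_potentials,
            {},
        )
        ms = mean_field(edgeless, TIGHT)
        ex = exact_marginals(edgeless)
        assert max_diff(ms, ex, edgeless.graph.vertices) < 1e-10

    def test_converged_output_is_fixed_point(self):
        mrf = make_toy_mrf(5, "cycle", 3, 8)
        ms = mean_field(mrf, InferenceConfig(max_iterations=300, tolerance=1e-10))
        assert ms.converged
        again = mean_field(mrf, InferenceConfig(max_iterations=300, tolerance=1e-10))
        assert max_diff(ms, again, mrf.graph.vertices) < 1e-9


class TestEdgeAppearance:
    def test_tree_edges_are_one(self):
        mrf = make_toy_mrf(6, "tree", 2, 3)
        rho = compute_edge_appearance(mrf.graph)
        assert all(v == 1.0 for v in rho.rho.values())

    def test_triangle_is_two_thirds(self):
        mrf = make_toy_mrf(3, "cycle", 2, 0)
        rho = compute_edge_appearance(mrf.graph)
        assert all(v == pytest.approx(2 / 3, abs=1e-12) for v in rho.rho.values())

    def test_four_cycle_is_three_quarters(self):
        mrf = make_toy_mrf(4, "cycle", 2, 0)
        rho = compute_edge_appearance(mrf.graph)
        assert all(v == pytest.approx(3 / 4, abs=1e-12) for v in rho.rho.values())

    @pytest.mark.parametrize("n,p,seed", [(4, 0.7, 0), (5, 0.6, 1), (6, 0.5, 2), (6, 0.8, 3)])
    def test_matches_spanning_tree_enumeration(self, n, p, seed):
        g = nx.gnp_random_graph(n, p, seed=seed)
        if not nx.is_connected(g):
            g = nx.compose(g, nx.path_graph(n))
        rho = compute_edge_appearance(g)
        brute = brute_force_rho(g)
        for e, want in brute.items():
            assert rho.get(*e) == pytest.approx(want, abs=1e-9)


class TestTRBP:
    @pytest.mark.parametrize("topology", ["chain", "tree", "cycle", "complete"])
    def test_rho_one_reduces_to_lbp(self, topology):
        mrf = make_toy_mrf(5 if topology != "complete" else 4, topology, 3, 11)
        cfg = InferenceConfig(max_iterations=80, tolerance=1e-13)
        a = lbp(mrf, cfg)
        b = trbp(mrf, uniform_edge_appearance(mrf.graph), cfg)
        assert max_diff(a, b, mrf.graph.vertices) < 1e-10

    def test_single_vertex(self):
        mrf = make_toy_mrf(1, "chain", 3, 2)
        ms = trbp(mrf, uniform_edge_appearance(mrf.graph))
        v = mrf.vertex_potentials[0]
        assert ms[0] == pytest.approx(v / v.sum())

    def test_true_rho_on_loopy_graph_converges(self):
        mrf = make_toy_mrf(5, "cycle", 3, 13)
        ms = trbp(mrf, None, InferenceConfig(max_iterations=300, tolerance=1e-8))
        for i in mrf.graph.vertices:
            assert ms[i].sum() == pytest.approx(1.0, abs=1e-9)


class TestGBP:
    def test_triangle_free_matches_lbp(self):
        mrf = make_toy_mrf(6, "cycle", 3, 17)
        a = lbp(mrf, TIGHT)
        b = gbp(mrf, TIGHT)
        assert a.converged and b.converged
        assert max_diff(a, b, mrf.graph.vertices) < 1e-8

    def test_single_triangle_exact(self):
        mrf = make_toy_mrf(3, "cycle", 3, 19)
        ms = gbp(mrf, TIGHT)
        ex = exact_marginals(mrf)
        assert max_diff(ms, ex, mrf.graph.vertices) < 1e-8

    def test_complete_graph_runs_and_normalizes(self):
        mrf = make_toy_mrf(5, "complete", 2, 23)
        ms = gbp(mrf, InferenceConfig(max_iterations=200))
        for i in mrf.graph.vertices:
            assert ms[i].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_vertex(self):
        mrf = make_toy_mrf(1, "chain", 2, 29)
        ms = gbp(mrf)
        v = mrf.vertex_potentials[0]
        assert ms[0] == pytest.approx(v / v.sum())


class TestDispatchAndInvariance:
    def test_unknown_algorithm(self):
        mrf = make_toy_mrf(3, "chain", 2, 0)
        with pytest.raises(ValueError, match="unknown algorithm"):
            run_inference(mrf, "maxproduct")

    @pytest.mark.parametrize("alg", ["lbp", "mf", "trbp", "gbp"])
    def test_uniform_rescaling_invariance(self, alg):
        mrf = make_toy_mrf(5, "cycle", 3, 31)
        scaled = MarkovRandomField(
            mrf.graph,
            {i: 7.3 * v for i, v in mrf.vertex_potentials.items()},
            {e: 0.21 * m for e, m in mrf.edge_potentials.items()},
        )
        cfg = InferenceConfig(max_iterations=300, tolerance=1e-12)
        a = run_inference(mrf, alg, cfg)
        b = run_inference(scaled, alg, cfg)
        assert max_diff(a, b, mrf.graph.vertices) < 1e-9

    def test_vertex_relabeling_invariance(self):
        mrf = make_toy_mrf(5, "chain", 3, 37)
        perm = [4, 3, 2, 1, 0]
        from rotamrf.interaction_graph import InteractionGraph

        relabeled = MarkovRandomField(
            InteractionGraph(
                vertices=[perm[i] for i in mrf.graph.vertices],
                edges={frozenset(perm[v] for v in e) for e in mrf.graph.edges},
                candidates={perm[i]: c for i, c in mrf.graph.candidates.items()},
            ),
            {perm[i]: v for i, v in mrf.vertex_potentials.items()},
            {
                tuple(sorted((perm[i], perm[j]))): (
                    m if perm[i] < perm[j] else m.T
                )
                for (i, j), m in mrf.edge_potentials.items()
            },
        )
        a = lbp(mrf, TIGHT)
        b = lbp(relabeled, TIGHT)
        assert max(
            float(np.max(np.abs(a[i] - b[perm[i]]))) for i in mrf.graph.vertices
        ) < 1e-8
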