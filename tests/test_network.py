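"""DPI pruning and interactome inference against planted truth."""

import itertools

import numpy as np
import pytest

from regnet import NetworkParams, apply_dpi, infer_interactome, synthetic


def dpi_oracle(edges, regulators, tolerance):
    """Exhaustive-triple reference implementation of the triangle rule."""
    regulators = set(regulators)
    edges = {tuple(sorted(k)): w for k, w in edges.items()}
    nodes = sorted({n for pair in edges for n in pair})
    removed = set()
    for a, b, c in itertools.combinations(nodes, 3):
        triangle = []
        for u, v in ((a, b), (a, c), (b, c)):
            key = (u, v) if u <= v else (v, u)
            if key not in edges:
                triangle = None
                break
            triangle.append(key)
        if triangle is None:
            continue
        for mid in (a, b, c):
            if mid not in regulators:
                continue
            legs = [k for k in triangle if mid in k]
            (direct,) = [k for k in triangle if mid not in k]
            if edges[direct] < (1 - tolerance) * min(edges[legs[0]], edges[legs[1]]):
                removed.add(direct)
    return {k: w for k, w in edges.items() if k not in removed}


class TestDPI:
    def test_textbook_triangle_drops_weakest_edge(self):
        edges = {("A", "B"): 0.9, ("B", "C"): 0.8, ("A", "C"): 0.3}
        pruned = apply_dpi(edges, regulators={"A", "B", "C"})
        assert set(pruned) == {("A", "B"), ("B", "C")}

    def test_two_node_graph_unchanged(self):
        edges = {("A", "B"): 0.5}
        assert apply_dpi(edges, regulators={"A"}) == edges

    def test_non_regulator_intermediate_does_not_prune(self):
        edges = {("A", "B"): 0.9, ("B", "C"): 0.8, ("A", "C"): 0.3}
        # B (the only intermediate stronger than the weak edge) is a target
        pruned = apply_dpi(edges, regulators={"A", "C"})
        assert pruned == edges

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            nodes = [f"n{i}" for i in range(15)]
            regulators = set(rng.choice(nodes, size=5, replace=False))
            edges = {}
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.35:
                    edges[(a, b)] = float(rng.random())
            tol = float(rng.choice([0.0, 0.1, 0.3]))
            assert apply_dpi(edges, regulators, tol) == dpi_oracle(
                edges, regulators, tol
            )

    def test_every_removal_is_justified_by_a_triangle(self):
        # no triangle ever removes its own strongest edge: each removed
        # edge must be the strict weakest leg of some regulator-mediated
        # triangle (an edge can still be strongest in one triangle and
        # weakest in another)
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(10)]
        edges = {
            tuple(sorted((a, b))): float(rng.random())
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.5
        }
        regulators = set(nodes[:4])
        pruned = apply_dpi(edges, regulators=regulators)
        removed = set(edges) - set(pruned)
        adjacency: dict[str, dict[str, float]] = {}
        for (a, b), w in edges.items():
            adjacency.setdefault(a, {})[b] = w
            adjacency.setdefault(b, {})[a] = w
        for a, c in removed:
            justified = any(
                b in adjacency[a] and b in adjacency[c]
                and edges[(a, c)] < min(adjacency[a][b], adjacency[c][b])
                for b in regulators
                if b not in (a, c)
            )
            assert justified, f"edge {(a, c)} removed without a justifying triangle"


class TestInferInteractome:
    def test_noise_free_recovery_is_exact(self):
        net = synthetic.generate_network(5, 8, 0.0, 30, 0.0, seed=0)
        design = synthetic.StudyDesign(("A",), ("x", "y"), 20)
        expr, _ = synthetic.simulate_expression(net, design, noise_sd=1e-6, seed=0)
        params = NetworkParams(p_threshold=1e-8, n_bootstrap=0, seed=0)
        inter = infer_interactome(expr, net.regulators, params)
        inferred = {
            (r, e.target) for r, edges in inter.regulons.items() for e in edges
        }
        planted = net.edge_set()
        assert planted <= inferred
        background = set(net.background_genes)
        assert not {e for e in inferred if e[1] in background}

    def test_edges_meet_threshold_and_no_self_edges(self, desk_data):
        net, _, expr, _ = desk_data
        params = NetworkParams(bonferroni=True, n_bootstrap=0, seed=1)
        inter = infer_interactome(expr, net.regulators, params)
        thr = inter.params["applied_mi_threshold"]
        for reg, edges in inter.regulons.items():
            for e in edges:
                assert e.target != reg
                assert e.mi >= thr

    def test_absent_regulators_skipped_and_reported(self, desk_data):
        net, _, expr, _ = desk_data
        params = NetworkParams(mi_threshold=0.2, n_bootstrap=0)
        inter = infer_interactome(expr, net.regulators + ["GHOST"], params)
        assert inter.params["skipped_regulators"] == ["GHOST"]
        assert "GHOST" not in inter.regulons

    def test_too_few_samples_and_empty_regulators_rejected(self, desk_data):
        net, _, expr, _ = desk_data
        with pytest.raises(ValueError):
            infer_interactome(expr.subset_samples(expr.samples[:5]), net.regulators)
        with pytest.raises(ValueError):
            infer_interactome(expr, [])

    def test_bootstrap_consensus_keeps_maximal_support(self):
        net = synthetic.generate_network(2, 6, 0.0, 10, 0.0, seed=2)
        design = synthetic.StudyDesign(("A",), ("x", "y"), 15)
        expr, _ = synthetic.simulate_expression(net, design, noise_sd=0.2, seed=2)
        params = NetworkParams(mi_threshold=0.3, n_bootstrap=12, seed=2)
        inter = infer_interactome(expr, net.regulators, params)
        assert inter.n_edges() > 0
        for reg, edges in inter.regulons.items():
            for e in edges:
                assert 0 < e.support <= 12
        # strong planted edges supported in every run must be present
        full = [
            (r, e.target)
            for r, edges in inter.regulons.items()
            for e in edges
            if e.support == 12
        ]
        assert full, "expected at least one edge with maximal support"
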