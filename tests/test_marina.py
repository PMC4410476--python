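"""Master-regulator calling: signatures, trimming, NES, overlap test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from regnet import synthetic
from regnet.containers import Edge, EnrichmentResult, GeneSignature
from regnet.marina import (
    call_candidates,
    compute_signature,
    marina,
    mr_overlap_test,
    trim_regulon,
)

from conftest import truth_interactome


class TestSignature:
    def test_welch_t_matches_direct_formula(self, desk_data):
        _, _, expr, _ = desk_data
        sig = compute_signature(expr, "non_dependent", "dependent")
        a = expr.values[expr.samples_in_group("non_dependent")].to_numpy()
        b = expr.values[expr.samples_in_group("dependent")].to_numpy()
        for i, gene in enumerate(expr.genes[:50]):
            ma, mb = a[i].mean(), b[i].mean()
            va, vb = a[i].var(ddof=1), b[i].var(ddof=1)
            expected = (mb - ma) / math.sqrt(va / a.shape[1] + vb / b.shape[1])
            assert sig.scores[gene] == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_give_zero_t(self):
        values = pd.DataFrame(
            np.tile(np.arange(4.0), (3, 1)),
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3", "s4"],
        )
        ann = pd.DataFrame(
            {"region": "A", "group": ["x", "x", "y", "y"], "subject": "s"},
            index=values.columns,
        )
        from regnet.containers import ExpressionMatrix

        # per gene, groups x and y have identical means and variances
        values.loc[:] = [[1, 2, 1, 2], [0, 5, 0, 5], [3, 4, 3, 4]]
        sig = compute_signature(ExpressionMatrix(values, ann), "x", "y")
        assert np.allclose(sig.scores, 0.0)

    def test_dominant_effect_ranks_first(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.standard_normal((5, 8)) * 0.1,
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        values.iloc[3, :4] = 1.0
        values.iloc[3, 4:] = [3.0, 3.001, 2.999, 3.0005]
        ann = pd.DataFrame(
            {"region": "A", "group": ["x"] * 4 + ["y"] * 4, "subject": "s"},
            index=values.columns,
        )
        from regnet.containers import ExpressionMatrix

        sig = compute_signature(ExpressionMatrix(values, ann), "x", "y")
        assert sig.ranking()[0] == "g3"

    def test_missing_group_lists_available(self, desk_data):
        _, _, expr, _ = desk_data
        with pytest.raises(ValueError, match="naive"):
            compute_signature(expr, "nonexistent", "dependent")


class TestTrimRegulon:
    def test_small_regulon_unchanged(self):
        edges = [Edge(f"t{i}", 0.1 * i) for i in range(40)]
        assert trim_regulon(edges, 100) == edges

    def test_trims_to_top_mi(self):
        rng = np.random.default_rng(1)
        edges = [Edge(f"t{i}", float(rng.random())) for i in range(150)]
        kept = trim_regulon(edges, 100)
        assert len(kept) == 100
        dropped = set(e.target for e in edges) - set(e.target for e in kept)
        min_kept = min(e.mi for e in kept)
        for e in edges:
            if e.target in dropped:
                assert e.mi <= min_kept

    def test_boundary_ties_resolved_by_support_then_id(self):
        edges = [
            Edge("a", 0.5, support=1),
            Edge("b", 0.5, support=9),
            Edge("c", 0.5, support=1),
            Edge("d", 0.9, support=0),
        ]
        kept = trim_regulon(edges, 2)
        assert [e.target for e in kept] == ["d", "b"]


class TestMarina:
    def test_planted_regulator_tops_ranking(self, desk_data):
        net, _, expr, _ = desk_data
        sig = compute_signature(expr, "non_dependent", "dependent")
        results = marina(truth_interactome(net), sig, n_permutations=1000, seed=0)
        assert results[0].regulator == "R001"
        assert results[0].p < 0.01
        assert results[0].nes > results[1].nes

    def test_null_nes_standardised(self, small_net):
        design = synthetic.StudyDesign(("A",), ("x", "y"), 12)
        expr = synthetic.simulate_null_expression(small_net, design, seed=3)
        sig = compute_signature(expr, "x", "y")
        results = marina(truth_interactome(small_net), sig, n_permutations=2000, seed=3)
        for r in results:
            assert abs(r.nes) < 4.0
            # normal-map and empirical tails agree to Monte-Carlo accuracy
            assert r.p_empirical == pytest.approx(norm.sf(r.nes), abs=0.08)

    def test_eligibility_rule_excludes_small_regulons(self, small_net):
        design = synthetic.StudyDesign(("A",), ("x", "y"), 12)
        expr = synthetic.simulate_null_expression(small_net, design, seed=4)
        sig = compute_signature(expr, "x", "y")
        inter = truth_interactome(small_net)
        inter.regulons["R001"] = inter.regulons["R001"][:10]  # below 26
        results = marina(inter, sig, n_permutations=200, seed=4)
        assert "R001" not in {r.regulator for r in results}

    def test_no_eligible_regulator_warns_and_returns_empty(self, small_net):
        design = synthetic.StudyDesign(("A",), ("x", "y"), 12)
        expr = synthetic.simulate_null_expression(small_net, design, seed=5)
        sig = compute_signature(expr, "x", "y")
        results = marina(truth_interactome(small_net), sig, min_regulon=1000)
        assert results == []


class TestCandidates:
    def test_empty_input(self):
        assert call_candidates([]) == []

    def test_boundary_p_excluded(self):
        res = [
            EnrichmentResult("a", 0.5, 2.5, 0.01, 0.01, [], 30),
            EnrichmentResult("b", 0.5, 2.6, 0.009, 0.02, [], 30),
        ]
        called = call_candidates(res, alpha=0.01)
        assert [r.regulator for r in called] == ["b"]

    def test_empirical_p_selectable(self):
        res = [EnrichmentResult("a", 0.5, 2.5, 0.5, 0.001, [], 30)]
        assert call_candidates(res, 0.01, use="empirical") == res
        assert call_candidates(res, 0.01, use="normal") == []


class TestOverlap:
    def test_worked_hypergeometric_case(self):
        # |U|=10, |A|=5, |B|=4, overlap 4: P = C(5,4) C(5,0) / C(10,4) = 5/210
        universe = [f"r{i}" for i in range(10)]
        k, p = mr_overlap_test(universe[:5], universe[1:5], universe)
        assert k == 4
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_bounded_by_one(self):
        universe = [f"r{i}" for i in range(8)]
        k, p = mr_overlap_test(universe[:3], universe[5:], universe)
        assert k == 0
        assert 0 < p <= 1

    def test_degenerate_full_sets(self):
        universe = ["a", "b", "c"]
        k, p = mr_overlap_test(universe, universe, universe)
        assert k == 3
        assert p == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            mr_overlap_test({"x"}, {"a"}, {"a", "b"})
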