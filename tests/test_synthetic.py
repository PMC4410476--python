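"""Generator properties: determinism, planted structure, noise-free limits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, pearsonr

from regnet import synthetic
from regnet.marina import compute_signature


def binom_bounds(n: int, p: float, level: float = 0.99) -> tuple[int, int]:
    lo, hi = binom.interval(level, n, p)
    return int(lo), int(hi)


class TestGenerateNetwork:
    def test_single_regulon_degenerate(self):
        net = synthetic.generate_network(1, 5, 0.0, 0, 0.0, seed=1)
        assert net.regulators == ["R001"]
        targets = net.regulon_map["R001"]
        assert len(targets) == 5
        assert "R001" not in targets
        assert all(eff.sign == 1 for eff in targets.values())

    def test_zero_overlap_forces_disjoint_regulons(self):
        net = synthetic.generate_network(10, 30, 0.0, 0, 0.0, seed=2)
        all_targets = [t for r in net.regulators for t in net.regulon_map[r]]
        assert len(all_targets) == 300
        assert len(set(all_targets)) == 300

    def test_overlap_and_sign_fractions_match_parameters(self):
        # empirical shared-target and negative-sign fractions over 50 seeds
        # must land inside binomial 99% bounds of the requested proportions
        shared = negative = total = 0
        for seed in range(50):
            net = synthetic.generate_network(10, 30, 0.2, 0, 0.3, seed=seed)
            counts: dict[str, int] = {}
            for reg in net.regulators:
                for t in net.regulon_map[reg]:
                    counts[t] = counts.get(t, 0) + 1
            for reg in net.regulators:
                for t, eff in net.regulon_map[reg].items():
                    total += 1
                    shared += counts[t] >= 2
                    negative += eff.sign == -1
        lo, hi = binom_bounds(total, 0.2)
        assert lo <= shared <= hi
        lo, hi = binom_bounds(total, 0.3)
        assert lo <= negative <= hi

    def test_infeasible_overlap_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            synthetic.generate_network(1, 5, 0.5, 0, 0.0, seed=0)

    def test_deterministic_for_fixed_seed(self):
        a = synthetic.generate_network(5, 10, 0.3, 20, 0.4, seed=9)
        b = synthetic.generate_network(5, 10, 0.3, 20, 0.4, seed=9)
        assert a.regulon_map == b.regulon_map
        assert a.background_genes == b.background_genes


class TestSimulateExpression:
    def test_noise_free_targets_track_activity(self):
        net = synthetic.generate_network(1, 8, 0.0, 0, 0.0, seed=3)
        design = synthetic.StudyDesign(("A",), ("x", "y"), 10)
        expr, truth = synthetic.simulate_expression(net, design, noise_sd=1e-9, seed=3)
        act = truth.latent_activity.loc["R001"].to_numpy()
        for t in net.regulon_map["R001"]:
            r = pearsonr(expr.values.loc[t].to_numpy(), act)[0]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_planted_shift_moves_group_mean_activity(self):
        net = synthetic.generate_network(2, 8, 0.0, 0, 0.0, seed=4)
        design = synthetic.StudyDesign(
            ("A",), ("g1", "g2"), 12, {"R001": {("A", "g2"): 2.0}}
        )
        diffs = []
        for seed in range(20):
            _, truth = synthetic.simulate_expression(net, design, seed=seed)
            act = truth.latent_activity.loc["R001"]
            ann = truth.sample_annotations
            diffs.append(
                act[ann["group"] == "g2"].mean() - act[ann["group"] == "g1"].mean()
            )
        assert np.mean(diffs) == pytest.approx(2.0, abs=3 * 1.0 / np.sqrt(20 * 6))

    def test_null_design_gives_uniform_t_test_pvalues(self):
        # no shifts anywhere: per-gene two-group Welch tests must be null
        from scipy.stats import t as t_dist

        net = synthetic.generate_network(3, 10, 0.0, 40, 0.0, seed=5)
        below = total = 0
        for seed in range(20):
            design = synthetic.StudyDesign(("A",), ("g1", "g2"), 10)
            expr, _ = synthetic.simulate_expression(net, design, seed=100 + seed)
            sig = compute_signature(expr, "g1", "g2")
            p = 2 * t_dist.sf(np.abs(sig.scores.to_numpy()), df=18)
            below += (p < 0.05).sum()
            total += len(p)
        lo, hi = binom_bounds(total, 0.05)
        assert lo <= below <= hi

    def test_decoupling_separates_expression_from_activity(self):
        net = synthetic.generate_network(1, 8, 0.0, 0, 0.0, seed=6)
        design = synthetic.StudyDesign(("A",), ("x", "y"), 50)
        expr, truth = synthetic.simulate_expression(
            net, design, decoupling=1.0, seed=6
        )
        act = truth.latent_activity.loc["R001"].to_numpy()
        own = expr.values.loc["R001"].to_numpy()
        assert 0.2 < pearsonr(own, act)[0] < 0.95

    def test_bit_identical_under_same_seed(self):
        net = synthetic.generate_network(3, 10, 0.0, 20, 0.2, seed=7)
        design = synthetic.desk_design(shifted_regulator="R001")
        e1, t1 = synthetic.simulate_expression(net, design, seed=11)
        e2, t2 = synthetic.simulate_expression(net, design, seed=11)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        pd.testing.assert_frame_equal(t1.latent_activity, t2.latent_activity)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            synthetic.StudyDesign((), ("a",), 4)


class TestSimulateProbes:
    def test_noise_free_probes_collapse_to_gene_values(self):
        net = synthetic.generate_network(1, 5, 0.0, 5, 0.0, seed=8)
        design = synthetic.StudyDesign(("A",), ("x", "y"), 5)
        expr, _ = synthetic.simulate_expression(net, design, seed=8)
        probes, truth = synthetic.simulate_probes(
            expr, probes_per_gene=3, bad_probe_fraction=0.0, probe_noise_sd=1e-12, seed=8
        )
        collapsed = probes.values.groupby(probes.probe_to_gene).mean()
        pd.testing.assert_frame_equal(
            collapsed.sort_index(), expr.values.sort_index(), check_names=False
        )

    def test_bad_probe_count_matches_expectation(self):
        net = synthetic.generate_network(2, 20, 0.0, 60, 0.0, seed=9)
        design = synthetic.StudyDesign(("A",), ("x", "y"), 5)
        expr, _ = synthetic.simulate_expression(net, design, seed=9)
        _, truth = synthetic.simulate_probes(expr, 4, 0.25, 0.1, seed=9)
        lo, hi = binom_bounds(len(truth), 0.25)
        assert lo <= truth["is_bad"].sum() <= hi

    def test_bad_probes_uncorrelated_with_good_ones(self):
        net = synthetic.generate_network(1, 20, 0.0, 0, 0.0, seed=10)
        design = synthetic.StudyDesign(("A",), ("x", "y"), 25)
        expr, _ = synthetic.simulate_expression(net, design, seed=10)
        probes, truth = synthetic.simulate_probes(expr, 4, 0.25, 0.1, seed=10)
        cors = []
        for gene, grp in truth.groupby("gene"):
            bad = grp[grp.is_bad].probe_id
            good = grp[~grp.is_bad].probe_id
            for b in bad:
                for g in good:
                    cors.append(
                        pearsonr(
                            probes.values.loc[b].to_numpy(),
                            probes.values.loc[g].to_numpy(),
                        )[0]
                    )
        assert cors, "fixture produced no bad/good probe pairs"
        assert abs(np.mean(cors)) < 0.1


class TestGeneratePromoters:
    def test_boundary_fractions_plant_everywhere_or_nowhere(self):
        pssm = synthetic.gr_like_pfm()
        targets, controls, labels = synthetic.generate_promoters(
            20, 20, pssm, length=200,
            planted_fraction_target=1.0, planted_fraction_control=0.0, seed=0,
        )
        by_class = labels.groupby("promoter_class")["planted"].sum()
        assert by_class["target"] == 20
        assert by_class["control"] == 0

    def test_gc_content_within_binomial_bounds(self):
        pssm = synthetic.gr_like_pfm()
        _, controls, _ = synthetic.generate_promoters(
            0 + 1, 999, pssm, length=1000,
            planted_fraction_target=0.0, planted_fraction_control=0.0,
            gc_content=0.5, seed=1,
        )
        seqs = "".join(controls.sequences.values())
        gc = seqs.count("G") + seqs.count("C")
        lo, hi = binom_bounds(len(seqs), 0.5)
        assert lo <= gc <= hi

    def test_planted_count_matches_fraction(self):
        pssm = synthetic.gr_like_pfm()
        # 137 inferred-target promoters at a 30% planting rate: expect ~41
        planted = 0
        for seed in range(5):
            _, _, labels = synthetic.generate_promoters(
                137, 1, pssm, planted_fraction_target=0.3,
                planted_fraction_control=0.0, seed=seed,
            )
            planted += labels[labels.promoter_class == "target"]["planted"].sum()
        lo, hi = binom_bounds(5 * 137, 0.3)
        assert lo <= planted <= hi

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_promoters(
                5, 5, synthetic.gr_like_pfm(), planted_fraction_target=1.5
            )

    def test_null_expression_is_unstructured(self):
        net = synthetic.generate_network(2, 30, 0.0, 10, 0.0, seed=11)
        design = synthetic.StudyDesign(("A",), ("x", "y"), 20)
        expr = synthetic.simulate_null_expression(net, design, seed=11)
        targets = list(net.regulon_map["R001"])
        act_proxy = expr.values.loc["R001"].to_numpy()
        rs = [
            pearsonr(expr.values.loc[t].to_numpy(), act_proxy)[0] for t in targets
        ]
        assert abs(np.mean(rs)) < 0.15
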