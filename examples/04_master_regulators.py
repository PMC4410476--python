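"""Identify master regulators of the dependent-vs-non-dependent contrast.

The signature ranks genes by |Welch t|; each regulon (trimmed to its top
100 interactions, eligible if >25 targets) is scored by GSEA enrichment,
normalised against 10,000 gene-label permutations, and called at
P < 0.01 on the standard-normal NES scale (NES 2.33 <-> P 0.01).
"""

from regnet import call_candidates, compute_signature, marina, mr_overlap_test
from regnet import synthetic
from regnet.containers import Edge, Interactome

net = synthetic.desk_network(seed=0)
expr, _ = synthetic.simulate_expression(net, synthetic.desk_design(), seed=0)
interactome = Interactome(
    {r: [Edge(t, 1.0) for t in ts] for r, ts in net.regulon_map.items()}
)

candidate_sets = {}
for region in ("regionA", "regionB"):
    ids = expr.annotations.index[expr.annotations["region"] == region]
    sig = compute_signature(expr.subset_samples(ids), "non_dependent", "dependent")
    results = marina(interactome, sig, n_permutations=10_000, seed=0)
    top = results[0]
    print(f"{region}: top regulator {top.regulator} "
          f"NES={top.nes:.2f} p={top.p:.2e} (regulon size {top.regulon_size_used})")
    candidate_sets[region] = {r.regulator for r in call_candidates(results, 0.01)}

k, p = mr_overlap_test(
    candidate_sets["regionA"], candidate_sets["regionB"], set(net.regulators)
)
print(f"cross-region MR overlap: {k} shared candidate(s), Fisher P = {p:.3g}")
print("The planted regulator R001 tops both regions — the analogue of a")
print("regulator recruited brain-wide. With a single candidate per region and")
print("only 10 regulators in the universe the overlap P bottoms out at 0.1;")
print("the test becomes informative for the larger MR sets of real studies.")
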