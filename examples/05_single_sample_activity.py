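"""Infer per-sample regulator activity and compare it with the latent truth.

Each sample's signature is its signed deviation from the dataset mean;
a regulator's activity in that sample is the normalised enrichment score
of its regulon in that signature. The point of the regulon readout: it
stays accurate even when the regulator's own transcript is a poor proxy
for its activity (here the expression-activity decoupling is turned up
to make that dissociation visible).
"""

import numpy as np

from regnet import synthetic
from regnet.activity import activity_matrix
from regnet.containers import Edge, Interactome

net = synthetic.desk_network(seed=0)
expr, truth = synthetic.simulate_expression(
    net, synthetic.desk_design(), decoupling=2.0, seed=0
)
interactome = Interactome(
    {r: [Edge(t, 1.0) for t in ts] for r, ts in net.regulon_map.items()}
)

act = activity_matrix(interactome, expr, n_permutations=1000, seed=0)
latent = truth.latent_activity.loc["R001"].to_numpy()

r_act = np.corrcoef(act.row("R001"), latent)[0, 1]
r_expr = np.corrcoef(expr.values.loc["R001"].to_numpy(), latent)[0, 1]
print(f"activity matrix: {act.values.shape[0]} regulators x {act.values.shape[1]} samples")
print(f"corr(inferred activity, latent truth) = {r_act:.2f}")
print(f"corr(own expression,    latent truth) = {r_expr:.2f}")

ann = expr.annotations
row = act.values.loc["R001"]
for group in ("naive", "non_dependent", "dependent"):
    print(f"mean R001 activity in {group:>13}: {row[ann['group'] == group].mean():+.2f}")
print("Activity rises only in the dependent group, matching the planted +2")
print("shift; the regulon readout tracks the truth far better than the")
print("regulator's own decoupled transcript does.")
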