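# regnet

Reverse engineering and interrogation of transcriptional regulatory
networks from expression profiles.

Many transcription factors are post-translationally regulated, so their
*activity* is not readable from their own transcript. `regnet` implements
the network-based alternative used in systems biology to find the drivers
of a phenotype — for example, the regulators recruited in specific brain
regions during the transition to drug dependence: infer each regulator's
target set (its *regulon*) from expression data alone, then read the
regulator's activity off the coherent behaviour of its targets.

The pipeline stages, all exercised end to end on synthetic data with
planted ground truth:

1. **Probe cleaning** — collapse probe-level matrices to gene level by
   correlation clustering, discarding uninformative probes.
2. **Network inference** — pairwise mutual information I(R; t) between
   regulators and candidate targets on the copula (rank) scale, a
   permutation-calibrated significance threshold (extrapolated with an
   exponential tail model down to P = 1e-8), Data Processing Inequality
   pruning of indirect edges (for a chain A–B–C, I(A;C) ≤ min(I(A;B),
   I(B;C))), and optional bootstrap consensus.
3. **Master regulators** — rank genes by |Welch t| for a group contrast;
   score each regulon (trimmed to its top 100 interactions, eligible if
   >25 targets) by GSEA running-sum enrichment; normalise against 10,000
   gene-label permutations: NES = (ES − μ₀)/σ₀, one-sided P = 1 − Φ(NES)
   (so NES ≈ 2.33 ↔ P = 0.01); call candidates at P < 0.01 and compare MR
   sets across regions with Fisher's exact test.
4. **Single-sample activity** — each sample's signature is its signed
   deviation from the dataset mean; a regulator's activity in a sample is
   its regulon's NES in that signature.
5. **Activity correlation** — Pearson correlation of activity rows,
   tested against random regulons of the same sizes.
6. **Motif enrichment** — PSSM scanning of ±500 bp promoters on both
   strands; Fisher test of motif occurrences in inferred-target vs
   control promoters.

## Worked example

Infer a network from 200 synthetic profiles driven by 10 planted
regulators (30 targets each, 200 background genes, unit effects, noise
sd 1) and compare with the planted truth:

```python
from regnet import NetworkParams, infer_interactome, synthetic

net = synthetic.desk_network(seed=0)
expr, _ = synthetic.simulate_expression(net, synthetic.flat_design(200), seed=0)
inter = infer_interactome(expr, net.regulators,
                          NetworkParams(bonferroni=True, n_bootstrap=0, seed=0))
```

Running `python examples/03_network_inference.py` (the script around the
snippet) prints:

```
candidate pairs    : 5045
applied MI cutoff  : 0.103 nats
edges inferred     : 300 (planted: 300)
precision / recall : 0.993 / 0.993   F1 = 0.993
```

The MI cutoff is the permutation-null quantile matching a Bonferroni-
corrected P of 0.05/5045 per pair; F1 ≈ 0.99 means the threshold cleanly
separates planted regulator–target dependence from background at this
sample size. Interrogating the planted-truth regulons for masters of the
dependent-vs-non-dependent contrast
(`python examples/04_master_regulators.py`) prints:

```
regionA: top regulator R001 NES=6.28 p=1.72e-10 (regulon size 30)
regionB: top regulator R001 NES=6.05 p=7.25e-10 (regulon size 30)
```

R001 is the one regulator whose latent activity was shifted +2 in the
dependent group: its regulon is maximally enriched in the contrast
signature in both regions, so it is called as the master regulator —
without its own expression ever entering the calculation. The other
examples cover probe cleaning, single-sample activity (the inferred
activity row tracks the planted latent activity at r ≈ 0.9 even when the
regulator's own transcript is decoupled from it), activity correlation,
motif enrichment, and the full pipeline (`regnet run config.txt` on the
shell; every artifact carries the config hash and seed, and reruns are
bit-identical).

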