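# Methods

`regnet` implements an expression-only workflow for reverse engineering a
transcriptional regulatory network and interrogating it for the drivers of
a phenotype: mutual-information (MI) network inference, master-regulator
(MR) identification by regulon enrichment, per-sample regulator activity,
regulator–regulator activity coupling, and promoter binding-site
enrichment. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Mutual-information estimation

Dependence between two expression profiles is measured as MI in nats.
Both vectors are first mapped to normalised mid-ranks (the empirical
copula), so the estimate depends on the data only through rank order.
Two consequences are load-bearing and tested: estimates are *bit-exactly*
invariant under strictly increasing transforms of either input, and
exactly symmetric in their arguments (leaf contributions are accumulated
with exact summation, so traversal order cannot perturb the total).

The default estimator is adaptive partitioning: the unit square is
recursively split into quadrants, descending only where the
quadrant-count uniformity statistic `sum (n_i - m/4)^2 / (m/4)` exceeds
3.84 (the 0.05 point of a chi-square with 1 df — the canonical cutoff for
this estimator family; configurable) and the cell holds at least 8
points. Each leaf cell contributes the plug-in term
`p log(p / (p_row p_col))` with empirical marginals. A fixed-bin
estimator (equal-width grid, ~n^(1/3) bins per axis) is provided as a
cross-check. Constant inputs return MI 0 with a flag rather than an
error.

On the deterministic balanced encoding of the perfectly dependent binary
joint (p(0,0) = p(1,1) = 1/2, n = 400, jittered), the estimator recovers
ln 2 within 0.1 nats; an unbalanced random encoding is systematically
biased low because the dyadic splits no longer align with the cluster
boundary, which is why the test fixes the balanced construction.

## Significance threshold for edges

Null MI values are generated from random permutations (a rank-based
estimator needs only a permutation paired with the identity). The right
tail of the null is fitted with the exponential survival model
`log P(MI > m) = a + b m` over the upper half of the null sample
(default 1,000 null pairs; raised from smaller values because the fitted
slope is the dominant source of threshold variance). Solving the fit at a
target P gives the MI cutoff; this extrapolates to P values (1e-8) that
direct permutation cannot reach.

Measured on this estimator the true null tail decays *faster* than
exponential, so extrapolated cutoffs are conservative: the realised
false-pass rate at a nominal P is below nominal. The calibration tests
therefore bound the false rate from above rather than matching it
two-sidedly. Two thresholding modes are exposed, mirroring the two
conventions in use for this analysis family: a fixed per-pair P (default
1e-8, appropriate at genome scale with millions of candidate pairs) and a
Bonferroni mode (P = 0.05 / number of candidate pairs). At desk scale
(~5,000 pairs, 200 samples, unit effect weights) the planted-edge MI
(~0.27 nats) sits below the extrapolated 1e-8 cutoff (~0.34), which was
designed for a universe a thousandfold larger; the recovery benchmarks
accordingly use the Bonferroni mode, where median edge-recovery F1 is
~0.99.

## DPI pruning and bootstrap consensus

For every triangle whose indirect path runs through a regulator, the
direct edge is removed when its MI is strictly below
`(1 - tolerance) * min` of the two legs (tolerance default 0). Removal
decisions are evaluated on the original weights and applied
simultaneously, so results are traversal-order independent; a
brute-force triple-enumeration oracle checks equivalence. Note the
per-triangle guarantee — a triangle never removes its own strongest
edge — does not forbid an edge being strongest in one triangle and
removed as the weakest of another.

With bootstrapping enabled, the full pass (MI, threshold, DPI) is
repeated on resamples of the samples; the MI cutoff is computed once on
the original sample size and reused, since the null depends on n only.
An edge enters the consensus when its support count beats a one-sided
binomial test against the mean chance rate (total edge occurrences /
candidate pairs / runs), Bonferroni-corrected over the edges observed at
least once; an edge present in every run is always kept, covering the
degenerate case where the chance model saturates. The consensus statistic
is a documented package choice — the upstream literature runs 100
bootstraps but does not state the consensus rule.

## Master-regulator analysis

A group contrast is summarised as per-gene Welch t-statistics (sign =
second group minus first), ranked by |t| descending with ties broken by
gene id. Each regulon is intersected with the measured gene universe,
trimmed to its top-100 MI interactions (de-biasing enrichment, which
otherwise favours large regulons; ties by bootstrap support then target
id), and analysed if at least 26 targets remain ("more than 25").
Intersection precedes trimming and eligibility so unmeasured targets
never count.

Enrichment is the weighted Kolmogorov–Smirnov running sum: members add
`|t|^w` (w default 1) normalised by the members' total weight,
non-members subtract `1/(N - n)`; the enrichment score (ES) is the signed
extreme, and the leading edge contains the members at or before the
positive extreme (at/after, for a negative ES). A batch evaluator scores
the running-sum extreme only at member positions; it agrees with the
O(N) reference to 1e-12 and carries the permutation nulls.

The null shuffles the signature's gene labels, equivalent to placing the
regulon at uniformly random rank positions; nulls are shared per regulon
size. NES = (ES − null mean) / null sd; the reported P is the one-sided
standard-normal tail of the NES (so P = 0.01 corresponds to NES ≈ 2.33),
with the empirical permutation tail reported alongside — the two
conventions coexist in this analysis family and they agree here to
Monte-Carlo accuracy under exchangeable nulls. Candidates are called at
P < 0.01 (strict). MR sets from different strata are compared with a
one-sided hypergeometric (Fisher) overlap test; the identical tail
routine backs the promoter enrichment test below.

**Calibration caveat.** Gene-label shuffling assumes exchangeable genes.
On synthetic data whose regulons co-vary through their regulator's
baseline activity but carry *no* group effect, the label-shuffling null
is anticonservative (measured ~13% of regulators at nominal 1%, for both
the normal-map and empirical P) — the well-known inter-gene-correlation
property of gene-permutation enrichment nulls. The type-I calibration
benchmark therefore uses fully exchangeable null data (i.i.d. genes;
measured 0.2–0.8% at nominal 1%), and P values on strongly co-expressed
null regulons should be read as enrichment scores, not calibrated error
rates. Sample-permutation nulls would restore calibration at the cost of
sensitivity to sample covariance; they are not implemented because the
label-shuffling convention is the one this pipeline family prescribes.

## Single-sample activity

Each sample's signature is its deviation from the dataset mean profile
(no variance scaling by default — one sample has no within-sample
variance; a z-scale option divides by the gene's across-sample sd).
Unlike the contrast analysis, per-sample signatures are ranked by
*signed* score: the sign of the deviation is the direction of the
regulator's activity, and a directional activity (positive NES =
targets coherently above the dataset mean) is what makes cross-sample
activity profiles, group contrasts of activity, and activity
correlations meaningful. An |score| ranking would conflate activation
with repression and destroy the sign of group contrasts, so the signed
ranking is the package's design choice for this stage. Null
member-position sets are drawn once per regulon size and shared across
samples (each sample still gets its own null ES distribution because its
weights differ); per-sample NES values are assembled into the
regulators × samples activity matrix.

On the desk benchmark the inferred activity row of the planted regulator
correlates with its latent activity at r ≈ 0.9, and remains ≈ 0.9 when
the regulator's own transcript is strongly decoupled from its activity
(r ≈ 0.6) — the dissociation the regulon readout exists to handle.

## Activity correlation

Coupling between two regulators is the Pearson correlation of their
activity rows. Significance comes from a random-regulon null: gene sets
matching the two (trimmed) regulon sizes, drawn uniformly without
replacement from the measured universe excluding the two regulators'
own genes, mutually disjoint within a draw; their activity rows are
computed with the same machinery and correlated. The P value is the
two-sided, add-one-smoothed exceedance (1 + #{|r_null| ≥ |r_obs|}) /
(n_random + 1), which can never return 0; membership (not MI weight)
structure is what the null randomises. Inner enrichment nulls are shared
across draws per (sample, size), which is exact because the null ES
distribution depends only on the signature and the set size.

## Promoter binding-site enrichment

A position frequency matrix (JASPAR flat text, read via Biopython) with
a 0.5 pseudocount per base becomes a log-likelihood-ratio matrix against
a background composition estimated from the pooled control promoters.
Every window of every promoter (by convention 1,000 bp, ±500 bp around
the TSS) is scored on both strands — the reverse strand via the
base-complemented, position-reversed matrix — and windows containing N
are skipped; ties resolve to the smaller position, then the forward
strand. A promoter has an occurrence when its maximum score reaches the
control-set 95th percentile (the published cutoff for this scoring
scheme is not restated in the sources this package follows, so a
quantile rule is the declared substitute; a fixed-score cutoff is
available), and the target-vs-control occurrence table is tested with
the shared one-sided Fisher routine. At the study-scale set sizes (137
targets, 1,000 controls) with 30% vs 2% planted instances, the test
detects enrichment at P < 0.01 in 10/10 seeded runs.

## Probe cleaning

Per gene, probes are linked when their Pearson correlation (Spearman
optional) reaches the threshold (default 0.5); single-linkage components
of that graph whose mean within-cluster correlation also reaches the
threshold are candidate clusters; the largest is kept (ties: higher mean
correlation, then smallest probe id) and averaged into the gene value;
genes keeping fewer than 2 probes are dropped, and every probe's fate is
reported. This is a deliberate simplification of published probe
cleaners: no re-mapping against a transcript database, and one cluster
per gene (no alternative-transcript probesets). Constant probes
correlate with nothing and are dropped.

## Synthetic data: what it shows and what it does not

The generator plants a network (regulators with signed, weighted target
sets plus background genes), a study design (regions × ordered groups ×
replicates), and latent per-sample regulator activities (baseline sd 1
plus per-cell shifts); targets are linear-Gaussian functions of activity
plus noise (sd 1 by default), the regulator's own transcript is activity
plus noise attenuated by a decoupling factor (default 0.5), and an
optional monotone cube transform on targets exercises the estimator's
rank invariance. Desk preset: 10 regulators × 30 targets + 200
background genes, 2 regions × 3 groups × 8 replicates, one regulator
shifted +2 in the most-exposed group; effect weights are 1, all effects
activating. Probe and promoter fixtures plant, respectively, junk probes
(pure noise, default fraction 0.25) and motif instances sampled from a
synthetic 14-bp nuclear-receptor-style PFM (invented counts shaped like
a hormone-response element — deliberately not a database matrix).

These defaults were chosen once for testability at desk scale (runs of
seconds to minutes): no published effect-size scale exists for the real
tissue data this design emulates. Passing benchmarks show the machinery
is correct and calibrated under the generative model; they do not show
that real brain expression data meet that model. In particular the
generator has no region-specific covariance, no batch structure,
linear-Gaussian target links only, and exchangeability violations appear
only through planted regulons.

## Pipeline

The orchestrated run mirrors the study design: pooled network over all
samples (per-region networks optional), per-region contrast signatures
and MR calls, cross-region MR overlap, activity inference, optional
activity correlation and motif enrichment. One global seed fans out to
fixed per-stage offsets; every artifact header carries the config hash
and seed; stage wall times go to the logger (not the artifacts) so a
rerun with the same config is bit-identical — verified file-for-file in
the tests. Stage failures abort with the stage named, retaining partial
artifacts.

## Known limitations

- The exponential tail model makes edge thresholds conservative for this
  estimator; treat the nominal edge P as an upper bound on the false-edge
  rate.
- Gene-label permutation P values are anticonservative under strong
  inter-gene correlation (above).
- Mode of regulation (activator vs repressor two-tail analysis) is not
  modelled in the contrast analysis; |t| ranking absorbs direction.
- The probe cleaner emits one cluster per gene and cannot recover
  alternative-transcript probesets.
- Bootstrap consensus P values inherit the arbitrariness of the chance
  model when run counts are small; support counts are reported so users
  can apply their own rule.
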