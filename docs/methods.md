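# Methods

This note documents the statistical models implemented in sigrev, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
recorded. No empirical claim is made here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression

**TPM.** TPM_gj = 10^6 · (K_gj / len_g) / Σ_i (K_ij / len_i) with gene
lengths in kb; the pipeline works on log2(TPM + 1). Base 2 is used throughout
so effects read as log2 fold changes. Columns of TPM sum to 10^6 by
construction, which makes the transform invariant to per-sample depth.

**Moderated linear model.** Per gene, OLS of log expression on condition plus
source-database dummies (the batch covariate absorbs compendium-specific
offsets). Residual variances are shrunk by the empirical-Bayes squeeze:
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) fit by the method of
moments on log variances (a scaled-F model: d₀ solves
trigamma(d₀/2) = var(log s²) − trigamma(d_g/2); non-positive residual
variance of log s² means complete shrinkage, d₀ = ∞). Moderated t uses
d₀ + d_g degrees of freedom. Multiple testing: **Bonferroni** for this route.
Rank-deficient designs (e.g. database confounded with condition) raise an
error naming the confounded columns.

**Negative-binomial GLM.** Size factors are median-of-ratios against the
geometric-mean pseudo-reference, excluding genes with any zero count. Each
gene gets an NB GLM (log link, log-size-factor offsets, condition + database
design) fit by IRLS, batched across genes with a shared design; convergence
tolerance 1e-8 on coefficients, 100 iterations, non-converged genes flagged
with p = NA. Dispersions are method-of-moments within design cells,
clamped to [1e-8, 10], then shrunk **halfway in log space** toward a fitted
a₀ + a₁/mean trend (two trimmed least-squares rounds). The halfway weight is
a pinned constant: it keeps the estimator simple and reproducible, and the
planted-truth recovery and calibration results in the acceptance suite are
the evidence it suffices at the simulated sample sizes. Wald p-values from
the unpenalized fit are BH-adjusted. The *reported* log2 fold change is the
posterior mode under a zero-centered normal prior on the condition
coefficient (a ridge refit), with the prior scale fit by marginal maximum
likelihood over genes — a deliberately lighter-tailed stand-in for heavier
shrinkage estimators, used only for ranking genes into signatures.

**Signature selection.** Genes with adjusted p < 0.05 are ranked by |log2FC|
descending (ties by gene id); the ranking is walked, skipping genes absent
from the perturbation-assay universe, until 100 genes (band 90–120) are
collected; positive fold change goes to the up set, negative to down. A
single ranking is used rather than forced up/down balance, so asymmetric
signatures arise naturally. If fewer eligible genes exist than the lower
band edge, all are returned with a warning flag rather than an error.

## Transfer-learning route

**Projection.** Latent loadings Z (genes × LVs, sparse, non-negative) are an
*input*; fitting the factorization itself is out of scope. Expression rows
are z-scored across samples before projection — the loadings were learned on
standardized data, and transfer on raw TPM scale would be meaningless — and
activity is B = (ZᵀZ + λI)⁻¹ ZᵀY_std with λ = 1e-6. The ridge is numerical
regularization only (plain matrix-multiplication transfer is the λ→0
limit); orthonormal loadings recover ZᵀY_std exactly.

**LV testing and the 3-SD rule.** Per-LV activity is tested with the same
moderated linear model (condition + database), Bonferroni-adjusted. On top
of p < 0.05, an absolute-effect cutoff keeps only the most different LVs:
upper = mean + 3·SD and lower = mean − 3·SD of the per-LV effects, cutoff =
(|upper| + |lower|)/2 rounded to two decimals (bounds of 0.27 and −0.23 give
0.25). The rule presumes many LVs; with very few LVs the strong effects
inflate the SD past themselves and nothing passes — configurations here use
≥25 LVs. A fixed cutoff can be passed instead (the label-switch experiment
pins 0.05).

**Signature assembly.** Significant LVs, ordered by |effect| descending,
contribute genes round-robin: each LV in turn yields its next-highest-weight
gene that is in the universe, has a nonzero fold change in the NB-GLM result
(which supplies the up/down sign; taking signs from the count-based route
keeps both routes on one fold-change scale), and is not yet selected, until 100 genes.
Round-robin is one of several defensible allocation rules; it guarantees
every significant LV representation, and the output is invariant to LV input
order given the |effect| ordering.

**Label-switch validation.** To show that gene labels carry the transferred
information: for switch fractions 10%…100%, a random subset of gene labels
is shuffled among itself (uniform permutation, not forced derangement), the
study re-projected and re-tested (adj p < 0.05, |effect| ≥ 0.05), 50
repetitions per fraction by default; the curve of mean significant-LV count
is summarized by an OLS slope/R²/p against fraction, with the unpermuted
count included as the fraction-0 baseline. On planted data the slope is
negative. Note the experiment is only informative when shuffling actually
*dilutes* signal: if differential genes are a large share of each LV support,
relabeled signal re-enters other LVs and the curve flattens — the acceptance
script therefore runs it at sparsity 0.02 on a 1200-gene universe.

## Signature reversion

**Enrichment score.** Genes ranked by z descending, ties broken by gene id
(level-5-style z-score ties are rare but determinism is required). Hit
increments are weighted by |z| with exponent 1 (the standard weighted-KS
choice, pinned). ES is the running-sum extremum of largest magnitude; the
extremum can only occur immediately after or immediately before a hit, so
the implementation scores a size-k set in O(k log k) after pre-ranking, and
a brute-force full-length running sum serves as the test oracle. Exact
|max| = |min| ties (which occur when the miss step divides the hit mass
evenly) resolve toward the positive extremum, with 1e-12 float tolerance;
the oracle applies the same rule. A set with all-zero weights falls back to
equal weighting.

**WTCS / NCS / Tau.** WTCS = (ES_up − ES_down)/2 when signs differ, else 0.
NCS divides positive scores by the mean of positive scores in the same
cell-line group and negative scores by |mean of negative scores| (same-sign
pooling, the CMap convention; a lone score of its sign is its own mean and
is flagged). Tau(d) = sign(NCS_q(d)) · (100/N) · #{r : |NCS_null(d,r)| <
|NCS_q(d)|} against a bank of N matched-size random query signatures scored
across all drugs and NCS-normalized per query (default N = 1000; curated
touchstone signature collections are platform-internal, so random
matched-size queries define the percentile here).

**Permutation p and filter.** The null draws random up/down gene sets of the
query's in-reference sizes; p(d) = (1 + #{null WTCS ≤ WTCS(d)})/(n_perm + 1),
one-sided in the reversal tail because only inversion is ever a candidate;
BH across drugs. The p/FDR null and the Tau bank are two independent seeded
draws. Because WTCS has an atom at zero (the same-sign rule), this p-value
is exactly calibrated in its lower tail but cannot be uniform over [0, 1];
the calibration suite tests the tail property. The candidate filter keeps
NCS < 0 AND FDR < 0.05 AND Tau < −80, all strict, FDA-approved drugs only
when annotations are given, ordered by NCS ascending.

## Validation benchmarks

**Sensitivity.** A cell line is sensitive to a drug when the median-collapsed
log2 viability fold change is < 0.3 (strict); missing entries are excluded.
A drug counts as sensitive *for a disease* when a strict majority of its
evaluated disease lines are sensitive — several drug-level aggregations are
defensible; majority rule is pinned here but configurable.

**Permutation enrichment.** Observed = fraction of candidates with the
annotation (trial membership for the disease; screen sensitivity); null =
fractions of n_perm same-size draws without replacement from the
FDA-approved universe (1000 draws for trials, 10,000 for the screen);
p_empirical = (1 + #{null ≥ observed})/(n_perm + 1). A one-tailed rank-sum
p comparing candidate indicators against the pooled null indicators is also
reported; a 1-vs-N rank-sum comparison admits more than one pairing of samples,
so the empirical permutation p is the primary statistic. The observed
fraction is discrete in |candidates|, so p-value uniformity under the null
is only approached for candidate sets of a few dozen drugs — the calibration
suite sizes accordingly.

**Targets and gene effects.** Per-target hypergeometric upper-tail
enrichment of the target's drug set among candidates versus the approved
universe, BH-adjusted. Gene-effect summaries are missing-aware means of
CRISPR essentiality scores over requested cell lines (negative = fitness
cost; ≈ −1 for core-essential genes).

## Networks and ontology

Drug–drug similarity is the cosine of perturbation profiles or the Tanimoto
coefficient |a∧b|/|a∨b| of fingerprint bit vectors; all-zero rows are
flagged and excluded from edges. The network keeps the ⌈10%⌉ largest
off-diagonal pairs **globally** (ties at the cut all retained; per-node
retention would be the alternative reading), and Leiden communities are
seeded and deterministic (modularity partition, iterated to convergence;
exhaustive-oracle-equivalent on graphs ≤ 8 nodes). PPI edges are kept when
combined score / 1000 > 0.7 (strict); centrality = degree, unnormalized
Brandes betweenness, and eigenvector centrality by power iteration (on A + I
so bipartite components converge; tolerance 1e-9; unit-normalized per
connected component). Route-unique gene sets are compared by Kruskal–Wallis,
followed (only on rejection at 0.05) by pairwise two-tailed rank-sum tests;
BH adjustment is primary and Bonferroni is also reported for
comparability with stricter conventions.

Term enrichment is upper-tail hypergeometric with BH (tool-internal multi-query
corrections have no published closed form, so standard BH is used). Wang semantic similarity propagates S-values upward
from each term (S = 1 at the term, multiplied by 0.8 per is_a edge and 0.6
per part_of edge, max over paths) and scores the shared-ancestor S-mass over
the total; terms under disjoint roots score 0. Term grouping is Ward
clustering on 1 − similarity cut at distance 1 − 0.7, with the
largest-annotation term (ties lexicographic) as group representative.

## Synthetic data: what it emulates, and what it does not

Counts are NB(mean = baseline · 2^(condition·β_g + database offset),
dispersion 0.1) with lognormal baselines (median ≈ 100), gene lengths
log-uniform in [0.5, 10] kb, two databases with per-gene N(0, 0.25²) log2
offsets assigned round-robin within condition (never confounded). Exactly
⌈frac_de·n_genes⌉ genes carry β = ±lfc_scale with exactly balanced signs.
Defaults — 2000 genes, 40+40 samples, 5% DE at |log2FC| = 2 — describe a
mid-sized tumor/control cohort with strong, detectable effects.

Loadings have exactly ⌈sparsity·genes⌉ non-negative weights per column.
Active LVs draw their support from planted DE genes of a single sign
(alternating across active LVs), same-sign actives taking disjoint slices of
the pool — shared support would make the columns collinear and split the
planted effect; mixed signs would cancel it. Two active LVs (one up, one
down) are the default.

Reverser drugs superimpose z = −strength·sign(β) (strength 4) on the planted
DE genes over N(0, 1) noise; non-reversers are pure noise. Acting only on
planted DE genes keeps the "inverse signature" ground truth unambiguous.
Annotations are Bernoulli with base rates 0.25 (trial) and 0.2 (screen
sensitivity), reverser odds multiplied by 16; eight reversers among 60 drugs
by default, sized so that annotation enrichment is detectable at the small
candidate-set sizes the filter produces. Reverser fingerprints share a set
32-bit block; all simulated drugs are flagged FDA-approved, matching a
reference already restricted to approved compounds.

One RNG stream per artifact is split from the master seed (plant, counts,
loadings, perturbation, annotations), so changing the drug panel never
perturbs the counts, and every generator is bitwise-reproducible per seed.

**Not emulated:** replicate-level aggregation of perturbation profiles,
plate structure, dose–response (one dose/time point, one cell line);
library-size heterogeneity beyond size-factor scale; correlated gene
modules outside the planted loadings; heavy-tailed or outlier dispersion;
real ontology topology. Passing tests therefore demonstrate correctness of
the statistical machinery and recoverability under the declared generative
model — not performance on real tumor compendia.

## Problem sizes in the standard runs

The acceptance script uses 20 seeded replicates of the default configuration
for planted-truth recovery and 30 global-null replicates (600 genes, 12+12
samples, 200 drugs) for calibration; the label-switch experiment runs 5
fractions × 10 repetitions on a 1200-gene study. These sizes give binomial
error a few percent wide on the reported rates while keeping a full run
around a minute on one CPU.

## Known limitations

- The NB dispersion estimator (cell-wise moments, halfway log shrink) is
  coarser than profile-likelihood estimators; at very small sample sizes its
  Wald tests will be anti-conservative sooner than DESeq2's.
- The ridge-normal shrunken fold change under-shrinks large-variance genes
  relative to heavy-tailed priors; it is used only for ranking.
- Tau is computed against random matched-size query banks, not against a
  curated compendium of real signatures; its absolute scale therefore
  differs from platform Tau even though its semantics match.
- The reversion permutation p is valid but conservative above its lower
  tail (WTCS atom at zero).
- The 3-SD LV cutoff degenerates when only a handful of LVs exist.
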