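# Methods

## Design and model

The study design is a set of P phylogenetically independent species
pairs (P = 3 by default), each pairing a desert specialist with a mesic
relative, with ~5 biological replicates per species. Within a pair,
species and habitat are confounded by construction — the design cannot
separate "this species differs" from "desert differs" inside one pair —
which is exactly why convergence is assessed *across* pairs: a habitat
effect that replicates in every independent pair is evidence of a
shared (convergent) shift, while pair × habitat interaction captures
lineage-specific shifts.

Counts are modeled per gene as negative binomial with a log link,
`Var = mu + alpha mu^2`, and offsets `log s_j` (median-of-ratios size
factor; times a known per-(gene, sample) length offset when transcript
lengths differ across species). The full design is saturated over the
2P species cells: intercept + habitat (desert = 1) + (P − 1) pair
indicators + (P − 1) habitat × pair interactions.

Fitting is iteratively reweighted least squares with fixed per-gene
dispersion, vectorized across genes that share a design matrix (the
weighted normal equations for all genes are assembled with `einsum` and
solved as a batch of p × p systems). Convergence: relative deviance
change below 1e-8, at most 100 iterations; linear predictors are
clipped at ±30 to keep all-zero cells finite. Non-converged genes are
flagged, logged, and excluded from FDR and classification.

## Dispersion

Two estimators are provided:

* `estimate_dispersion` — pooled method-of-moments over design cells:
  on normalized counts, each cell contributes excess variance
  `v - m * mean(1/s)` against `m^2`, pooled with weights (n_g − 1) and
  floored at 1e-8. Simple, deterministic, and accurate at large n
  (planted alpha = 0.2 is recovered within [0.1, 0.3] at n = 1000).
* `estimate_dispersion_cr` (pipeline default) — per-gene profile
  likelihood over a 30-point log-spaced grid in [1e-4, 2], scored with
  the Cox–Reid adjustment `-0.5 logdet(X'WX)` under the saturated
  design, refined by one quadratic interpolation step in log-alpha.

The default changed from moments to CR profile likelihood because the
moment estimator's sampling noise at ~23 residual degrees of freedom
measurably inflates the downstream likelihood-ratio tests: in global
null simulations the habitat LRT rejected 7–8% of genes at nominal 5%
with moment plug-ins, versus ~5.1% when the true dispersions are
supplied, and ~6.3–6.9% with CR estimates. Neither estimator shrinks
across genes (moderation is deliberately out of scope), so a small
liberal excess is irreducible: plugging any finite-df dispersion
estimate into a chi-square LRT is slightly anticonservative. The test
suite therefore asserts exact 3-binomial-SE calibration with known
dispersions, a transparent 8% ceiling with estimated ones, and
distributional uniformity of the null habitat p-values by
Kolmogorov–Smirnov at 2,000 genes (which CR estimates pass). Dispersion
is shared between the full and reduced fits of a gene so nested
log-likelihood ordering holds by construction.

## Tests and classification

Habitat: LRT of (pair + habitat) vs. (pair), df = 1. Interaction: joint
LRT of the saturated model vs. (pair + habitat), df = P − 1 — one
decision per gene rather than per-term tests, matching the binary
classification rule. Both p-vectors are BH-adjusted separately over the
analyzed (converged) genes. The choice of nested LRTs (rather than
contrasts inside the full model) makes "main effect" and "interaction"
unambiguous under any factor coding; pairwise desert-vs-mesic tests
within one pair use the Wald statistic on the single habitat
coefficient, the common choice for single-coefficient contrasts.

A gene is shared when `habitat_q < 0.01` and `interaction_q > 0.05`
(both thresholds configurable; these are the analysis defaults), and is
`shared_up` / `shared_down` when all P per-pair log2 fold changes from
the saturated fit agree in sign, else `shared_discordant` — discordant
genes are possible because the interaction test has finite power, so
the up/down counts need not exhaust the shared total.

The magnitude filter keeps shared genes whose **mean** |log2FC| across
pairs exceeds the threshold (default 0.5); requiring **every** pair to
exceed it is available as `mode="min"`, since the plain-language
description of this filter admits both readings.

Fold-change sign caveat: with equal size factors the two-group NB MLE
is the arithmetic group mean, so the log2FC sign equals the sign of the
raw mean difference exactly; with heterogeneous factors the MLE weights
samples differently and genes with near-zero differences can disagree
with the naive normalized-mean sign (observed concordance > 98%).

Expression filters operate on raw counts: the shared model analyzes
genes with mean count strictly greater than 20 per sample within every
species; pairwise tests keep genes with mean ≥ 10 across the pair's
samples. Size factors are median-of-ratios with reference genes =
genes nonzero in every sample; scaling one sample's counts by c scales
its factor *relative to any other sample's* by exactly c (the absolute
factor scales by c^(1−1/n) because the geometric-mean reference absorbs
c^(1/n)).

## Permutation null

Null hypothesis: habitat labels carry no information beyond species
structure. For each gene and each pair independently, the pair's two
habitat labels are exchanged with probability 1/2, replicates moving as
blocks — 2^P equally likely configurations per gene. Each permuted
dataset is refit, BH-readjusted over the same gene universe, and
reclassified; the shared count is recorded, and the observed count gets
the add-one empirical p-value `(1 + #{null >= obs}) / (n_perm + 1)`
(never exactly zero, by construction).

Implementation: the pair-only and saturated models' log-likelihoods are
invariant under within-pair label swaps (a swap only renames which
species cell is "desert"), so only the (pair + habitat) model varies —
and it takes one of 2^P values per gene. All 2^P fits are computed once
and each permuted dataset's LRT statistics are assembled by lookup;
this is algebraically identical to refitting every permutation (a test
forces configurations through the public fitting path and checks
equality) and makes 10,000 permutations on thousands of genes a matter
of seconds. Per-gene dispersions are estimated once on observed data
and reused: the estimator depends only on species cells, which the swap
never splits. The expression filter is likewise computed once on
observed data. A dataset-level swap mode (one configuration for all
genes per permutation) is available for sensitivity analysis.

Note that with strong genuinely shared effects the null distribution is
not centered at zero: the all-pairs-swapped configuration (probability
1/(2^P) per gene) preserves concordance with flipped sign, so permuted
datasets recover a fraction of the planted genes. The observed count
still exceeds every null count by a wide margin in such scenarios.

## Overlap tests

Hypergeometric upper tail `P(X >= k)` for the intersection of two gene
sets within an explicitly supplied universe (both sets are intersected
with it first); expectation `|A||B|/|U|`; a depletion (lower-tail)
alternative is available. The universe must be the intersection of the
analyzed-gene sets of the two experiments being compared — it is a
required argument precisely because overlap p-values are meaningless
without it, and published analyses often leave it implicit.
`set_fraction` rounds half-up (so 702/8174 prints as 8.6%, matching
set-accounting conventions rather than banker's rounding).

## Ordination

PCA treats samples as observations on the variance-stabilized matrix
`log2(count/s + 1)` (a closed-form, monotone stand-in for parametric
variance-stabilizing transforms; adequate for ordination), column-
centered, full SVD, all filtered genes (no top-variance preselection —
configurable). Clustering is average linkage on 1 − Pearson
correlation between sample profiles, exported as an ultrametric Newick
tree. In this design, pair/phylogeny structure dominates the leading
components and habitat appears in a later component; the simulation
tests assert exactly that geometry.

## Synthetic data

The generator runs the analysis model forward:
`y ~ NB(s_j exp(eta), alpha_i)` with per-gene baselines
(log-normal, natural-log mean 5.0, sd 1.5 — median ~150 counts),
per-(gene, pair) offsets (sd 0.5, the expression divergence between
families), planted effects, lognormal dispersions (median 0.08, log-sd
0.8, typical of bulk RNA-seq with wild-caught outbred animals), and
log-uniform size factors in [0.5, 2]. The layout mirrors the emulated
study: 3 pairs × 2 habitats × 5 replicates with one species at 4.
Defaults for effect structure: 8% shared genes (48% up), modest
magnitudes (lognormal, median 0.4 log2 units — most convergent shifts
in such data are small), 15% lineage-specific genes with independent
per-pair N(0, 1.2) effects. Per-(gene, species) offsets independent of
habitat exist as an option but default to 0: within a pair such offsets
are statistically indistinguishable from habitat effects, so a nonzero
default would make the truth classes ill-defined.

What the generator does *not* emulate: correlated expression among
co-regulated genes (the permutation null likewise treats genes as
independent), cross-species mapping/annotation artifacts, length
differences (length offsets are supported in the model but not planted
by default), batch structure, and outlier samples. Passing tests
therefore demonstrate correctness of the inference machinery under the
assumed model, not robustness to those real-data complications.

### Recovery experiments

The planted-recovery evaluation plants effects at |log2FC| ≥ 1
(lognormal magnitudes floored at 1) and alpha ≤ 0.1 (capped), n = 5,
3 pairs, 800 genes × 20 seeds. Sensitivity (~0.99) is computed over
planted shared genes that pass the expression filter; observed FDR
(~0.03) is measured against a null background. Lineage-specific
("interaction") genes are assessed separately: with independent
per-pair N(0, 1.2) effects, ~9–10% of them are classified shared —
these are draws whose three effects happen to land concordant and
near-equal, i.e. realized patterns that *are* shared and that no test
can reject; counting them as false discoveries (which would put the
strict FDR near 0.12) conflates the sampling mechanism of the truth
table with the realized signal, so the two quantities are reported
separately.

## Problem sizes and numerical choices

The acceptance script uses 800 genes × 20 seeds for recovery, 1,000
genes × 10,000 permutations for the strong-effect null, 20,000
Monte-Carlo draws against the 64-configuration exact null at 2 genes
(total-variation distance ~0.005), and 2,000 genes for null
calibration — sizes chosen so the full script completes in well under a
minute while keeping Monte-Carlo error far below the decision margins.
Ties in BH are handled by the step-up convention; LRT statistics are
clipped at zero with negative values beyond 1e-6 treated as convergence
failures; dispersions are floored at 1e-8 (effectively Poisson);
empty filter results are permitted and logged.

## Known limitations

* No dispersion moderation: per-gene estimates at ~5 replicates are
  noisy, and the habitat LRT runs ~1–2 points liberal at the 5% level
  (see Dispersion); the FDR thresholds used for classification operate
  on BH-adjusted values far in the tail, where the effect is smaller.
* The permutation null inherits the independence-across-genes
  assumption; co-regulated gene sets make it anticonservative in the
  same way as in the original analysis strategy.
* With only 3 pairs, the interaction test (df = 2, n ≈ 29) has limited
  power against mild heterogeneity; "shared" therefore means "no
  detectable interaction", not "provably equal effects".
* The length correction must be supplied externally; it cannot be
  estimated from counts alone.
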