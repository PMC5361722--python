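# Methods

## The region of independence (ROI_q)

For an expression matrix (genes × samples, raw non-negative values) and a
signature of k genes split into up- and down-directed subsets, each gene
present in the matrix ranks the n samples from lowest to highest
expression; down-directed genes are negated before ranking, so low
expression earns a high rank.  Tied expression receives average ranks —
the procedure is otherwise silent on ties, and average ranks keep the
observed rank-sum scale commensurate with the integer null below.  The
per-sample sum of the k ranks orders the cohort; equal sums are ordered by
sample id so results are deterministic.

The null asks where a patient with no coherent signature signal would land:
an artificial patient is ranked by each gene independently with an integer
drawn uniformly from {0, ..., n+1}, and the k draws are summed.  This is
repeated `n_trials` (default 10,000) times.  The region of independence at
quantile q (default 0.95) is the closed interval between the (1−q)/2 and
(1+q)/2 empirical quantiles of these null sums.  Nearest-rank (type-1)
quantiles are used so both bounds are attainable null values and the closed
interval provably contains at least a fraction q of the trials; empirical
coverage is therefore slightly above q (≈ 95.0–95.1% at q = 0.95), never
below.  Samples with rank sums strictly below the lower bound are labeled
`low`, strictly above the upper bound `high`, `independent` otherwise;
sums equal to a bound are conservatively independent, so activation is
never called without evidence.

Choices worth noting:

* **Integer vs continuous null.** The draw domain {0, ..., n+1} is the
  literal "rank among n+1 positions" reading; a continuous Uniform(0, n+1)
  variant is available behind `RoiConfig(integer_null=False)`.  For the
  small exact cases we enumerate, the integer pmf is the k-fold convolution
  of the uniform pmf on n+2 points and matches the sampled bounds within
  one rank-sum step at 10^5 trials.
* **Symmetric two-sided quantiles.** The defining property is only "contains
  q of the trials"; symmetry about the median is adopted because the
  low/high calls are meant to be exchangeable under direction reversal
  (swapping a signature's up and down sets exactly swaps the low and high
  label sets — a tested invariant).
* **Determinism.** Each signature draws from its own RNG stream derived
  from (seed, CRC32 of the signature id), so batch results do not depend on
  the order signatures are processed.
* **Minimum signature size.** Signatures with fewer than
  `min_genes_present` (default 5) genes in the matrix are skipped in batch
  runs rather than errored.

Everything is rank-based, so any strictly increasing per-gene transform of
the data leaves the partition unchanged.  The partition is deliberately a
cohort-level construct — adding samples can relabel others — which is
precisely the dependence the absolute models remove.

## Winnowing

A signature whose independent fraction exceeds 0.8 partitions the cohort no
better than a random gene set and is dropped (`informative` iff
frac_independent ≤ 0.8, the strict-"exceed" reading; the cutoff is
configurable).  The reference point is a single gene-label permutation of
the whole dataset, computed once and shared by all signatures; repeated
permutations can be requested by passing fresh `permuted_expr` matrices.
Winnowing warns below 200 samples, where the region is unstable.

## Gold standard and dataset balancing

ROI_95 labels are computed per training dataset, never on a merged matrix:
the training corpora this mimics span heterogeneous platforms whose
intensities are not commensurable.  Each sample receives weight
1 / (D · n_d) (D datasets, n_d samples in its dataset), so every dataset
contributes total weight 1/D regardless of size; duplicating an entire
dataset leaves weighted rule scores unchanged (tested).

## Rule mining, K selection, naive Bayes

For every ordered pair (x, y) of universe genes — the universe being the
explicit intersection of the training datasets' genes — the rule
"expr(x) > expr(y)" is scored per class c as

    score(r, c) = Ŵ(r true | c) − Ŵ(r true | not c),

the difference of weighted in-class and out-of-class frequencies of the
rule being true.  The source procedure never names its association
statistic; this is the simplest one consistent with ranking rules by
association strength, and it sits behind a small interface so alternatives
can be swapped in.  Both orientations are covered because (x, y) and
(y, x) are distinct ordered pairs.  The top-K list interleaves the
per-class rankings (high, low, independent, repeating) with deduplication
on the gene pair, so no class's evidence is starved by another's stronger
scores.

K is selected over `k_grid` (default 1–50) by 10-fold cross-validation,
stratified jointly by class and dataset, with rules re-ranked within each
training fold; the criterion is weighted Cohen's kappa on the held-out
fold, ties going to the smallest K.  If the rarest class has fewer samples
than folds, the fold count is reduced with a warning.

The K rules are combined by naive Bayes.  Weighted class counts are
rescaled to an effective n (weights sum to the number of labeled samples)
and Laplace-smoothed with α = 1:

    P(r true | c) = (eff_true_c + 1) / (eff_c + 2).

Priors are the weighted class frequencies (a uniform-prior option exists).
Posteriors are computed in log space; missing-gene rules at prediction
time are dropped and counted, with the likelihood renormalized over the
evaluated rules, and a call is refused when more than half the rules are
missing (threshold configurable).  Ties: equal expression makes a rule
false (strict >), and an exact posterior tie yields `independent`.

Models are retained only if Cohen's kappa against the gold standard is
significant in **every** training dataset after Bonferroni correction
across the candidate models (the correction family is logged in the
results; the family choice is ours, as the source leaves it open).
Training runs winnowing first — on the largest training dataset — so
uninformative signatures never reach the rule miner.

## Agreement statistics

`cohen_kappa` implements κ = (p_o − p_e)/(1 − p_e) with the classical
large-sample null variance

    var0 = [p_e + p_e² − Σ_c a_c b_c (a_c + b_c)] / [n (1 − p_e)²],

z = κ/se0 and a two-sided normal p-value.  The authoritative check is a
permutation oracle in the test suite: the analytic p tracks a 10^4-shuffle
null within Monte-Carlo error, and under simulated independence the
p-value is uniform.  Both-raters-constant-and-equal is flagged as
degenerate (κ undefined).  `fisher_association` is exact for 2×2 tables
and a seeded Monte-Carlo permutation test (chi-square statistic) for r×c;
`bh_fdr` is the standard step-up adjustment; a Kruskal–Wallis wrapper is
provided for score-vs-partition association.

## Cohort-composition instability experiment

`zscore_signature` standardizes each signature gene across the cohort
(population sd, for determinism; sample sd by flag), negates down genes,
and combines as Σ z_g / √k.  `stability_experiment` scores every sample in
the full cohort and again in its stratum-only cohort and reports the
absolute shift.  Any cohort-standardized scorer shifts when strata differ
in signature prevalence; an absolute model's posterior is a pure function
of (model, profile), so its shift is identically zero.  Only the z-score
combiner is implemented natively — it is fully specified by one formula —
and the harness accepts any scorer callable so external tools can be
plugged in.

## Synthetic data generator

The generator produces the cohort structure the ROI assumes.  On the log
scale, gene g in sample s is

    log x_gs = μ_g + ε_gs,   μ_g ~ N(base_log_mean, base_log_sd),
                             ε_gs ~ N(0, noise_sd),

exponentiated to non-negative raw values (log-normal-like intensities).
Gene-specific baselines μ_g matter: they give within-sample gene orderings
a stable component for pair rules to learn.  For each planted signature
(disjoint gene blocks), a fraction `frac_low`/`frac_high` of samples is
drawn at random as coherent blocks: high-block samples get +δ·noise_sd on
up genes and −δ on down genes (low mirrored); independent-block samples
get i.i.d. per-(gene, sample) N(0, δ·noise_sd) jitter, which preserves
marginal spread but destroys the coherent ordering.  Defaults (δ = 2–3 sd,
k = 15–50 genes, blocks 0.3/0.4/0.3, n = 200–500) are the regimes a
realistic strongly-regulated program would occupy.

Multi-dataset simulation shares μ_g and the signature truth across
datasets, draws fresh samples per dataset, and applies per-dataset global
affine distortions on the log scale plus optional class-fraction skew.
Platform pairs render the same samples twice; the distortion family is a
global (per-profile) affine log map plus gene-wise log offsets
(`gene_scale_sd`) plus i.i.d. noise.  A per-gene transform cannot be both
gene-specific and order-preserving within samples, so the zero-noise case
is per-profile affine (prediction agreement is then exactly 100%), and the
gene-wise offsets are the knob that perturbs cross-gene order the way a
real platform switch does.

What the generator does **not** emulate: gene–gene correlation outside
planted signatures, batch effects within a dataset, count noise
(overdispersion) of sequencing data, missing values, or probe-level
structure.  Passing tests therefore demonstrate the algorithmic properties
of the procedures — coverage, recovery, absoluteness, transfer under
monotone distortion — not performance on any real tumor cohort.

## Problem sizes and numerical choices

The validation suite uses cohorts of 200–500 samples, gene universes of
60–500 genes, 3 + 1 training/validation datasets of 200 samples each and
6 planted + 4 noise signatures for the end-to-end experiment; null
distributions use 10,000 trials (10^5 where checked against exact
enumeration).  These sizes put every distinguishing property well past its
detection threshold while a full run of the suite stays desk-scale.  Rule
truth values are cached as a float32 (pairs × samples) matrix shared across
signatures and CV folds; scoring a fold is then one matrix product.  The
acceptance script derives all per-run seeds from the single `--seed`
argument.

## Known limitations

* ROI labels for a random signature are still a deterministic function of
  the data, so pair rules can partially mimic them in-sample; winnowing
  before training is what keeps such models out, and skipping it
  (`do_winnow=False`) shifts that burden entirely onto the kappa filter.
* The association score, smoothing, priors, k-grid and Bonferroni family
  are this package's own defaults, config-exposed; they are not claimed to
  reproduce any particular published model catalogue.
* The mined rule space is quadratic in the universe size; universes beyond
  a few thousand genes need chunked mining or a pre-restricted universe.
* No survival analysis, no normal-vs-tumor state assessment, and no
  reimplementation of GSVA/ssGSEA/PLAGE (the z-score combiner stands in
  for relative scorers in the instability experiment).
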