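# aips — absolute single-sample calling of gene-signature activation

Pathway-activation scorers in common use (z-score combination, ssGSEA,
GSVA, PLAGE, ...) are *relative*: a patient's score for a gene signature is
only interpretable against the distribution of scores in a surrounding
cohort, and it moves when the cohort's composition changes — restrict a
breast-cancer dataset to ER-positive samples and every remaining patient's
score shifts.  That is unusable when a single tumor profile arrives in
isolation.

This package implements an *absolute* alternative in two stages, for
bulk or single-cell expression matrices on any platform whose within-sample
gene ordering is meaningful (microarray intensities, RNA-seq abundances):

**1. The region of independence (ROI_q)** — a cohort-level, rank-based
partition used to build training labels.  For a signature with k genes,
each gene ranks the n samples by expression (down-directed genes are
negated first), and the per-sample sum of the k ranks linearly orders the
cohort.  An artificial patient is ranked by drawing, per gene, an integer
uniformly from {0, ..., n+1} and summing; repeating this 10,000 times gives
a null rank-sum distribution, and the central interval containing q = 95%
of the trials is the region of independence.  Samples below it are called
**low**, above it **high**, inside it **independent** (no coherent
signature signal).  Signatures whose independent fraction exceeds 0.8
behave like random gene sets and are winnowed out.

**2. Absolute models** — for each informative signature, ROI_95 labels are
computed per training dataset (never on a merged matrix) and mimicked by a
single-sample classifier: every ordered gene pair (x, y) defines the binary
rule "expr(x) > expr(y)", rules are ranked per class by their
dataset-balanced association with the gold-standard labels, the top K
(chosen by stratified 10-fold cross-validation on weighted Cohen's kappa)
are combined in a naive Bayes classifier, and only models whose agreement
with the gold standard is Bonferroni-significant in **every** training
dataset are retained.  A retained model classifies one profile using only
within-sample comparisons, so its call is invariant to monotone platform
transforms and can never depend on which other samples happen to be around.

## Worked example

```python
import warnings
from aips import *

# a synthetic 300-sample cohort with one planted 40-gene signature
cfg = SimConfig(
    n_samples=300, n_genes=200,
    signatures=[SignatureSpec("ESR1_UPDN", k=40, frac_low=0.3, frac_high=0.3,
                              delta=3.0, frac_down=0.25)],
    seed=42,
)
expr, truth = simulate_cohort(cfg)
sig = truth.signatures["ESR1_UPDN"]

# cohort-level partition
res = SignatureROI(expr, sig, q=0.95, n_trials=10_000).fit(seed=7)
print(res.summary())

# train absolute models on three independent synthetic datasets
datasets = {k: v[0] for k, v in simulate_multidataset(cfg, 3).items()}
results = AipsTrainer(datasets, [sig], k_grid=range(1, 21), seed=7).fit()
print(results.summary())

# classify one profile in isolation
model = results.retained_models[0]
pred = predict_single(model, expr.profile("S000"), sample_id="S000")
```

This prints:

```
ROI_0.95 partition for signature 'ESR1_UPDN'
  samples: 300   signature genes used: 40
  null trials: 10000   region: [4916, 7112]   null coverage: 0.9502
  class fractions: low=0.317  independent=0.383  high=0.300

Absolute signature model training
  gene universe: 200 genes
  candidate signatures: 1  informative: 1
  trained models: 1  retained (Bonferroni alpha=0.05): 1

  signature                   K  min kappa      max p retained
  ESR1_UPDN                  19      0.965  6.27e-123 True
```

The ROI recovered the planted 30/40/30 block structure (fractions
0.317/0.383/0.300) and its region contains 95.0% of the null trials, as the
construction guarantees.  The trained 19-rule model agrees with the
per-dataset gold standard at kappa ≥ 0.965 and classifies sample `S000` as
`high` with posterior 0.9995 — matching its planted label — from that one
profile alone.

The same pipeline is available from the shell: `aips simulate`, `aips roi`,
`aips winnow`, `aips train`, `aips predict`, `aips stability`,
`aips collapse`, `aips kappa` (see `aips --help`).

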