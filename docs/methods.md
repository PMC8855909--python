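# Methods

## Model overview

`brafsig` treats BRAF pathway activity as a latent, continuous quantity
observable through a weighted set of upregulated genes. The pipeline
has four statistical stages: signature construction, single-sample
scoring, copy-number amplification calling, and downstream clinical
association. Each stage is exposed as library functions and a CLI
subcommand; all randomness flows from explicit integer seeds.

## Signature construction

Expression enters as nonnegative linear-scale estimates (RSEM-like) and
is transformed as log2(x + 1). The pseudocount keeps zeros at zero and
makes the transform invertible; the transform state is tracked on the
matrix object and double transformation is refused.

Sample labels come from MAF-style mutation records: *mutant* = at least
one BRAF V600E row; *wildtype* = no BRAF row of any kind; *excluded* =
BRAF-mutated but never V600E. Excluded samples are dropped from
training, since they are neither clean cases nor clean controls.
Samples with missing age or sex are dropped with a warning rather than
imputed — per-gene fits should not differ in their case weighting.

Each gene is fit independently by maximum-likelihood logistic
regression of mutant status on (gene, age, sex), via Newton iterations
(statsmodels). Genes whose fit fails, separates, or has non-finite
standard errors are excluded rather than patched; a zero-variance gene
is non-estimable by construction. Ranking uses the Wald p-value of the
gene coefficient — a single cheap statistic that is consistent across
tens of thousands of genes; ties in p are broken lexicographically by
gene identifier for determinism. The signature keeps the top n genes
with positive gene coefficient and assigns weights

    w = min(-log10 p, 10) / 10  ∈ [0, 1],

capping −log₁₀p at 10 so a few extreme genes cannot dominate. Note the
cap also implies p = 1 → w = 0; in practice selected genes have small p
and weights well above 0.

Signature size defaults to 200. `cross_validate_sizes` estimates
classification power over a size grid (default 20, 40, …, 800) by
stratified k-fold cross-validation (default 5 folds), refitting the
per-gene models on training folds and scoring held-out folds; AUC
against mutation status is the metric. Cross-validation scoring uses a
reduced permutation count (default 100) since only the within-fold
ranking of scores matters for AUC.

## Single-sample scoring

Scoring is cohort-relative: each gene's across-sample median is
subtracted first, so a sample's profile records deviation from the
cohort. A single sample therefore cannot be scored alone; append it to
a reference cohort. After restriction to the signature genes (at least
80% of the signature must be present, configurable), the profile is
sorted into decreasing normalized expression with ties broken by gene
identifier.

The statistic is a weighted two-sample Kolmogorov–Smirnov construction
over the ranked list: foreground and background CDFs accumulate
|g_k|·w_k and |g_k|·(1−w_k) respectively, each normalized by its total,
and the pre-score is the value of f − b at the index maximizing
|f − b| (first such index on ties). Ranking uses the *signed* values —
upregulated genes first — while accumulation uses magnitudes, so both
curves are genuine distribution functions rising from 0 to 1.
Accumulating signed values instead would place Σ g_k w_k in the
denominators; because median-normalized values sum to approximately
zero, those denominators hover near zero with arbitrary sign and the
statistic becomes unbounded and directionless (we measured chance-level
mutant/wildtype discrimination under that variant). The magnitude
construction is the one under which the score behaves as the
enrichment-style statistic the method intends: positive when
high-weight genes concentrate at the top of the sample's ranking,
negative when they concentrate at the bottom.

With all weights equal (e.g. w = 0.5) the two curves coincide and the
pre-score is exactly 0; swapping w for 1 − w negates the pre-score.

**Permutation null.** The null shuffles the alignment between the
sorted expression vector and the weight vector within the signature
subset (the sample's ranking is its data; what is random under the
null is which rank carries which weight) and recomputes the pre-score;
1000 permutations by default. Each sample's permutation stream is
seeded from the cohort seed and the sample identifier, making scores
independent of column order and bit-reproducible.

**Normalization.** score = pre-score / mean(|null pre-scores|), keeping
the pre-score's sign. The summary is configurable: `mean` (default),
`median`, or `signed_mean` (mean over null values sharing the
pre-score's sign, the normalized-enrichment-score convention, falling
back to all values when none share it). The default uses every
permutation and, because the null is close to sign-symmetric, has the
smallest Monte-Carlo variance: on a reference sample at 1000
permutations the score's spread across independent seeds is ~4.6%
relative, versus ~7.6% for the sign-stratified summary (which halves
the effective permutation count and adds random-denominator-count
noise). A zero pre-score maps to score 0; an all-zero null (possible
only for degenerate profiles) is an error.

## Amplification calling

Linear copy numbers are transformed as log2(cn / 2) so diploid maps to
exactly 0; log2-ratio input passes through. The dialect is declared by
the caller, never sniffed — the transform silently corrupts calls if
guessed wrong. A sample is AMP for a gene when some segment overlapping
the gene locus (1-based closed intervals, SEG convention) has
transformed value strictly greater than log2(2.8/2) ≈ 0.485 and segment
length (end − start + 1) strictly less than 151 Mb; otherwise WT. The
2.8-copy threshold (rather than 3.0) absorbs tumor-purity dilution; the
length cap excludes whole-chromosome-7 gains from counting as focal
BRAF/EGFR amplification. Both inequalities are strict and pinned by
boundary tests. When several segments qualify, any one suffices for the
call and the one with maximal locus overlap is recorded as supporting
evidence; the length threshold applies to the segment, not to its
overlap with the locus. The same configuration applies to any locus
(BRAF and EGFR both sit on chromosome 7 and share the defaults).

## Downstream statistics

* **Median dichotomization**: values strictly above the median → high,
  at or below → low. The deterministic tie rule best approximates two
  equal-sized groups; an all-constant vector has no split and errors.
* **One-sided Wilcoxon rank-sum** (aberrant > wildtype): exact
  enumeration when the pooled sample has ≤ 12 observations without
  ties, normal approximation with tie correction otherwise (scipy).
* **ROC/AUC**: pairwise probability form, ties counted half
  (scikit-learn).
* **Survival**: Kaplan–Meier product-limit curves per group, two-sample
  log-rank test, univariate Cox proportional hazards with Efron tie
  handling and 95% Wald intervals (lifelines). Non-converged Cox fits
  (e.g. survival-separated groups) are flagged, not raised.
* **Drug sensitivity**: per-drug Pearson correlation of score with IC50
  over shared cell lines (≥ 3 required), two-sided p, sorted for
  volcano-style reporting; constant inputs flag the drug as undefined.
* **Therapy response**: group×response contingency table with response
  rates, two-sided Fisher exact test, and a multivariate logistic model
  of response on score plus optional age/sex/other-therapy covariates
  (separation flagged).

No multiple-testing correction is applied across drugs or genes: the
ranking consumes raw p-values by design.

## Synthetic cohorts

The generator produces the statistical structure the analyses assume,
with planted ground truth returned alongside every dataset:

* **Expression**: log2 values ~ Normal(baseline 8, sd 1); a planted
  gene set is shifted up by `effect_size` (default 1.0 log2 units) in
  mutant samples; linear scale is 2^x − 1 clipped at 0, so the
  pipeline's log2(x+1) recovers the planted shift exactly while the
  linear values show RSEM-like right skew. Defaults: 5000 genes, 80
  samples (half mutant), 100 signal genes. Age ~ Uniform(30, 85),
  sex ~ Bernoulli(0.5). Mutants are written as MAF `p.V600E` rows plus
  scattered passenger mutations.
* **`signal_seed`** decouples the planted-biology draw from the
  sampling noise: fixing it while varying `seed` yields independent
  cohorts from the same "population", giving honest train/held-out
  evaluations.
* **Copy number**: a chosen number of samples carry a gain segment of
  given copy number and length centered on the locus; all others are
  diploid.
* **Survival**: exponential proportional hazards; samples above the
  score median have hazard divided by `hazard_ratio` (high score →
  longer survival), with independent exponential censoring.
* **Drug**: IC50 = intercept + slope·score + Normal(0, σ); choosing
  σ = sd(score)·√(1/ρ² − 1) plants an exact population correlation ρ.
* **Response**: Bernoulli response at 60% (low-score) vs 20%
  (high-score) rates, the contrast reported for checkpoint-blockade
  sensitivity.

What the generator does **not** emulate: pathway co-expression
structure (planted genes are independent), tumor-purity mixtures,
single-cell dropout, and batch effects. Passing tests therefore show
the pipeline recovers planted signals of realistic magnitude under
clean noise — not that it is robust to those real-data pathologies.

One master seed expands into named child seeds via
`numpy.random.SeedSequence.spawn`, so subsystems are reproducible in
isolation; all derived seeds stay below 2³¹.

## Problem sizes and tolerances

The reference test conditions are 5000 genes × 80 samples for training
(40 mutant / 40 wildtype, 100 planted genes, effect 1.0, sd 1.0) and a
held-out cohort of the same shape; the acceptance script scores a
400-sample held-out cohort, the scale of a metastatic validation set.
Oracle-equivalence checks (curves, pre-score) are asserted at 1e-12;
exact tests (Wilcoxon, Fisher) are swept against full enumeration for
pooled n ≤ 8; hazard-ratio recovery is asserted within 0.15 on the log
scale over 50 replicates at n = 400; Monte-Carlo score stability is
asserted below 5% relative across 20 seeds at 1000 permutations.

## Known limitations

* Scores are cohort-relative (median normalization): the same sample
  scored against different reference cohorts gets different values;
  cross-dataset score magnitudes are not comparable.
* The weighted-KS statistic uses only within-signature information; a
  signature whose weights are nearly constant carries almost no
  discriminating power regardless of the expression data.
* Per-gene logistic fits at small n (tens of samples) produce noisy
  p-values; separated genes are dropped, which can bias against the
  strongest markers in tiny cohorts.
* Amplification calling ignores tumor purity beyond the 2.8-copy slack
  and performs no GISTIC-style recurrence modeling.
* Downweighted ("downregulated") signature components are out of
  scope; only upregulated weights are defined.
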