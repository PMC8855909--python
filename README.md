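# brafsig

A pipeline for building and applying a weighted **BRAF-V600E gene
signature** in melanoma transcriptomics. About half of skin cutaneous
melanomas carry the activating BRAF V600E mutation, which drives the
MAPK/ERK pathway — but other aberrations (BRAF amplification, NRAS
mutation, EGFR amplification) can activate the same pathway. A
continuous, expression-based *pathway-activity score* is therefore more
informative than the binary mutation call for prognosis and for
predicting sensitivity to BRAF inhibitors. `brafsig` implements that
idea end to end for anyone working with bulk or single-cell expression
cohorts plus mutation / copy-number / clinical annotations.

## What it computes

**Signature construction.** Each gene's log2 expression is used to
predict V600E status in a labeled cohort via per-gene logistic
regression with clinical covariates,

&nbsp;&nbsp;&nbsp;&nbsp;P(mutant) = σ(β₀ + β₁·gene + β₂·age + β₃·sex).

The top *n* genes with β₁ > 0 (default n = 200), ranked by the Wald
p-value of β₁, form the signature with weights
w = min(−log₁₀ p, 10) / 10.

**Per-sample score.** For each sample the cohort-median-normalized
profile is restricted to the signature genes and sorted into decreasing
order g₁ ≥ … ≥ gₙ. Two cumulative distribution functions are built over
the magnitudes,

&nbsp;&nbsp;&nbsp;&nbsp;f(i) = Σₖ≤ᵢ |gₖ|·wₖ / Σₖ≤ₙ |gₖ|·wₖ,
&nbsp;&nbsp;&nbsp;&nbsp;b(i) = Σₖ≤ᵢ |gₖ|·(1−wₖ) / Σₖ≤ₙ |gₖ|·(1−wₖ),

and the **pre-score** is the signed extremum of f − b (a weighted
Kolmogorov–Smirnov statistic in the GSEA/BASE family): positive when
high-weight genes crowd the top of the ranking, negative when they sink
to the bottom. The **score** divides the pre-score by the mean |null
pre-score| over 1000 permutations of the weight-to-rank alignment.

**Downstream analyses.** Copy-number amplification calls from SEG
segments (log2 ratio > log2(2.8/2) and segment length < 151 Mb, both
strict), one-sided Wilcoxon score comparisons between aberrant and
wildtype groups, ROC/AUC, Kaplan–Meier + log-rank + univariate Cox
survival stratification at the median score, per-drug Pearson
correlation of score with IC50, and Fisher / logistic-regression
analysis of binary therapy response.

A fully seeded synthetic-data module generates cohorts with planted
ground truth (signal genes, amplified samples, survival hazards, IC50
couplings) in exactly the file dialects the parsers read, so the whole
pipeline is testable without any external downloads.

## Worked example

Build a signature on a labeled cohort and score an independent cohort
drawn from the same population:

```python
import pandas as pd
from brafsig import (CohortSpec, gen_expression, log2_transform,
                     label_braf_status, select_signature, score_cohort,
                     roc_auc, wilcoxon_one_sided)
from brafsig.signature import fit_all_genes

train = gen_expression(CohortSpec(n_genes=2000, n_samples=80,
                                  n_signal_genes=50, seed=1))
logm = log2_transform(train.matrix)
status = label_braf_status(train.mutations, list(logm.sample_ids))
fits = fit_all_genes(logm, status, train.covariates)
signature = select_signature(fits, 100)
print("recovered planted genes:",
      len(set(signature.genes) & set(train.signal_genes)), "/ 50")

test = gen_expression(CohortSpec(n_genes=2000, n_samples=80,
                                 n_signal_genes=50, seed=2, signal_seed=1))
results = score_cohort(log2_transform(test.matrix), signature,
                       n_permutations=1000, seed=0)
scores = pd.Series([r.score for r in results],
                   index=[r.sample_id for r in results])
mut = scores.index.isin(test.mutant_samples)
print(f"mutant mean score:   {scores[mut].mean():+.2f}")
print(f"wildtype mean score: {scores[~mut].mean():+.2f}")
print(f"AUC: {roc_auc(scores.to_numpy(), mut.astype(int)).auc:.3f}")
print(f"one-sided Wilcoxon p: "
      f"{wilcoxon_one_sided(scores[mut], scores[~mut]).p_value:.2e}")
```

Output:

```
recovered planted genes: 49 / 50
mutant mean score:   +1.37
wildtype mean score: -1.36
AUC: 0.988
one-sided Wilcoxon p: 2.95e-14
```

49 of the 50 planted signal genes make the 100-gene signature; on the
held-out cohort, mutant samples score strongly positive and wildtype
samples negative, separating the two groups almost perfectly
(AUC 0.988) with overwhelming rank-sum evidence that mutants score
higher.

The same stages are available as a CLI:

```bash
brafsig simulate --out-dir fixtures --seed 7
brafsig build-signature --expression fixtures/expression.tsv \
    --mutations fixtures/mutations.maf.tsv --clinical fixtures/clinical.tsv \
    --out signature.tsv
brafsig score --expression fixtures/expression.tsv \
    --signature signature.tsv --out scores.tsv --seed 7
brafsig call-aberrations --segments fixtures/segments.seg.tsv \
    --locus 7 140419127 140624564 BRAF --out calls.tsv
brafsig analyze --scores scores.tsv --mutations fixtures/mutations.maf.tsv \
    --clinical fixtures/clinical.tsv --drug fixtures/drug_response.tsv \
    --response fixtures/therapy_response.tsv --out-dir report
```

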