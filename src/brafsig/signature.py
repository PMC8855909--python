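"""Construction of the weighted mutation signature.

The signature is built from a labeled cohort: every gene's log2
expression is used, together with age and sex, as the predictor in a
per-gene logistic regression of V600E mutant vs. wildtype status,

    P(mutant) = sigmoid(b0 + b1 * gene + b2 * age + b3 * sex).

Genes with positive b1 (upregulated in mutants) are ranked by the Wald
p-value of b1; the top n form the signature with per-gene weight

    w = min(-log10(p), 10) / 10,

i.e. -log10 p capped at 10 so a handful of extreme genes cannot
dominate the score. Samples carrying a non-V600E BRAF mutation are
excluded from training since they are neither clean mutants nor clean
wildtypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import (
    ExpressionMatrix,
    ParameterError,
    SignatureWeights,
    LINEAR,
    LOG2,
)

logger = logging.getLogger(__name__)

MUTANT = "mutant"
WILDTYPE = "wildtype"
EXCLUDED = "excluded"

WEIGHT_CAP = 10.0  # cap on -log10(p) before scaling into [0, 1]


@dataclass
class GeneFit:
    """Per-gene logistic fit: intercept, gene, age, sex coefficients."""

    gene: str
    beta0: float = np.nan
    beta1: float = np.nan
    beta2: float = np.nan
    beta3: float = np.nan
    p_value: float = np.nan
    converged: bool = False


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value x by log2(x + 1).

    The +1 pseudocount keeps zero-expression genes at exactly 0 and
    makes the transform invertible. Double transformation is refused.
    """
    if matrix.transform_state == LOG2:
        raise ParameterError("matrix is already log2-transformed")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), transform_state=LOG2)


def inverse_log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if matrix.transform_state == LINEAR:
        raise ParameterError("matrix is already on the linear scale")
    return ExpressionMatrix(
        np.exp2(matrix.values) - 1.0, transform_state=LINEAR
    )


def _normalize_protein_change(value: str) -> str:
    value = str(value).strip()
    return value[2:] if value.startswith("p.") else value


def label_braf_status(mutations: pd.DataFrame, samples: list[str]) -> pd.Series:
    """Per-sample BRAF label from a MAF-minimal table.

    mutant: at least one BRAF V600E record; wildtype: no BRAF record of
    any kind; excluded: BRAF records but none of them V600E. Mutation
    rows for samples outside ``samples`` are dropped with a warning.
    """
    samples = [str(s) for s in samples]
    known = set(samples)
    muts = mutations.copy()
    muts["Tumor_Sample_Barcode"] = muts["Tumor_Sample_Barcode"].astype(str)
    unknown = set(muts["Tumor_Sample_Barcode"]) - known
    if unknown:
        logger.warning(
            "dropping mutation rows for %d sample(s) absent from the "
            "expression matrix", len(unknown)
        )
        muts = muts[muts["Tumor_Sample_Barcode"].isin(known)]

    braf = muts[muts["Hugo_Symbol"].astype(str) == "BRAF"]
    v600e_samples = set(
        braf.loc[
            braf["HGVSp_Short"].map(_normalize_protein_change) == "V600E",
            "Tumor_Sample_Barcode",
        ]
    )
    any_braf_samples = set(braf["Tumor_Sample_Barcode"])

    labels = []
    for s in samples:
        if s in v600e_samples:
            labels.append(MUTANT)
        elif s not in any_braf_samples:
            labels.append(WILDTYPE)
        else:
            labels.append(EXCLUDED)
    return pd.Series(labels, index=pd.Index(samples, name="sample_id"),
                     name="braf_status")


def fit_gene_model(
    gene_expr: np.ndarray,
    status: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    gene: str = "",
) -> GeneFit:
    """Maximum-likelihood logistic fit of status on one gene + covariates.

    Returns the coefficient estimates and the Wald p-value for the gene
    coefficient. A zero-variance gene, a failed or separated fit, or
    non-finite standard errors all yield ``converged=False`` so the gene
    is excluded downstream rather than patched.
    """
    gene_expr = np.asarray(gene_expr, dtype=float)
    status = np.asarray(status, dtype=float)
    classes = np.unique(status)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ParameterError("status must be binary with both classes present")
    if np.ptp(gene_expr) == 0:
        return GeneFit(gene=gene, converged=False)
    X = np.column_stack([
        np.ones_like(gene_expr),
        gene_expr,
        np.asarray(age, dtype=float),
        np.asarray(sex, dtype=float),
    ])
    if not np.isfinite(X).all():
        raise ParameterError("covariates must be finite")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(status, X).fit(disp=0, method="newton", maxiter=50)
    except Exception:
        return GeneFit(gene=gene, converged=False)
    ok = (
        bool(res.mle_retvals.get("converged", False))
        and np.isfinite(res.params).all()
        and np.isfinite(res.bse).all()
        and np.isfinite(res.pvalues[1])
        and res.pvalues[1] > 0
    )
    return GeneFit(
        gene=gene,
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        beta2=float(res.params[2]),
        beta3=float(res.params[3]),
        p_value=float(res.pvalues[1]),
        converged=ok,
    )


def fit_all_genes(
    matrix: ExpressionMatrix,
    status: pd.Series,
    covariates: pd.DataFrame,
) -> list[GeneFit]:
    """Fit the per-gene logistic model for every gene in the matrix.

    ``status`` holds mutant/wildtype/excluded labels indexed by sample;
    excluded samples and samples with missing covariates are dropped
    (with a warning) before fitting.
    """
    if matrix.transform_state != LOG2:
        raise ParameterError("expression must be log2-transformed before fitting")
    cov = covariates.set_index(covariates["sample_id"].astype(str))
    status = status[status.isin([MUTANT, WILDTYPE])]
    keep = [
        s for s in matrix.sample_ids.astype(str)
        if s in status.index and s in cov.index
        and np.isfinite(cov.loc[s, "age"]) and np.isfinite(cov.loc[s, "sex"])
    ]
    dropped = matrix.n_samples - len(keep)
    if dropped:
        logger.warning("dropping %d sample(s) without usable label/covariates",
                       dropped)
    y = (status.loc[keep] == MUTANT).to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ParameterError("both mutant and wildtype samples are required")
    age = cov.loc[keep, "age"].to_numpy(dtype=float)
    sex = cov.loc[keep, "sex"].to_numpy(dtype=float)
    sub = matrix.values[keep].to_numpy(dtype=float)
    logger.info("fitting %d genes on %d samples (%d mutant / %d wildtype)",
                matrix.n_genes, len(keep), int(y.sum()), int((1 - y).sum()))
    return [
        fit_gene_model(sub[i], y, age, sex, gene=str(g))
        for i, g in enumerate(matrix.gene_ids)
    ]


def weight_from_p(p: float) -> float:
    """Signature weight min(-log10(p), 10) / 10, on [0, 1]."""
    if p <= 0:
        return 1.0
    return min(-np.log10(p), WEIGHT_CAP) / WEIGHT_CAP


def select_signature(fits: list[GeneFit], n: int) -> SignatureWeights:
    """Top-n upregulated genes by ascending Wald p, with capped weights.

    Keeps converged fits with b1 > 0, sorts by (p, gene identifier) for
    determinism under ties, takes the first n and assigns each the
    weight min(-log10 p, 10)/10.
    """
    if not fits:
        raise ParameterError("no gene fits supplied")
    eligible = [
        f for f in fits
        if f.converged and f.beta1 > 0 and np.isfinite(f.p_value)
    ]
    if len(eligible) < n:
        raise ParameterError(
            f"only {len(eligible)} eligible upregulated genes, "
            f"cannot build a signature of size {n} "
            f"(short by {n - len(eligible)})"
        )
    eligible.sort(key=lambda f: (f.p_value, f.gene))
    chosen = eligible[:n]
    return SignatureWeights(
        genes=[f.gene for f in chosen],
        weights=np.array([weight_from_p(f.p_value) for f in chosen]),
        provenance={
            "n_requested": n,
            "n_eligible": len(eligible),
            "min_p": chosen[0].p_value,
            "max_p": chosen[-1].p_value,
        },
    )


def build_signature(
    matrix: ExpressionMatrix,
    mutations: pd.DataFrame,
    covariates: pd.DataFrame,
    n: int = 200,
) -> SignatureWeights:
    """End-to-end signature construction from a labeled linear cohort."""
    if matrix.transform_state == LINEAR:
        matrix = log2_transform(matrix)
    status = label_braf_status(mutations, list(matrix.sample_ids))
    fits = fit_all_genes(matrix, status, covariates)
    return select_signature(fits, n)


DEFAULT_SIZE_GRID = tuple(range(20, 801, 20))


def cross_validate_sizes(
    matrix: ExpressionMatrix,
    status: pd.Series,
    covariates: pd.DataFrame,
    sizes: tuple[int, ...] = DEFAULT_SIZE_GRID,
    k_folds: int = 5,
    seed: int = 0,
    n_permutations: int = 100,
) -> pd.DataFrame:
    """Cross-validated classification power of signatures of varying size.

    For each candidate size, a signature is fit on the training folds and
    each held-out sample is scored; the AUC of score vs. mutation status
    is averaged over folds. Folds are stratified by status. Sizes larger
    than the number of eligible genes in some fold are flagged in the
    output rather than silently skipped. Scoring inside cross-validation
    uses a reduced permutation count since only the score ranking within
    a fold matters for AUC.
    """
    from sklearn.model_selection import StratifiedKFold

    from .scoring import score_cohort
    from .stats import roc_auc

    if list(sizes) != sorted(sizes):
        raise ParameterError("sizes must be ascending")
    if k_folds < 2:
        raise ParameterError("k_folds must be >= 2")
    if matrix.transform_state == LINEAR:
        matrix = log2_transform(matrix)

    usable = status[status.isin([MUTANT, WILDTYPE])].index
    sub = ExpressionMatrix(matrix.values[list(usable)], transform_state=LOG2)
    y = (status.loc[usable] == MUTANT).to_numpy(dtype=int)

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_aucs: dict[int, list[float]] = {s: [] for s in sizes}
    flagged: set[int] = set()
    for fold_i, (train, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_ids = [usable[i] for i in train]
        test_ids = [usable[i] for i in test]
        train_m = ExpressionMatrix(sub.values[train_ids], transform_state=LOG2)
        test_m = ExpressionMatrix(sub.values[test_ids], transform_state=LOG2)
        fits = fit_all_genes(train_m, status.loc[train_ids], covariates)
        for size in sizes:
            try:
                sig = select_signature(fits, size)
            except ParameterError:
                flagged.add(size)
                continue
            results = score_cohort(
                test_m, sig, n_permutations=n_permutations,
                seed=seed + fold_i,
            )
            scores = np.array([r.score for r in results])
            fold_aucs[size].append(roc_auc(scores, y[test]).auc)

    rows = []
    for size in sizes:
        aucs = fold_aucs[size]
        rows.append(
            {
                "size": size,
                "mean_auc": float(np.mean(aucs)) if aucs else np.nan,
                "n_folds": len(aucs),
                "flagged": size in flagged,
            }
        )
    return pd.DataFrame(rows)
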