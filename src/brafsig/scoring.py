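"""Single-sample signature activity scoring.

The score follows the BASE (binding association with sorted expression)
family of rank-based single-sample statistics, a close relative of the
GSEA enrichment score. For one sample:

1. the cohort is median-normalized per gene (across-sample median
   subtracted), so each value is the sample's deviation from the cohort;
2. the profile is restricted to the signature genes and sorted into
   decreasing normalized expression, giving values g_1 >= ... >= g_n
   with aligned weights w_1, ..., w_n;
3. two cumulative curves are formed over the magnitudes of the ranked
   values g_1 >= ... >= g_n,

       f(i) = sum_{k<=i} |g_k| w_k       / sum_{k<=n} |g_k| w_k
       b(i) = sum_{k<=i} |g_k| (1 - w_k) / sum_{k<=n} |g_k| (1 - w_k),

   the foreground tracking high-weight (informative) genes and the
   background the complementary weighting. Ranking uses the signed
   values (upregulated genes first) while accumulation uses their
   magnitudes, so f and b are genuine distribution functions rising
   from 0 to 1 — the weighted Kolmogorov-Smirnov construction of the
   GSEA/BASE family. Accumulating signed values instead would put
   near-zero, sign-flipping sums in the denominators (the centered
   values sum to roughly zero by construction) and the ratio would be
   unbounded and directionless;
4. the pre-score is the signed extremum of f - b (the value of f(i)-b(i)
   at the index maximizing |f - b|) — positive when high-weight genes
   concentrate at the top of the ranking;
5. the pre-score is normalized against a permutation null obtained by
   shuffling the alignment between the sorted values and the weights
   (1000 permutations by default): the score divides the pre-score by
   the mean absolute value of the null pre-scores. The null summary is
   configurable (mean of |null|, median of |null|, or the sign-
   stratified mean of the normalized-enrichment-score convention).

Scores are signed: a strongly negative score means signature genes sit
at the bottom of the sample's ranking (pathway underexpression).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    DegenerateInputError,
    ExpressionMatrix,
    ParameterError,
    ScoreResult,
    SignatureWeights,
    LOG2,
)

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_MIN_OVERLAP = 0.8

_NULL_SUMMARIES = ("mean", "median", "signed_mean")


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-sample median from every sample.

    Requires at least two samples: the median of a single sample would
    zero the whole profile and the score is only meaningful relative to
    a reference cohort.
    """
    if matrix.transform_state != LOG2:
        raise ParameterError("median normalization expects log2 expression")
    if matrix.n_samples < 2:
        raise DegenerateInputError(
            "median normalization needs >= 2 samples; score single samples "
            "by appending them to a reference cohort"
        )
    centered = matrix.values.sub(matrix.values.median(axis=1), axis=0)
    return ExpressionMatrix(centered, transform_state=LOG2)


@dataclass
class RankedProfile:
    """Signature-subset expression of one sample, sorted decreasing."""

    genes: list[str]
    g: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.genes) == len(self.g) == len(self.w)):
            raise ParameterError("genes, g and w must be aligned")
        if np.any(np.diff(self.g) > 0):
            raise ParameterError("g must be non-increasing")


@dataclass
class CumulativeCurves:
    f: np.ndarray
    b: np.ndarray


def rank_signature_subset(
    sample_profile: pd.Series,
    signature: SignatureWeights,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
) -> RankedProfile:
    """Restrict a normalized profile to the signature and sort it.

    Sorting is by decreasing normalized expression; ties are broken by
    gene identifier so the ranking is deterministic across platforms.
    Fails if fewer than ``min_overlap_fraction`` of the signature genes
    are present in the profile.
    """
    present = [g for g in signature.genes if g in sample_profile.index]
    n_missing = signature.size - len(present)
    if len(present) < min_overlap_fraction * signature.size:
        raise ParameterError(
            f"only {len(present)}/{signature.size} signature genes present "
            f"({n_missing} missing); need at least "
            f"{min_overlap_fraction:.0%} overlap"
        )
    w_map = dict(zip(signature.genes, signature.weights))
    g = sample_profile[present].to_numpy(dtype=float)
    w = np.array([w_map[x] for x in present])
    names = np.array(present, dtype=object)
    # lexsort: last key is primary -> decreasing g, then gene id ascending
    order = np.lexsort((names, -g))
    return RankedProfile(
        genes=[str(x) for x in names[order]], g=g[order], w=w[order]
    )


def cumulative_curves(profile: RankedProfile) -> CumulativeCurves:
    """Foreground/background cumulative ratios of the ranked profile.

    Accumulates |g_k| weighted by w_k (foreground) and 1 - w_k
    (background); both curves are non-decreasing and end at 1.
    """
    return _curves_from_arrays(profile.g, profile.w)


def _curves_from_arrays(g: np.ndarray, w: np.ndarray) -> CumulativeCurves:
    mag = np.abs(g)
    fg = mag * w
    bg = mag * (1.0 - w)
    f_den = fg.sum()
    b_den = bg.sum()
    if f_den == 0.0 or b_den == 0.0:
        raise DegenerateInputError(
            "degenerate profile: zero cumulative-curve denominator "
            f"(foreground={f_den}, background={b_den})"
        )
    return CumulativeCurves(f=np.cumsum(fg) / f_den, b=np.cumsum(bg) / b_den)


def pre_score(curves: CumulativeCurves) -> float:
    """Signed extremum of f - b: the value at the index maximizing |f - b|."""
    d = curves.f - curves.b
    return float(d[np.argmax(np.abs(d))])


def null_distribution(
    profile: RankedProfile,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> np.ndarray:
    """Permutation null of the pre-score.

    Each permutation shuffles the alignment between the sorted
    expression values and the weight vector (the ordering of g is the
    sample's data and stays fixed; what is random under the null is
    which rank carries which weight), then recomputes the curves and the
    signed pre-score. Restricted to the signature subset, matching the
    cumulative sums' range.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(profile.g)
    mag = np.abs(profile.g)
    W = rng.permuted(
        np.tile(profile.w, (n_permutations, 1)), axis=1
    )
    fg = mag[None, :] * W
    bg = mag[None, :] * (1.0 - W)
    f_den = fg.sum(axis=1)
    b_den = bg.sum(axis=1)
    if np.any(f_den == 0.0) or np.any(b_den == 0.0):
        raise DegenerateInputError(
            "zero cumulative-curve denominator in a permutation"
        )
    d = np.cumsum(fg, axis=1) / f_den[:, None] - np.cumsum(bg, axis=1) / b_den[:, None]
    idx = np.argmax(np.abs(d), axis=1)
    return d[np.arange(n_permutations), idx]


def normalize_score(
    pre: float,
    null: np.ndarray,
    null_summary: str = "mean",
) -> tuple[float, float, float]:
    """Normalize a pre-score against its permutation null.

    Returns ``(score, null_mean_pos, null_mean_neg)``. The default
    divides the pre-score by the mean absolute value of all null
    pre-scores, which keeps the sign of the pre-score and uses every
    permutation (the lowest-variance Monte-Carlo summary; the null is
    close to sign-symmetric so the same-signed restriction adds noise
    without changing the scale). ``"median"`` swaps in the median of
    |null|; ``"signed_mean"`` restricts to the null values sharing the
    pre-score's sign (the normalized-enrichment-score convention),
    falling back to all of them when none share it. A zero pre-score
    maps to score 0.
    """
    if null_summary not in _NULL_SUMMARIES:
        raise ParameterError(f"null_summary must be one of {_NULL_SUMMARIES}")
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ParameterError("null distribution is empty")
    pos = null[null > 0]
    neg = null[null < 0]
    null_mean_pos = float(np.mean(pos)) if pos.size else np.nan
    null_mean_neg = float(np.mean(neg)) if neg.size else np.nan
    if pre == 0.0:
        return 0.0, null_mean_pos, null_mean_neg
    if np.all(null == 0.0):
        raise DegenerateInputError(
            "all null pre-scores are zero; normalized score undefined"
        )
    if null_summary == "median":
        denom = float(np.median(np.abs(null)))
    elif null_summary == "signed_mean":
        same_sign = pos if pre > 0 else neg
        ref = same_sign if same_sign.size else null
        denom = float(np.mean(np.abs(ref)))
    else:
        denom = float(np.mean(np.abs(null)))
    return pre / denom, null_mean_pos, null_mean_neg


def _sample_seed(seed: int, sample_id: str) -> int:
    """Per-sample child seed from (cohort seed, sample identity).

    Hashing the identity rather than the position keeps scores invariant
    to sample ordering in the matrix.
    """
    digest = hashlib.sha256(f"{seed}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def score_sample(
    normalized_profile: pd.Series,
    signature: SignatureWeights,
    sample_id: str,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
    null_summary: str = "mean",
) -> ScoreResult:
    """Score one already-median-normalized profile."""
    profile = rank_signature_subset(
        normalized_profile, signature, min_overlap_fraction
    )
    curves = cumulative_curves(profile)
    pre = pre_score(curves)
    sseed = _sample_seed(seed, sample_id)
    null = null_distribution(profile, n_permutations, seed=sseed)
    score, npos, nneg = normalize_score(pre, null, null_summary)
    return ScoreResult(
        sample_id=sample_id,
        pre_score=pre,
        score=score,
        null_mean_pos=npos,
        null_mean_neg=nneg,
        n_genes_used=len(profile.g),
        n_permutations=n_permutations,
        seed=seed,
    )


def score_cohort(
    matrix: ExpressionMatrix,
    signature: SignatureWeights,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP,
    null_summary: str = "mean",
) -> list[ScoreResult]:
    """Median-normalize a cohort once and score every sample.

    Deterministic given the seed; each sample's permutation stream is
    derived from the cohort seed and the sample identifier, so results
    do not depend on column order.
    """
    if matrix.transform_state != LOG2:
        raise ParameterError("score_cohort expects a log2-transformed matrix")
    centered = median_normalize(matrix)
    results = []
    for s in centered.sample_ids:
        try:
            results.append(
                score_sample(
                    centered.values[s],
                    signature,
                    sample_id=str(s),
                    n_permutations=n_permutations,
                    seed=seed,
                    min_overlap_fraction=min_overlap_fraction,
                    null_summary=null_summary,
                )
            )
        except (ParameterError, DegenerateInputError) as exc:
            raise type(exc)(f"sample {s}: {exc}") from exc
    return results
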