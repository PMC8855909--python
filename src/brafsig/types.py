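"""Shared data containers for the signature pipeline.

The pipeline moves four kinds of data between stages: a gene-by-sample
expression matrix with an explicit transform state (linear RSEM-like
values vs. log2), an ordered gene->weight signature, per-sample score
records, and genomic interval records (copy-number segments, gene loci).
Everything tabular is backed by pandas; these classes add the invariants
the stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"

_TRANSFORM_STATES = (LINEAR, LOG2)


class PipelineError(ValueError):
    """Base class for all pipeline validation and computation errors."""


class ParameterError(PipelineError):
    """Invalid user-supplied parameter or specification."""


class FormatError(PipelineError):
    """Malformed input file or table."""


class DegenerateInputError(PipelineError):
    """Input on which the requested statistic is undefined."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a transform-state flag.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, columns are sample
        identifiers. Linear-state values must be nonnegative and finite;
        log2-state values must be finite.
    transform_state
        ``"linear"`` for RSEM-like nonnegative estimates, ``"log2"``
        after log2(x + 1) transformation.
    """

    values: pd.DataFrame
    transform_state: str = LINEAR

    def __post_init__(self) -> None:
        if self.transform_state not in _TRANSFORM_STATES:
            raise ParameterError(
                f"transform_state must be one of {_TRANSFORM_STATES}, "
                f"got {self.transform_state!r}"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene identifiers: {list(dup[:5])}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample identifiers: {list(dup[:5])}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise FormatError("expression matrix contains non-finite values")
        if self.transform_state == LINEAR and arr.size and (arr < 0).any():
            raise FormatError("linear-scale expression values must be >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SignatureWeights:
    """Ordered gene signature with per-gene weights.

    Genes are ordered by ascending p-value of the per-gene logistic fit
    (most significant first); each weight is ``min(-log10(p), 10) / 10``,
    so weights are non-increasing along the list and bounded by 1.
    """

    genes: list[str]
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ParameterError("genes and weights must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("signature genes must be unique")
        if self.weights.size and (
            (self.weights < 0).any() or (self.weights > 1).any()
        ):
            raise ParameterError("signature weights must lie in [0, 1]")

    @property
    def size(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=pd.Index(self.genes, name="gene"),
                         name="weight")


@dataclass
class ScoreResult:
    """Per-sample activity score with its permutation-null summaries."""

    sample_id: str
    pre_score: float
    score: float
    null_mean_pos: float
    null_mean_neg: float
    n_genes_used: int
    n_permutations: int
    seed: Optional[int] = None


def scores_to_frame(results: list[ScoreResult]) -> pd.DataFrame:
    """Tidy table of score results, one row per sample."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "pre_score": [r.pre_score for r in results],
            "score": [r.score for r in results],
            "null_mean_pos": [r.null_mean_pos for r in results],
            "null_mean_neg": [r.null_mean_neg for r in results],
            "n_genes_used": [r.n_genes_used for r in results],
            "n_permutations": [r.n_permutations for r in results],
            "seed": [r.seed for r in results],
        }
    )


@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of a gene, 1-based closed coordinates (SEG style)."""

    chromosome: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not str(self.chromosome):
            raise ParameterError("chromosome must be nonempty")
        if self.start > self.end:
            raise ParameterError(
                f"locus start {self.start} exceeds end {self.end}"
            )


@dataclass(frozen=True)
class CNVSegment:
    """One segmented copy-number record, 1-based closed coordinates."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if not str(self.chromosome):
            raise FormatError("segment chromosome must be nonempty")
        if self.start > self.end:
            raise FormatError(
                f"segment start {self.start} > end {self.end} "
                f"for sample {self.sample_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, locus: GeneLocus) -> bool:
        return (
            str(self.chromosome) == str(locus.chromosome)
            and self.start <= locus.end
            and self.end >= locus.start
        )
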