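"""Gene-amplification calls from segmented copy-number data.

A sample is called amplified (AMP) for a gene when at least one segment
overlapping the gene locus has a log2 copy-number ratio strictly above
``cn_threshold`` and a segment length strictly below
``max_segment_length``; otherwise it is wild type (WT). The defaults —
log2(2.8/2) and 151 Mb — call roughly single-copy gains while rejecting
whole-chromosome-arm events: 2.8 rather than 3.0 copies guards against
tumor-purity dilution of the signal, and the length cap excludes whole
chromosome 7 gains from counting as focal amplification of BRAF or EGFR.

Linear copy numbers are transformed as log2(cn / 2), so diploid maps to
exactly 0; log2-ratio input passes through unchanged. The dialect is
declared by the caller, never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import CNVSegment, GeneLocus, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_CN_THRESHOLD = float(np.log2(2.8 / 2.0))
DEFAULT_MAX_SEGMENT_LENGTH = 151_000_000

AMP = "AMP"
WT = "WT"


@dataclass
class AmplificationConfig:
    gene_locus: GeneLocus
    cn_threshold: float = DEFAULT_CN_THRESHOLD
    max_segment_length: int = DEFAULT_MAX_SEGMENT_LENGTH

    def __post_init__(self) -> None:
        if self.cn_threshold <= 0:
            raise ParameterError("cn_threshold must be > 0")
        if self.max_segment_length <= 0:
            raise ParameterError("max_segment_length must be > 0")


@dataclass
class AmplificationCall:
    sample_id: str
    gene: str
    status: str
    supporting_segment: Optional[CNVSegment] = None

    def __post_init__(self) -> None:
        if self.status == AMP and self.supporting_segment is None:
            raise ParameterError("AMP call requires a supporting segment")


def transform_cn(value: float, dialect: str) -> float:
    """Map a segment value onto the log2 copy-number-ratio scale.

    ``linear_cn`` values are halved and log2-transformed (diploid -> 0);
    ``log2_ratio`` values pass through.
    """
    if dialect == "log2_ratio":
        return float(value)
    if dialect == "linear_cn":
        if value <= 0:
            raise ParameterError(
                f"linear copy number must be > 0, got {value}"
            )
        return float(np.log2(value / 2.0))
    raise ParameterError(f"unknown SEG dialect {dialect!r}")


def call_amplification(
    segments: list[CNVSegment],
    config: AmplificationConfig,
    dialect: str = "linear_cn",
    samples: Optional[list[str]] = None,
) -> list[AmplificationCall]:
    """Per-sample AMP/WT calls for the configured gene locus.

    Both thresholds are strict inequalities: a segment at exactly 2.8
    copies, or exactly 151 Mb long, does not qualify. When several
    overlapping segments qualify, the one with maximal overlap with the
    locus is recorded as the supporting segment. Samples with no segment
    overlapping the locus are called WT with a warning; ``samples``
    optionally fixes the full sample universe (so samples with no
    segments at all still receive a call).
    """
    locus = config.gene_locus
    by_sample: dict[str, list[CNVSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    universe = list(samples) if samples is not None else sorted(by_sample)

    calls = []
    for sample_id in universe:
        overlapping = [
            s for s in by_sample.get(sample_id, []) if s.overlaps(locus)
        ]
        if not overlapping:
            logger.warning(
                "sample %s has no segment overlapping %s; calling WT",
                sample_id, locus.name or locus.chromosome,
            )
            calls.append(AmplificationCall(sample_id, locus.name, WT))
            continue
        qualifying = [
            s for s in overlapping
            if transform_cn(s.value, dialect) > config.cn_threshold
            and s.length < config.max_segment_length
        ]
        if qualifying:
            best = max(
                qualifying,
                key=lambda s: (
                    min(s.end, locus.end) - max(s.start, locus.start),
                    -s.start,
                ),
            )
            calls.append(AmplificationCall(sample_id, locus.name, AMP, best))
        else:
            calls.append(AmplificationCall(sample_id, locus.name, WT))
    return calls


def calls_to_frame(calls: list[AmplificationCall], dialect: str = "linear_cn") -> pd.DataFrame:
    rows = []
    for c in calls:
        seg = c.supporting_segment
        rows.append(
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "status": c.status,
                "chromosome": seg.chromosome if seg else "",
                "start": seg.start if seg else np.nan,
                "end": seg.end if seg else np.nan,
                "log2_ratio": transform_cn(seg.value, dialect) if seg else np.nan,
            }
        )
    return pd.DataFrame(rows)


def group_by_aberration(
    labels: pd.Series,
    scores: pd.Series,
    restrict_to: Optional[list[str]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition scores into (aberrant, non-aberrant) vectors.

    ``labels`` is a boolean (or 0/1, or "AMP"/"WT") series indexed by
    sample; every scored sample must be labeled. ``restrict_to`` limits
    the partition to a background subset first — e.g. BRAF-wildtype
    samples when testing NRAS mutation against the score.
    """
    labels = pd.Series(labels)
    scores = pd.Series(scores)
    if restrict_to is not None:
        scores = scores[scores.index.isin(set(restrict_to))]
    unlabeled = scores.index.difference(labels.index)
    if len(unlabeled):
        raise ParameterError(
            f"{len(unlabeled)} scored sample(s) lack an aberration label, "
            f"e.g. {list(unlabeled[:3])}"
        )
    lab = labels.loc[scores.index]
    if lab.dtype == object:
        aberrant = lab.astype(str).str.upper().isin({"AMP", "MUTANT", "TRUE", "1"})
    else:
        aberrant = lab.astype(bool)
    return (
        scores[aberrant].to_numpy(dtype=float),
        scores[~aberrant].to_numpy(dtype=float),
    )
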