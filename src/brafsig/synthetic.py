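"""Synthetic cohort generators with planted ground truth.

These generators emulate the statistical structure of the real study
inputs — a two-group log2 expression shift in a planted gene set with
age/sex covariates, segment-level copy-number gains over a gene locus,
exponential proportional-hazards survival tied to a score split, and
IC50 values linearly coupled to a score — so every downstream stage can
be tested end-to-end without downloads, against known truth.

Expression is generated log-normally: Normal(baseline_mean, noise_sd)
on the log2 scale, then mapped to the linear scale as ``2**x - 1``
clipped at 0. This mimics the right skew of RSEM estimates while keeping
the planted log2 shift exact after the pipeline's log2(x + 1) transform.

Every generator takes an explicit integer seed and is bit-reproducible;
:func:`spawn_seeds` expands one master seed into independent per-component
child seeds so subsystems stay reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    CNVSegment,
    ExpressionMatrix,
    GeneLocus,
    ParameterError,
    LINEAR,
)


def spawn_seeds(master_seed: int, labels: list[str]) -> dict[str, int]:
    """Deterministically expand one master seed into named child seeds."""
    children = np.random.SeedSequence(master_seed).spawn(len(labels))
    return {
        label: int(child.generate_state(1)[0] % (2**31))
        for label, child in zip(labels, children)
    }


@dataclass
class CohortSpec:
    """Parameters of a two-group expression cohort.

    Defaults describe the reference test condition used throughout:
    5000 genes, 80 samples split evenly into mutant and wildtype, 100
    signal genes shifted up by one log2 unit in mutants, unit per-gene
    noise on a baseline of 8 log2 units (typical of moderately expressed
    RSEM genes).
    """

    n_genes: int = 5000
    n_samples: int = 80
    n_signal_genes: int = 100
    mutant_fraction: float = 0.5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    seed: int = 0
    #: seed of the planted-biology draw (which genes carry the signal).
    #: Defaults to ``seed``; fix it while varying ``seed`` to generate
    #: independent cohorts that share the same underlying signal genes
    #: (train/held-out splits of the same "population").
    signal_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ParameterError("need n_genes >= 1 and n_samples >= 2")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise ParameterError("n_signal_genes must be in [0, n_genes]")
        if not 0 < self.mutant_fraction < 1:
            raise ParameterError("mutant_fraction must lie strictly in (0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")


@dataclass
class SurvivalSpec:
    """Exponential proportional-hazards survival tied to a score split.

    Samples above the score median have their hazard divided by
    ``hazard_ratio`` (high score -> better survival). ``baseline_rate``
    is events per time unit in the low-score group; ``censor_rate`` is
    the rate of an independent exponential censoring process (0 disables
    censoring).
    """

    hazard_ratio: float = 2.0
    baseline_rate: float = 0.01
    censor_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ParameterError("hazard_ratio must be > 0")
        if self.baseline_rate <= 0:
            raise ParameterError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise ParameterError("censor_rate must be >= 0")


@dataclass
class DrugSpec:
    """Linear IC50-on-score model with Gaussian residuals."""

    slope: float = -1.0
    intercept: float = 0.0
    noise_sd: float = 1.0
    drug_name: str = "DRUG_A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class ExpressionCohort:
    """Generated cohort plus the planted ground truth."""

    matrix: ExpressionMatrix
    mutations: pd.DataFrame
    covariates: pd.DataFrame
    signal_genes: list[str] = field(default_factory=list)
    mutant_samples: list[str] = field(default_factory=list)


def gen_expression(spec: CohortSpec) -> ExpressionCohort:
    """Generate a linear-scale expression cohort with a planted signal.

    Mutant-labeled samples have the signal genes shifted upward by
    ``effect_size`` on the log2 scale. Mutants are recorded as MAF-style
    ``p.V600E`` missense rows in BRAF; age ~ Uniform(30, 85) and sex ~
    Bernoulli(0.5) are returned as covariates.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    samples = [f"SAMPLE{i:04d}" for i in range(spec.n_samples)]

    n_mut = int(round(spec.mutant_fraction * spec.n_samples))
    n_mut = min(max(n_mut, 1), spec.n_samples - 1)
    mutant_idx = np.sort(rng.choice(spec.n_samples, size=n_mut, replace=False))
    is_mutant = np.zeros(spec.n_samples, dtype=bool)
    is_mutant[mutant_idx] = True

    sig_seed = spec.seed if spec.signal_seed is None else spec.signal_seed
    sig_rng = np.random.default_rng(sig_seed)
    signal_idx = sig_rng.choice(
        spec.n_genes, size=spec.n_signal_genes, replace=False
    )
    signal_idx = np.sort(signal_idx)

    log2_vals = rng.normal(
        spec.baseline_mean, spec.noise_sd, size=(spec.n_genes, spec.n_samples)
    )
    log2_vals[np.ix_(signal_idx, is_mutant)] += spec.effect_size
    linear = np.clip(np.exp2(log2_vals) - 1.0, 0.0, None)

    matrix = ExpressionMatrix(
        pd.DataFrame(linear, index=genes, columns=samples),
        transform_state=LINEAR,
    )

    maf_rows = []
    for s in np.asarray(samples)[is_mutant]:
        maf_rows.append((s, "BRAF", "p.V600E", "Missense_Mutation"))
    # scatter passenger mutations so the table looks like a real MAF slice
    n_passenger = max(1, spec.n_samples // 3)
    for s in rng.choice(samples, size=n_passenger, replace=False):
        g = genes[int(rng.integers(spec.n_genes))]
        maf_rows.append((s, g, "p.A100T", "Missense_Mutation"))
    mutations = pd.DataFrame(
        maf_rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Hugo_Symbol",
            "HGVSp_Short",
            "Variant_Classification",
        ],
    )

    covariates = pd.DataFrame(
        {
            "sample_id": samples,
            "age": rng.uniform(30.0, 85.0, size=spec.n_samples),
            "sex": rng.integers(0, 2, size=spec.n_samples),
        }
    )

    return ExpressionCohort(
        matrix=matrix,
        mutations=mutations,
        covariates=covariates,
        signal_genes=[genes[i] for i in signal_idx],
        mutant_samples=[samples[i] for i in np.flatnonzero(is_mutant)],
    )


def gen_cnv_segments(
    samples: list[str],
    gene_locus: GeneLocus,
    n_amplified: int,
    copy_number: float = 3.0,
    segment_length: int = 100_000_000,
    seed: int = 0,
) -> tuple[list[CNVSegment], list[str]]:
    """Plant copy-number-gain segments over a gene locus.

    Exactly ``n_amplified`` randomly chosen samples carry a segment of
    the given linear copy number and length centered on the locus; every
    other sample carries a diploid (copy number 2) segment over the same
    region. Returns the segments and the list of amplified sample IDs.
    """
    if n_amplified > len(samples):
        raise ParameterError("n_amplified exceeds the number of samples")
    if segment_length < 1:
        raise ParameterError("segment_length must be >= 1 bp")
    rng = np.random.default_rng(seed)
    amplified = sorted(
        rng.choice(np.asarray(samples, dtype=object), size=n_amplified,
                   replace=False).tolist()
    )
    amplified_set = set(amplified)

    mid = (gene_locus.start + gene_locus.end) // 2
    start = max(1, mid - segment_length // 2)
    end = start + segment_length - 1

    segments = []
    for s in samples:
        cn = copy_number if s in amplified_set else 2.0
        segments.append(
            CNVSegment(
                sample_id=s,
                chromosome=gene_locus.chromosome,
                start=start,
                end=end,
                value=cn,
            )
        )
    return segments, amplified


def gen_survival(scores: pd.Series, spec: SurvivalSpec) -> pd.DataFrame:
    """Simulate overall survival linked to a median split of the scores.

    Event times are exponential with rate ``baseline_rate`` for the
    low-score group and ``baseline_rate / hazard_ratio`` for the
    high-score group; an independent exponential censoring process with
    rate ``censor_rate`` is applied.
    """
    scores = pd.Series(scores)
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ParameterError("scores must be finite")
    rng = np.random.default_rng(spec.seed)
    n = len(scores)
    high = vals > np.median(vals)
    rate = np.where(high, spec.baseline_rate / spec.hazard_ratio,
                    spec.baseline_rate)
    event_time = rng.exponential(1.0 / rate)
    if spec.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [str(s) for s in scores.index],
            "os_time": os_time,
            "os_event": os_event,
            "age": rng.uniform(30.0, 85.0, size=n),
            "sex": rng.integers(0, 2, size=n),
            "high_score_group": high.astype(int),
        }
    )


def gen_response(
    scores: pd.Series,
    p_respond_low: float = 0.6,
    p_respond_high: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary therapy response tied to a median split of the scores.

    Samples at or below the score median respond with probability
    ``p_respond_low``, samples above it with ``p_respond_high`` —
    low pathway activity predicting therapy sensitivity.
    """
    scores = pd.Series(scores)
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ParameterError("scores must be finite")
    for p in (p_respond_low, p_respond_high):
        if not 0 <= p <= 1:
            raise ParameterError("response probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    high = vals > np.median(vals)
    p = np.where(high, p_respond_high, p_respond_low)
    return pd.DataFrame(
        {
            "sample_id": [str(s) for s in scores.index],
            "response": (rng.uniform(size=len(vals)) < p).astype(int),
        }
    )


def gen_drug_response(scores: pd.Series, spec: DrugSpec) -> pd.DataFrame:
    """IC50 = intercept + slope * score + Normal(0, noise_sd)."""
    scores = pd.Series(scores)
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ParameterError("scores must be finite")
    rng = np.random.default_rng(spec.seed)
    ic50 = spec.intercept + spec.slope * vals + rng.normal(
        0.0, spec.noise_sd, size=len(vals)
    )
    return pd.DataFrame(
        {
            "cell_line_id": [str(s) for s in scores.index],
            "drug_name": spec.drug_name,
            "ic50": ic50,
        }
    )
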