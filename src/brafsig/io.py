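"""Readers and writers for the tabular formats the pipeline touches.

All files are plain tab-delimited text (optionally gzip-compressed via
pandas' transparent handling). Formats:

* expression: genes as rows, first column gene IDs, header row of sample
  IDs (TCGA/Firehose RSEM convention);
* mutations: MAF-minimal with columns ``Tumor_Sample_Barcode``,
  ``Hugo_Symbol``, ``HGVSp_Short``, ``Variant_Classification``;
* copy-number segments: SEG with columns ``Sample``, ``Chromosome``,
  ``Start``, ``End``, ``Value`` (1-based closed intervals);
* clinical: ``sample_id``, ``os_time``, ``os_event``, ``age``, ``sex``;
* drug response: ``cell_line_id``, ``drug_name``, ``ic50``;
* therapy response: ``sample_id``, ``response`` (0/1).

Unknown extra columns are ignored with a warning; missing mandatory
columns raise :class:`~brafsig.types.FormatError` naming the column.
The SEG value dialect (linear copy number vs. log2 ratio) is declared by
the caller, never sniffed, because the amplification transform depends
on it and silent misdetection would corrupt calls.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    CNVSegment,
    ExpressionMatrix,
    FormatError,
    ParameterError,
    LINEAR,
)

logger = logging.getLogger(__name__)

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "HGVSp_Short",
    "Variant_Classification",
]
SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Value"]
CLINICAL_COLUMNS = ["sample_id", "os_time", "os_event", "age", "sex"]
DRUG_COLUMNS = ["cell_line_id", "drug_name", "ic50"]
RESPONSE_COLUMNS = ["sample_id", "response"]

SEG_DIALECTS = ("linear_cn", "log2_ratio")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s table: ignoring extra column(s) %s", what, extra)
    return df[required]


def read_expression(path, transform_state: str = LINEAR) -> ExpressionMatrix:
    """Read a gene-by-sample expression TSV.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean expression (the common TCGA convention — deterministic, favors
    the better-measured isoform summary).
    """
    header = pd.read_csv(path, sep="\t", header=None, nrows=1, comment="#",
                         dtype=str).iloc[0]
    sample_ids = header[1:]
    if sample_ids.duplicated().any():
        dup = sample_ids[sample_ids.duplicated()].unique()
        raise FormatError(f"duplicate sample identifiers in header: {list(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = None
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric expression value at gene {df.index[i]!r} "
                f"(row {i + 1}), sample {col!r} (column {j + 1})"
            )
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError("expression matrix contains missing values")
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        logger.warning("collapsed duplicate gene rows (kept highest mean)")
    return ExpressionMatrix(df.astype(float), transform_state=transform_state)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_mutations(path) -> pd.DataFrame:
    """Read a MAF-minimal mutation table."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df = _require_columns(df, MAF_COLUMNS, "mutation")
    missense = df["Variant_Classification"].str.lower() == "missense_mutation"
    empty = df["HGVSp_Short"].isna() | (df["HGVSp_Short"].str.strip() == "")
    if (missense & empty).any():
        raise FormatError("missense rows must carry a nonempty HGVSp_Short")
    return df.reset_index(drop=True)


def write_mutations(table: pd.DataFrame, path) -> None:
    _require_columns(table, MAF_COLUMNS, "mutation").to_csv(
        path, sep="\t", index=False
    )


def read_segments(path, dialect: str) -> list[CNVSegment]:
    """Read a SEG table; ``dialect`` declares the value scale."""
    if dialect not in SEG_DIALECTS:
        raise ParameterError(f"SEG dialect must be one of {SEG_DIALECTS}")
    df = pd.read_csv(path, sep="\t", comment="#")
    df = _require_columns(df, SEG_COLUMNS, "segment")
    segments = []
    for row in df.itertuples(index=False):
        segments.append(
            CNVSegment(
                sample_id=str(row.Sample),
                chromosome=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                value=float(row.Value),
            )
        )
    return segments


def write_segments(segments: list[CNVSegment], path) -> None:
    pd.DataFrame(
        {
            "Sample": [s.sample_id for s in segments],
            "Chromosome": [s.chromosome for s in segments],
            "Start": [s.start for s in segments],
            "End": [s.end for s in segments],
            "Value": [s.value for s in segments],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df = _require_columns(df, CLINICAL_COLUMNS, "clinical")
    df = df.astype(
        {"sample_id": str, "os_time": float, "os_event": int, "age": float,
         "sex": int}
    )
    if (df["os_time"] < 0).any():
        raise FormatError("os_time must be >= 0")
    if not df["os_event"].isin([0, 1]).all():
        raise FormatError("os_event must be 0 (censored) or 1 (death)")
    return df.reset_index(drop=True)


def write_clinical(table: pd.DataFrame, path) -> None:
    _require_columns(table, CLINICAL_COLUMNS, "clinical").to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_drug(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df = _require_columns(df, DRUG_COLUMNS, "drug response")
    df = df.astype({"cell_line_id": str, "drug_name": str, "ic50": float})
    if not np.isfinite(df["ic50"]).all():
        raise FormatError("ic50 values must be finite")
    return df.reset_index(drop=True)


def write_drug(table: pd.DataFrame, path) -> None:
    _require_columns(table, DRUG_COLUMNS, "drug response").to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_response(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df = _require_columns(df, RESPONSE_COLUMNS, "therapy response")
    df = df.astype({"sample_id": str, "response": int})
    if not df["response"].isin([0, 1]).all():
        raise FormatError("response must be binary 0/1")
    return df.reset_index(drop=True)


def write_response(table: pd.DataFrame, path) -> None:
    _require_columns(table, RESPONSE_COLUMNS, "therapy response").to_csv(
        path, sep="\t", index=False
    )


def read_signature(path):
    """Read a two-column (gene, weight) signature TSV written by
    :func:`write_signature`; header comments are skipped."""
    from .types import SignatureWeights

    df = pd.read_csv(path, sep="\t", comment="#")
    df = _require_columns(df, ["gene", "weight"], "signature")
    return SignatureWeights(
        genes=[str(g) for g in df["gene"]],
        weights=df["weight"].to_numpy(dtype=float),
    )


def write_signature(signature, path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("gene\tweight\n")
        for g, w in zip(signature.genes, signature.weights):
            fh.write(f"{g}\t{w:.17g}\n")
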