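"""Readers and writers for every external representation the pipeline touches.

Everything on disk is plain tab-separated text. Expression tables are genes
in rows, samples in columns; pair-indicator tables use ``GENEA|GENEB`` row
ids; clinical tables carry the Table-1 style covariates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CLINICAL_COVARIATES,
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    PairIndicatorMatrix,
    RiskProfile,
    SignatureModel,
    UNKNOWN,
)

log = logging.getLogger("ferropair")


def read_expression(path, condition: pd.Series | dict | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    First column holds gene ids, the header row sample ids. Duplicate gene
    rows are collapsed by their mean (logged); duplicate sample columns are
    an error. ``condition`` maps sample id -> tumor/normal; when omitted,
    a ``condition`` row inside the file (if present) is used.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)

    cond = None
    if "condition" in df.index:
        cond = df.loc["condition"].astype(str)
        df = df.drop(index="condition")
    if condition is not None:
        cond = pd.Series(condition).astype(str)
    if cond is None:
        raise ValueError(
            f"{path} has no 'condition' row and no condition mapping was given"
        )

    # locate non-numeric cells before coercion so the error can name them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna()
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"non-numeric expression value at gene {gene!r}, sample {sample!r} in {path}"
        )
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        log.warning("collapsing %d duplicate gene rows by mean", n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric, cond)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write an expression matrix with its condition labels as a header row."""
    out = expr.values.copy()
    out.index.name = "gene_id"
    cond_row = pd.DataFrame(
        [expr.condition.values], index=pd.Index(["condition"], name="gene_id"),
        columns=out.columns,
    )
    pd.concat([cond_row, out]).to_csv(path, sep="\t")


def read_gtf_biotypes(path) -> GeneAnnotation:
    """Extract gene_id -> biotype from ``gene`` feature lines of a GTF.

    Accepts both the Ensembl ``gene_biotype`` and GENCODE ``gene_type``
    attribute dialects. Coordinates are ignored (never used downstream).
    Genes lacking a biotype attribute are skipped with a warning.
    """
    biotypes: dict[str, str] = {}
    symbols: dict[str, str] = {}
    n_gene_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line (need 9 fields): {line[:80]!r}")
            if fields[2] != "gene":
                continue
            n_gene_lines += 1
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                log.warning("gene feature without gene_id skipped")
                continue
            biotype = attrs.get("gene_biotype", attrs.get("gene_type"))
            if biotype is None:
                log.warning("gene %s has no biotype attribute; skipped", gene_id)
                continue
            biotypes[gene_id] = biotype
            if "gene_name" in attrs:
                symbols[gene_id] = attrs["gene_name"]
    if n_gene_lines == 0:
        raise ValueError(f"no 'gene' features found in {path}")
    return GeneAnnotation(
        biotype=pd.Series(biotypes, name="biotype"),
        symbol=pd.Series(symbols, name="symbol") if symbols else None,
    )


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_biotype_table(path) -> GeneAnnotation:
    """Two-column (gene_id <tab> biotype) alternative to a GTF."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "biotype"])
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in biotype table")
    return GeneAnnotation(biotype=df.set_index("gene_id")["biotype"])


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.biotype.rename_axis("gene_id").to_csv(path, sep="\t", header=False)


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """One gene symbol/id per line; blank lines and '#' comments ignored."""
    members = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                members.append(token)
    return GeneSet.from_iterable(name or Path(path).stem, dict.fromkeys(members))


def write_gene_list(gs: GeneSet, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gs))


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV, applying the follow-up validity filter.

    Rows with missing or non-positive follow-up time, or missing event
    status, are dropped and counted; duplicate sample ids keep the first
    occurrence. Missing covariate categories become ``"unknown"``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    sample_col = df.columns[0]
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} lacks required column {col!r}")
    n_in = len(df)
    dup = df[sample_col].duplicated()
    if dup.any():
        log.warning("dropping %d duplicate clinical rows (keeping first)", int(dup.sum()))
        df = df[~dup]
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    valid = time.notna() & (time > 0) & event.isin((0, 1))
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.warning(
            "dropped %d/%d clinical rows with invalid follow-up or event status",
            n_dropped, n_in,
        )
    df = df[valid].copy()
    df["time"] = time[valid]
    df["event"] = event[valid].astype(int)
    for col in CLINICAL_COVARIATES:
        if col in df.columns:
            df[col] = df[col].fillna(UNKNOWN)
    df = df.set_index(sample_col)
    df.index.name = "sample_id"
    table = ClinicalTable(df)
    table.n_dropped = n_dropped  # type: ignore[attr-defined]
    return table


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_pair_matrix(path) -> PairIndicatorMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairIndicatorMatrix(df.astype(np.int8))


def read_signature(path) -> SignatureModel:
    return SignatureModel.from_frame(pd.read_csv(path, sep="\t"))


def read_risk_profile(path) -> RiskProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RiskProfile(scores=df["score"], cutoff=float(df["cutoff"].iloc[0]))


def write_table(obj, path) -> None:
    """Write any of the pipeline's tabular results as deterministic TSV.

    Dispatches on type; plain DataFrames/Series are written as-is. Each
    output round-trips through the matching reader.
    """
    if isinstance(obj, PairIndicatorMatrix):
        out = obj.indicators.copy()
        out.index.name = "pair_id"
        out.to_csv(path, sep="\t")
    elif isinstance(obj, SignatureModel):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, RiskProfile):
        obj.to_frame().to_csv(path, sep="\t")
    elif isinstance(obj, ClinicalTable):
        write_clinical(obj, path)
    elif isinstance(obj, ExpressionMatrix):
        write_expression(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=not isinstance(obj.index, pd.RangeIndex))
    elif isinstance(obj, pd.Series):
        obj.to_csv(path, sep="\t", header=True)
    else:
        raise TypeError(f"no TSV writer for {type(obj).__name__}")
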