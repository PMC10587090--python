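"""Readers and writers for the tab-delimited file formats of the pipeline.

All files are UTF-8 tab-delimited with a header row and "." as the decimal
point. Expression matrices have gene symbols in the first column and sample
IDs in the header; centroid files are Parker-style (gene rows, one column per
subtype); partitions are two columns (gene, cluster ID or NA); clinical
tables use the exact column set of :data:`~pam50stab.datatypes.CLINICAL_COLUMNS`.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

from .datatypes import (
    CLINICAL_COLUMNS,
    LEGACY_GENE_ALIASES,
    PAM50_GENES,
    SUBTYPES,
    CentroidMatrix,
    ClinicalTable,
    ExpressionMatrix,
    FormatError,
    GeneSetPartition,
    ValidationError,
)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample FPKM matrix.

    Non-numeric or negative cells raise a :class:`ValidationError` naming the
    offending gene and sample.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # noqa: BLE001 - wrap parser failures uniformly
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.columns.empty:
        raise FormatError(f"{path}: missing sample header")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"{path}: non-numeric FPKM at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_centroid_matrix(
    path: str | Path,
    scale_tag: str = "centered_log",
    strict: bool = False,
    apply_aliases: bool = True,
) -> CentroidMatrix:
    """Read a Parker-layout centroid file (gene rows, subtype columns).

    Legacy gene symbols (e.g. CDCA1 for NUF2) are mapped to current names
    unless ``apply_aliases`` is off. Genes outside the canonical 50-gene list
    are retained with a warning, or rejected under ``strict``.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse centroid matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    missing = [s for s in SUBTYPES if s not in df.columns]
    if missing and scale_tag == "centered_log":
        raise FormatError(f"{path}: missing subtype columns {missing}")
    cols = [s for s in SUBTYPES if s in df.columns]
    df = df[cols]
    if apply_aliases:
        df.index = [LEGACY_GENE_ALIASES.get(g, g) for g in df.index]
    if len(df.index) > 50:
        raise ValidationError(f"{path}: {len(df.index)} genes; at most 50 expected")
    foreign = [g for g in df.index if g not in PAM50_GENES]
    if foreign:
        if strict:
            raise ValidationError(f"{path}: genes outside the PAM50 list: {foreign}")
        warnings.warn(f"{path}: genes outside the PAM50 list retained: {foreign}",
                      stacklevel=2)
    return CentroidMatrix(df.T.astype(float), scale_tag=scale_tag)


def write_centroid_matrix(centroids: CentroidMatrix, path: str | Path) -> None:
    centroids.values.T.to_csv(path, sep="\t", index_label="gene")


def read_gene_set_partition(path: str | Path) -> GeneSetPartition:
    """Read a two-column gene → cluster-ID file; "NA" marks unassigned genes."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse partition {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (gene, cluster)")
    genes, clusters = df.iloc[:, 0], df.iloc[:, 1]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValidationError(f"{path}: gene listed twice: {dup!r}")
    assignment: dict[str, int | None] = {}
    for g, c in zip(genes, clusters):
        if c in ("NA", "", "NaN", "nan"):
            assignment[g] = None
        else:
            try:
                assignment[g] = int(c)
            except ValueError as exc:
                raise ValidationError(f"{path}: bad cluster ID {c!r} for gene {g!r}") from exc
    return GeneSetPartition(assignment)


def write_gene_set_partition(partition: GeneSetPartition, path: str | Path) -> None:
    rows = [(g, "NA" if c is None else str(c)) for g, c in partition.assignment.items()]
    pd.DataFrame(rows, columns=["gene", "cluster"]).to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={"sample_id": str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse clinical table {path}: {exc}") from exc
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing clinical columns {missing}")
    df["endocrine_treated"] = df["endocrine_treated"].astype(int).astype(bool)
    return ClinicalTable(df[list(CLINICAL_COLUMNS)])


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    df = clinical.data.copy()
    df["endocrine_treated"] = df["endocrine_treated"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def _data_path(name: str):
    return resources.files("pam50stab.data").joinpath(name)


def load_default_centroids() -> CentroidMatrix:
    """Synthetic Parker-style PAM50 centroid fixture (centered-log scale).

    A stand-in for the Parker et al. centroid file: 50 genes x 5 subtypes
    constructed from gene-set-level subtype prototypes that reproduce the
    qualitative inter-centroid correlation structure of PAM50 (see
    docs/methods.md). It is synthetic, not the published centroid values.
    """
    with resources.as_file(_data_path("synthetic_pam50_centroids.tsv")) as p:
        return read_centroid_matrix(p)


def load_default_partition() -> GeneSetPartition:
    """The seven-core-gene-set PAM50 partition used by the perturbation sweep."""
    with resources.as_file(_data_path("pam50_gene_sets.tsv")) as p:
        return read_gene_set_partition(p)
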