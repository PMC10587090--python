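"""Shared domain types for PAM50 subtype-stability analysis.

The five intrinsic subtypes of breast cancer (Basal, HER2E, LumA, LumB,
Normal) are represented as plain strings drawn from :data:`SUBTYPES`; the
fixed alphabetical ordering of that tuple is the documented deterministic
tie-break order used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five PAM50 intrinsic subtypes, in the fixed (alphabetical) tie-break order.
SUBTYPES: tuple[str, ...] = ("Basal", "HER2E", "LumA", "LumB", "Normal")

#: Clinical subgroups defined by ER/PR/HER2 status.
SUBGROUPS: tuple[str, ...] = ("TNBC", "ERnHER2p", "ERpHER2p", "ERpHER2n", "unclassified")

#: Canonical 50-gene PAM50 signature (current HGNC symbols).
PAM50_GENES: tuple[str, ...] = (
    "ACTR3B", "ANLN", "BAG1", "BCL2", "BIRC5", "BLVRA", "CCNB1", "CCNE1",
    "CDC20", "CDC6", "CDH3", "CENPF", "CEP55", "CXXC5", "EGFR", "ERBB2",
    "ESR1", "EXO1", "FGFR4", "FOXA1", "FOXC1", "GPR160", "GRB7", "KIF2C",
    "KRT14", "KRT17", "KRT5", "MAPT", "MDM2", "MELK", "MIA", "MKI67",
    "MLPH", "MMP11", "MYBL2", "MYC", "NAT1", "NDC80", "NUF2", "ORC6",
    "PGR", "PHGDH", "PTTG1", "RRM2", "SFRP1", "SLC39A6", "TMEM45B", "TYMS",
    "UBE2C", "UBE2T",
)

#: Legacy symbols used in older centroid files mapped to current HGNC names.
LEGACY_GENE_ALIASES: dict[str, str] = {
    "CDCA1": "NUF2",
    "KNTC2": "NDC80",
    "ORC6L": "ORC6",
}

#: Offset added to FPKM before log2 transformation, applied uniformly.
LOG2_OFFSET: float = 0.1


class FormatError(ValueError):
    """A file does not conform to the expected tab-delimited layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class DegenerateProfileError(ValueError):
    """A sample's (centered) profile is constant: rank correlation undefined."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample FPKM matrix (linear scale, values >= 0)."""

    values: pd.DataFrame  # index = gene symbols, columns = sample IDs

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = sorted(v.index[v.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene symbols: {dups}")
        if v.columns.has_duplicates:
            dups = sorted(v.columns[v.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample IDs: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite FPKM at gene {v.index[g]!r}, sample {v.columns[s]!r}")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative FPKM {arr[g, s]} at gene {v.index[g]!r}, sample {v.columns[s]!r}")
        self.values.index.name = "gene"
        self.values.columns.name = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from expression matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)])

    def log2(self) -> pd.DataFrame:
        """log2(FPKM + 0.1) as a genes x samples DataFrame."""
        return np.log2(self.values + LOG2_OFFSET)


@dataclass
class CentroidMatrix:
    """Subtype-by-gene centroid values.

    ``scale_tag`` distinguishes Parker-style centered-log centroids from
    raw-FPKM refined (K0) centroids. Centered-log centroids must carry all
    five subtype rows; FPKM centroids may carry fewer (small subtypes can be
    dropped at construction).
    """

    values: pd.DataFrame  # index = subtypes, columns = gene symbols
    scale_tag: str = "centered_log"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("centered_log", "fpkm"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        bad = [s for s in self.values.index if s not in SUBTYPES]
        if bad:
            raise ValidationError(f"unknown subtype rows: {bad}")
        if self.scale_tag == "centered_log" and set(self.values.index) != set(SUBTYPES):
            raise ValidationError("centered-log centroids require all five subtype rows")
        if self.values.isna().any().any():
            raise ValidationError("centroid matrix contains missing values")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate genes in centroid matrix")
        if self.scale_tag == "fpkm" and (self.values.to_numpy() < 0).any():
            raise ValidationError("FPKM-scale centroids must be non-negative")
        # keep a fixed subtype row order
        order = [s for s in SUBTYPES if s in self.values.index]
        self.values = self.values.loc[order]

    @property
    def subtypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "CentroidMatrix":
        return CentroidMatrix(self.values[list(genes)], scale_tag=self.scale_tag)


CLINICAL_COLUMNS: tuple[str, ...] = (
    "sample_id", "er_status", "pr_status", "her2_status", "nodal_status",
    "endocrine_treated", "age_at_diagnosis", "tumor_size", "histology",
    "os_time", "os_event", "drfi_time", "drfi_event",
)

_MARKER_LEVELS = {"positive", "negative", "unknown"}


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation with survival endpoints (times in days)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in clinical table")
        for col in ("er_status", "pr_status", "her2_status"):
            bad = set(df[col].unique()) - _MARKER_LEVELS
            if bad:
                raise ValidationError(f"invalid {col} values: {sorted(bad)}")
        bad = set(df["nodal_status"].unique()) - {"positive", "negative", "unknown"}
        if bad:
            raise ValidationError(f"invalid nodal_status values: {sorted(bad)}")
        bad = set(df["histology"].unique()) - {"lobular", "other", "unknown"}
        if bad:
            raise ValidationError(f"invalid histology values: {sorted(bad)}")
        for col in ("os_time", "drfi_time"):
            if (df[col].to_numpy(dtype=float) < 0).any():
                raise ValidationError(f"negative {col}")
        for col in ("os_event", "drfi_event"):
            if not set(np.unique(df[col].to_numpy(dtype=int))) <= {0, 1}:
                raise ValidationError(f"{col} must be 0/1")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("sample_id")


def derive_clinical_subgroup(er: str, pr: str, her2: str) -> str:
    """Map ER/PR/HER2 status to one of the four clinical subgroups.

    TNBC requires all three markers negative; PR enters only that rule.
    Any unknown among the markers required by a rule yields ``unclassified``,
    as does the ER-/PR+/HER2- combination, which matches no named subgroup.
    """
    if er == "negative" and pr == "negative" and her2 == "negative":
        return "TNBC"
    if er == "negative" and her2 == "positive":
        return "ERnHER2p"
    if er == "positive" and her2 == "positive":
        return "ERpHER2p"
    if er == "positive" and her2 == "negative":
        return "ERpHER2n"
    return "unclassified"


def clinical_subgroups(clinical: ClinicalTable) -> pd.Series:
    """Per-sample clinical subgroup, indexed by sample_id."""
    df = clinical.data
    out = [
        derive_clinical_subgroup(er, pr, h2)
        for er, pr, h2 in zip(df["er_status"], df["pr_status"], df["her2_status"])
    ]
    return pd.Series(out, index=df["sample_id"].to_numpy(), name="subgroup")


@dataclass
class GeneSetPartition:
    """Assignment of genes to co-expression clusters 1..K, or unassigned (None).

    Unassigned genes are retained in full-gene centroid computations but are
    excluded from the leave-one-set-out sweep's background gene universe.
    """

    assignment: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = sorted({c for c in self.assignment.values() if c is not None})
        if ids and ids != list(range(1, len(ids) + 1)):
            raise ValidationError(f"cluster IDs must be contiguous from 1, got {ids}")

    @property
    def cluster_ids(self) -> list[int]:
        return sorted({c for c in self.assignment.values() if c is not None})

    def genes_in(self, cluster_id: int) -> list[str]:
        genes = [g for g, c in self.assignment.items() if c == cluster_id]
        if not genes:
            raise ValidationError(f"no such gene set: {cluster_id}")
        return genes

    @property
    def unassigned(self) -> list[str]:
        return [g for g, c in self.assignment.items() if c is None]

    @property
    def assigned_genes(self) -> list[str]:
        return [g for g, c in self.assignment.items() if c is not None]

    def background_genes(self, include_unassigned: bool = False) -> list[str]:
        """Gene universe for the perturbation sweep (union of the core sets)."""
        if include_unassigned:
            return list(self.assignment)
        return self.assigned_genes
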