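"""Refined single-sample classification from perturbation-stable (K0) tumors.

Tumors that never switch subtype under any single-gene-set exclusion are
treated as core cases of their subtype within a clinical subgroup. Their
mean FPKM per gene defines new subgroup-specific centroids (PAM50_K0), and
every tumor is then reclassified in single-sample mode: Spearman correlation
of its raw FPKM profile against each K0 centroid, with no offset, no log
transformation, and no gene centering. Because the classification is purely
rank-based, it is invariant to any strictly increasing transform of a
sample's profile — the property that removes the fragile centering step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import EnsembleClassification, _majority_call  # shared tie-break
from .datatypes import (
    SUBTYPES,
    CentroidMatrix,
    ExpressionMatrix,
    ValidationError,
)


@dataclass
class K0CentroidMatrix:
    """FPKM-scale centroids built from K0 tumors, with provenance counts."""

    centroids: CentroidMatrix            # scale_tag == "fpkm"
    subgroup: str | None
    k0_counts: dict[str, int]            # contributing K0 samples per subtype

    @property
    def subtypes(self) -> list[str]:
        return self.centroids.subtypes


def build_k0_centroids(
    expr: ExpressionMatrix,
    cls: EnsembleClassification,
    k0_flags: pd.Series,
    subgroups: pd.Series | None = None,
    subgroup_filter: str | None = None,
    min_k0_per_subtype: int = 5,
) -> K0CentroidMatrix:
    """Mean FPKM per (subtype, gene) over K0 tumors of the chosen subgroup.

    Subtypes with fewer than ``min_k0_per_subtype`` contributing K0 samples
    are dropped with a warning (set the threshold to 1 to keep every subtype
    that has any K0 representative).
    """
    calls = cls.calls()
    k0_samples = k0_flags.index[k0_flags.astype(bool)]
    k0_samples = k0_samples.intersection(calls.index)
    if subgroup_filter is not None:
        if subgroups is None:
            raise ValidationError("subgroup_filter requires a subgroups series")
        in_group = subgroups.index[subgroups == subgroup_filter]
        k0_samples = k0_samples.intersection(in_group)
    k0_samples = [s for s in k0_samples if s in expr.values.columns]
    if not k0_samples:
        raise ValidationError(
            f"no K0 samples available in subgroup {subgroup_filter!r}")
    rows, counts = {}, {}
    for st in SUBTYPES:
        members = [s for s in k0_samples if calls[s] == st]
        counts[st] = len(members)
        if len(members) >= min_k0_per_subtype:
            rows[st] = expr.values[members].mean(axis=1)
        elif members:
            warnings.warn(
                f"subtype {st}: only {len(members)} K0 samples "
                f"(< {min_k0_per_subtype}); centroid dropped", stacklevel=2)
    if not rows:
        raise ValidationError("no subtype reached min_k0_per_subtype")
    values = pd.DataFrame(rows).T
    centroids = CentroidMatrix(values, scale_tag="fpkm")
    return K0CentroidMatrix(centroids=centroids, subgroup=subgroup_filter,
                            k0_counts=counts)


def classify_k0(
    expr: ExpressionMatrix,
    k0_centroids: K0CentroidMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Single-sample Spearman classification against the K0 centroids.

    Raw FPKM profiles are rank-correlated with each available K0 centroid;
    the argmax wins with no correlation cut-off, ties broken as in the
    ensemble classifier. Returns a table (``pam50_k0`` plus per-subtype
    correlations) and the list of samples excluded for constant (degenerate)
    profiles.
    """
    cent = k0_centroids.centroids
    genes = [g for g in cent.genes if g in expr.values.index]
    if len(genes) < 3:
        raise ValidationError(f"only {len(genes)} genes shared; need >= 3")
    subtypes = cent.subtypes
    C = cent.values[genes].to_numpy()
    cr = rankdata(C, axis=1).astype(float)
    cr -= cr.mean(axis=1, keepdims=True)
    cnorm = np.sqrt((cr ** 2).sum(axis=1, keepdims=True))
    if (cnorm == 0).any():
        flat = [subtypes[i] for i in np.where(cnorm[:, 0] == 0)[0]]
        raise ValidationError(f"constant K0 centroid rows: {flat}")
    cz = cr / cnorm

    X = expr.values.loc[genes].to_numpy()
    sr = rankdata(X, axis=0)
    sr -= sr.mean(axis=0, keepdims=True)
    snorm = np.sqrt((sr ** 2).sum(axis=0, keepdims=True))
    degenerate = snorm[0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sz = np.where(snorm > 0, sr / snorm, np.nan)
    corr = cz @ sz  # available subtypes x samples

    excluded = [s for s, d in zip(expr.samples, degenerate) if d]
    if excluded:
        warnings.warn(f"excluding degenerate FPKM profiles: {excluded}",
                      stacklevel=2)
    rows, keep = [], []
    # fill the five-subtype correlation frame; unavailable subtypes stay NaN
    for j, sample in enumerate(expr.samples):
        if degenerate[j]:
            continue
        full = np.full(len(SUBTYPES), -np.inf)
        row = {}
        for i, st in enumerate(subtypes):
            full[SUBTYPES.index(st)] = corr[i, j]
            row[f"corr_{st}"] = corr[i, j]
        votes = (full == full.max()).astype(int)
        call = _majority_call(votes, np.where(np.isfinite(full), full, -np.inf),
                              sample)
        row["pam50_k0"] = call
        rows.append(row)
        keep.append(sample)
    cols = ["pam50_k0"] + [f"corr_{s}" for s in subtypes]
    table = pd.DataFrame(rows, index=pd.Index(keep, name="sample_id"),
                         columns=cols)
    return table, excluded


def transition_table(
    cls: EnsembleClassification,
    k0_calls: pd.DataFrame,
) -> pd.DataFrame:
    """5x5 PAM50_NC -> PAM50_K0 counts; the diagonal is unchanged calls."""
    common = cls.table.index.intersection(k0_calls.index)
    tab = pd.crosstab(cls.table.loc[common, "pam50_nc"],
                      k0_calls.loc[common, "pam50_k0"])
    return tab.reindex(index=SUBTYPES, columns=SUBTYPES, fill_value=0)
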