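"""Leave-one-gene-set-out centroid perturbation of the NC classifier.

One co-expression gene set at a time is removed from the centroid matrix,
the reference-set centering vectors, and the expression matrix; every sample
is reclassified once per reference set on the reduced gene universe. A
sample switches subtype for a perturbation when its original PAM50_NC
subtype is observed in at most half of the perturbed runs. Samples that
never switch under any single-set exclusion are the K0 (perturbation-stable)
cases.

The background gene universe of the sweep is the union of the core gene
sets: genes left unassigned by the partition take no part in the sweep
(configurable for sensitivity analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import EnsembleClassification, ReferenceSetCollection, classify_ensemble
from .datatypes import (
    SUBTYPES,
    CentroidMatrix,
    ExpressionMatrix,
    GeneSetPartition,
    ValidationError,
)

RECORD_COLUMNS = (
    "sample_id", "gene_set_id", "pam50_perturb", "switch", "corr_delta",
    "matches_2nd",
) + tuple(f"votes_{s}" for s in SUBTYPES)


def exclude_gene_set(
    centroids: CentroidMatrix,
    refsets: ReferenceSetCollection,
    expr: ExpressionMatrix,
    partition: GeneSetPartition,
    gene_set_id: int | None,
    include_unassigned: bool = False,
) -> tuple[CentroidMatrix, ReferenceSetCollection, ExpressionMatrix]:
    """Restrict centroids, centering vectors, and expression to the reduced universe.

    ``gene_set_id=None`` is the identity perturbation (background universe,
    nothing excluded). All three structures share the identical remaining
    gene list, in centroid gene order.
    """
    background = set(partition.background_genes(include_unassigned))
    if gene_set_id is None:
        removed: set[str] = set()
    else:
        removed = set(partition.genes_in(gene_set_id))
    avail = set(expr.genes) & set(refsets.genes)
    keep = [g for g in centroids.genes
            if g in background and g in avail and g not in removed]
    if len(keep) < 3:
        raise ValidationError(
            f"excluding gene set {gene_set_id} leaves {len(keep)} genes; need >= 3")
    return (centroids.subset_genes(keep),
            refsets.subset_genes(keep),
            expr.subset_genes(keep))


def perturb_classify(
    expr: ExpressionMatrix,
    refsets: ReferenceSetCollection,
    centroids: CentroidMatrix,
    partition: GeneSetPartition,
    gene_set_id: int | None,
    include_unassigned: bool = False,
) -> EnsembleClassification:
    """Ensemble NC classification on the reduced gene universe."""
    red_c, red_r, red_e = exclude_gene_set(
        centroids, refsets, expr, partition, gene_set_id, include_unassigned)
    return classify_ensemble(red_e, red_r, red_c)


def call_switch(vote_counts: dict[str, int] | pd.Series, pam50_nc: str,
                n_sets: int) -> bool:
    """Switch rule: the original subtype appears in <= 50% of perturbed runs."""
    votes = int(vote_counts[pam50_nc]) if pam50_nc in vote_counts else 0
    total = int(sum(vote_counts.values() if isinstance(vote_counts, dict)
                    else vote_counts))
    if total != n_sets:
        raise ValidationError(f"vote counts sum to {total}, expected {n_sets}")
    return 2 * votes <= n_sets


def perturbation_sweep(
    expr: ExpressionMatrix,
    refsets: ReferenceSetCollection,
    centroids: CentroidMatrix,
    partition: GeneSetPartition,
    cls: EnsembleClassification,
    include_unassigned: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Run every single-set exclusion and aggregate switch and K0 calls.

    ``cls`` must be the ensemble classification computed on the unreduced
    background gene universe (the identity perturbation), so that the
    identity sweep is exactly stable. Returns one record per
    sample x gene set and a per-sample boolean K0 flag (never switched).
    ``corr_delta`` is the mean perturbed correlation to the perturbed call
    minus the mean unperturbed correlation to PAM50_NC (positive = the
    perturbed call correlates better).
    """
    records = []
    base = cls.table
    for gene_set_id in partition.cluster_ids:
        pcls = perturb_classify(expr, refsets, centroids, partition,
                                gene_set_id, include_unassigned)
        common = base.index.intersection(pcls.table.index)
        pt = pcls.table.loc[common]
        bt = base.loc[common]
        for sample in common:
            nc = bt.at[sample, "pam50_nc"]
            second = bt.at[sample, "pam50_nc_2nd"]
            votes = {s: int(pt.at[sample, f"votes_{s}"]) for s in SUBTYPES}
            perturb_call = pt.at[sample, "pam50_nc"]
            switch = call_switch(votes, nc, pcls.n_sets)
            corr_delta = (pt.at[sample, f"corr_{perturb_call}"]
                          - bt.at[sample, f"corr_{nc}"])
            matches_2nd = (perturb_call == second) if (switch and second in SUBTYPES) \
                else pd.NA
            rec = {"sample_id": sample, "gene_set_id": gene_set_id,
                   "pam50_perturb": perturb_call, "switch": switch,
                   "corr_delta": corr_delta, "matches_2nd": matches_2nd}
            rec.update({f"votes_{s}": votes[s] for s in SUBTYPES})
            records.append(rec)
    records_df = pd.DataFrame(records, columns=list(RECORD_COLUMNS))
    k0 = (~records_df.groupby("sample_id")["switch"].any()).rename("k0")
    k0 = k0.reindex(base.index, fill_value=False)
    return records_df, k0


def switch_summary(
    records: pd.DataFrame,
    cls: EnsembleClassification,
    grouping: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Aggregate switch proportions and second-best concordance.

    Returns tables of the switch proportion per (subgroup, PAM50_NC, gene
    set) with denominators, the distribution of perturbed calls among
    switchers, and the proportion of switchers whose perturbed call equals
    their PAM50_NC_2nd. Empty strata report NaN with n=0.
    """
    df = records.merge(
        cls.table[["pam50_nc", "pam50_nc_2nd"]], left_on="sample_id",
        right_index=True, how="left")
    if grouping is not None:
        df["subgroup"] = df["sample_id"].map(grouping)
    else:
        df["subgroup"] = "all"

    keys = ["subgroup", "pam50_nc", "gene_set_id"]
    grp = df.groupby(keys, dropna=False)
    switch_prop = grp["switch"].agg(
        proportion="mean", n_switched="sum", n="size").reset_index()

    switchers = df[df["switch"]]
    perturb_dist = (switchers.groupby(keys + ["pam50_perturb"])
                    .size().rename("count").reset_index())

    m = switchers.dropna(subset=["matches_2nd"])
    if len(m):
        matches = m.groupby(keys)["matches_2nd"].agg(
            proportion="mean", n="size").reset_index()
        matches["proportion"] = matches["proportion"].astype(float)
    else:
        matches = pd.DataFrame(columns=keys + ["proportion", "n"])
    return {"switch_proportion": switch_prop,
            "perturb_distribution": perturb_dist,
            "matches_2nd": matches}
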