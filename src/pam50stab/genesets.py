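"""Co-expression gene sets, gene-set scores, and rank-based metagene scores.

The partition of the 50 PAM50 genes into co-expressed clusters drives the
leave-one-set-out perturbation sweep. ``cluster_genes`` is an average-linkage
hierarchical surrogate for core clustering (distance = 1 - Spearman); the
shipped fixture partition (see :func:`pam50stab.io.load_default_partition`)
encodes the seven published core sets used by all pipeline runs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .datatypes import (
    CentroidMatrix,
    ExpressionMatrix,
    GeneSetPartition,
    ValidationError,
)


def cluster_genes(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    corr_threshold: float = 0.5,
    min_coexpression: float = 0.3,
    seed: int = 0,  # noqa: ARG001 - kept for interface symmetry; method is deterministic
) -> GeneSetPartition:
    """Partition genes by average-linkage clustering on 1 - Spearman distance.

    The dendrogram is cut at distance ``1 - corr_threshold``. A gene left as
    a singleton whose strongest absolute correlation to any other gene falls
    below ``min_coexpression`` is placed in the unassigned bucket, as are
    constant genes (correlation undefined). Cluster IDs are renumbered 1..K
    by decreasing size (ties by first member gene name), so the result is
    deterministic.
    """
    if genes is None:
        genes = expr.genes
    if expr.n_samples < 20:
        warnings.warn(f"only {expr.n_samples} samples; >=20 recommended "
                      "for stable co-expression estimates", stacklevel=2)
    sub = expr.subset_genes(genes)
    log2 = sub.log2().to_numpy()
    const = np.ptp(log2, axis=1) == 0  # exact constancy; std has rounding noise
    if const.any():
        dropped = [g for g, c in zip(genes, const) if c]
        warnings.warn(f"constant genes placed unassigned: {dropped}", stacklevel=2)
    active = [g for g, c in zip(genes, const) if not c]
    assignment: dict[str, int | None] = {g: None for g in genes}
    if len(active) >= 2:
        ranks = rankdata(log2[~const], axis=1)
        rho = np.corrcoef(ranks)
        np.fill_diagonal(rho, 1.0)
        dist = np.clip(1.0 - rho, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(Z, t=1.0 - corr_threshold, criterion="distance")
        off = rho.copy()
        np.fill_diagonal(off, 0.0)
        max_abs = np.abs(off).max(axis=1)
        members: dict[int, list[str]] = {}
        for g, c, m in zip(active, raw, max_abs):
            if np.sum(raw == c) == 1 and m < min_coexpression:
                continue  # weakly co-expressed singleton -> unassigned
            members.setdefault(int(c), []).append(g)
        ordered = sorted(members.values(), key=lambda gs: (-len(gs), gs[0]))
        for new_id, gs in enumerate(ordered, start=1):
            for g in gs:
                assignment[g] = new_id
    return GeneSetPartition(assignment)


def split_cluster(
    partition: GeneSetPartition,
    cluster_id: int,
    into: list[list[str]],
) -> GeneSetPartition:
    """Manually split one cluster into explicitly listed sub-clusters.

    The listed gene lists must exactly cover the cluster and be disjoint;
    cluster IDs are re-compacted to stay contiguous from 1.
    """
    current = set(partition.genes_in(cluster_id))
    listed = [g for part in into for g in part]
    if len(listed) != len(set(listed)):
        raise ValidationError("split parts overlap")
    if set(listed) != current:
        raise ValidationError(
            f"split parts must exactly cover gene set {cluster_id}: "
            f"missing {sorted(current - set(listed))}, "
            f"extra {sorted(set(listed) - current)}")
    lookup = {g: i for i, part in enumerate(into) for g in part}
    new_assignment: dict[str, int | None] = {}
    next_id = 1
    id_map: dict[tuple, int] = {}
    for g, c in partition.assignment.items():
        if c is None:
            new_assignment[g] = None
            continue
        key = ("split", lookup[g]) if c == cluster_id else ("keep", c)
        if key not in id_map:
            id_map[key] = next_id
            next_id += 1
        new_assignment[g] = id_map[key]
    return GeneSetPartition(new_assignment)


def gene_set_scores(
    expr: ExpressionMatrix,
    partition: GeneSetPartition,
) -> pd.DataFrame:
    """Per-sample gene-set scores: mean log2(FPKM+0.1) over member genes.

    No gene centering is applied. Returns samples x gene sets.
    """
    log2 = expr.log2()
    cols = {}
    for cid in partition.cluster_ids:
        members = [g for g in partition.genes_in(cid) if g in log2.index]
        if not members:
            raise ValidationError(f"gene set {cid} has no measured genes")
        cols[cid] = log2.loc[members].mean(axis=0)
    out = pd.DataFrame(cols)
    out.index.name = "sample_id"
    return out


def metagene_rank_scores(
    expr: ExpressionMatrix,
    metagenes: dict[str, list[str]],
) -> pd.DataFrame:
    """Rank-based metagene scores in [0, 1] (samples x metagenes).

    Per gene, samples are ranked ascending by FPKM (mid-ranks for ties) and
    scaled as (rank-1)/(n-1); the metagene score is the mean scaled rank over
    member genes. Member genes absent from the matrix are dropped with a
    warning.
    """
    n = expr.n_samples
    if n < 2:
        raise ValidationError("metagene rank scores need >= 2 samples")
    scaled = (rankdata(expr.values.to_numpy(), axis=1) - 1.0) / (n - 1.0)
    scaled = pd.DataFrame(scaled, index=expr.genes, columns=expr.samples)
    cols = {}
    for name, genes in metagenes.items():
        if not genes:
            raise ValidationError(f"metagene {name!r} has an empty gene list")
        present = [g for g in genes if g in scaled.index]
        missing = [g for g in genes if g not in scaled.index]
        if missing:
            warnings.warn(f"metagene {name!r}: dropping missing genes {missing}",
                          stacklevel=2)
        if not present:
            raise ValidationError(f"metagene {name!r} has no measured genes")
        cols[name] = scaled.loc[present].mean(axis=0)
    out = pd.DataFrame(cols)
    out.index.name = "sample_id"
    return out


def centroid_geneset_means(
    centroids: CentroidMatrix,
    partition: GeneSetPartition,
) -> pd.DataFrame:
    """Mean centroid value per (subtype, gene set); subtypes x gene sets."""
    cols = {}
    for cid in partition.cluster_ids:
        members = [g for g in partition.genes_in(cid) if g in centroids.values.columns]
        if members:
            cols[cid] = centroids.values[members].mean(axis=1)
    return pd.DataFrame(cols)


def default_metagenes(partition: GeneSetPartition) -> dict[str, list[str]]:
    """Convenience metagene definitions from the three large core sets.

    The published metagene gene lists are configuration in this package;
    these defaults mirror the biology of the three large PAM50 co-expression
    modules (proliferation, steroid response, basal keratins).
    """
    ids = partition.cluster_ids
    names = {1: "proliferation", 2: "steroid_response", 3: "basal"}
    return {names.get(cid, f"set{cid}"): partition.genes_in(cid)
            for cid in ids if cid in names}
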