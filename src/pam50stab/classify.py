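"""Ensemble nearest-centroid (NC) PAM50 classification.

Each tumor is classified once per reference set: per-gene centering vectors
(median log2(FPKM+0.1) over a balanced reference subsample) are subtracted
from the tumor's log2 profile, Spearman correlations to the five subtype
centroids are computed over the shared genes, and the nearest (highest
correlation) centroid is the run's call. Over ``n_sets`` (default 100)
reference sets the majority vote is the PAM50_NC subtype; per-centroid mean
correlations across runs yield the second-best subtype (PAM50_NC_2nd) and
the best-minus-second correlation difference (delta), a distinctiveness
measure. No minimum correlation cut-off is applied: the argmax wins even
when every correlation is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import (
    SUBTYPES,
    CentroidMatrix,
    DegenerateProfileError,
    ExpressionMatrix,
    ValidationError,
)

AMBIGUOUS = "ambiguous"


@dataclass
class ReferenceSetCollection:
    """Balanced reference subsamples and their per-gene centering vectors."""

    sets: list[list[str]]
    centering: pd.DataFrame  # genes x n_sets, log2(FPKM+0.1) scale

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def genes(self) -> list[str]:
        return list(self.centering.index)

    def subset_genes(self, genes) -> "ReferenceSetCollection":
        return ReferenceSetCollection(sets=self.sets, centering=self.centering.loc[list(genes)])


@dataclass
class EnsembleClassification:
    """Per-sample vote counts, mean centroid correlations, and derived calls.

    ``table`` is indexed by sample ID with columns ``pam50_nc``,
    ``pam50_nc_2nd`` (a subtype or ``"ambiguous"``), ``delta``,
    ``corr_<subtype>`` (mean Spearman correlation over runs) and
    ``votes_<subtype>``. ``excluded`` lists samples dropped for degenerate
    (constant) centered profiles.
    """

    table: pd.DataFrame
    n_sets: int
    excluded: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def calls(self) -> pd.Series:
        return self.table["pam50_nc"]

    def mean_correlations(self) -> pd.DataFrame:
        return self.table[[f"corr_{s}" for s in SUBTYPES]].rename(
            columns={f"corr_{s}": s for s in SUBTYPES})

    def vote_counts(self) -> pd.DataFrame:
        return self.table[[f"votes_{s}" for s in SUBTYPES]].rename(
            columns={f"votes_{s}": s for s in SUBTYPES})


def default_composition(labels: pd.Series, set_size: int = 50) -> dict[str, int]:
    """Balanced per-subtype reference-set counts.

    Reference sets are balanced across subtypes (an equal share of
    ``set_size`` per subtype present, as in the near-balanced training
    cohort the original centroids were derived from), capped by the number
    of labelled samples available for each subtype. An unbalanced centering
    reference would bias the per-gene medians toward the majority subtype.
    """
    avail = labels.value_counts()
    present = [s for s in SUBTYPES if s in avail.index]
    share = max(1, set_size // max(len(present), 1))
    return {s: int(min(share, avail[s])) for s in present}


def build_reference_sets(
    expr: ExpressionMatrix,
    labels: pd.Series,
    composition: dict[str, int],
    n_sets: int = 100,
    seed: int = 0,
    statistic: str = "median",
) -> ReferenceSetCollection:
    """Draw ``n_sets`` balanced reference subsamples and compute centering.

    Each set draws, without replacement, ``composition[subtype]`` samples per
    subtype from the provisionally labelled cohort; the centering vector is
    the per-gene median (configurable to mean) of log2(FPKM+0.1) over the
    set's samples.
    """
    if statistic not in ("median", "mean"):
        raise ValidationError(f"unknown centering statistic {statistic!r}")
    labels = labels.loc[[s for s in labels.index if s in expr.values.columns]]
    pools = {st: labels.index[labels == st].to_numpy() for st in composition}
    for st, count in composition.items():
        if count < 1:
            raise ValidationError(f"composition count for {st} must be >= 1")
        if len(pools[st]) < count:
            raise ValidationError(
                f"insufficient {st} samples: need {count}, have {len(pools[st])}")
    rng = np.random.default_rng(seed)
    log2 = expr.log2()
    sets: list[list[str]] = []
    vectors = np.empty((log2.shape[0], n_sets))
    agg = np.median if statistic == "median" else np.mean
    for k in range(n_sets):
        members: list[str] = []
        for st in composition:  # fixed dict order keeps draws reproducible
            members.extend(rng.choice(pools[st], size=composition[st], replace=False))
        sets.append(members)
        vectors[:, k] = agg(log2[members].to_numpy(), axis=1)
    centering = pd.DataFrame(vectors, index=log2.index,
                             columns=[f"ref{k+1:03d}" for k in range(n_sets)])
    return ReferenceSetCollection(sets=sets, centering=centering)


def _spearman_to_centroids(centered: np.ndarray, centroid_ranks_z: np.ndarray) -> np.ndarray:
    """Spearman correlations of centered profiles (genes x samples) to centroids.

    ``centroid_ranks_z`` is the standardized mid-rank matrix (subtypes x genes),
    each row scaled so that the dot product with a standardized sample rank
    vector is the correlation. Columns with zero rank variance yield NaN.
    """
    g = centered.shape[0]
    ranks = rankdata(centered, axis=0)
    ranks -= ranks.mean(axis=0, keepdims=True)
    norm = np.sqrt((ranks ** 2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, ranks / norm, np.nan)
    return centroid_ranks_z @ z  # subtypes x samples


def _centroid_ranks_z(centroids: CentroidMatrix) -> np.ndarray:
    C = centroids.values.to_numpy()
    ranks = rankdata(C, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks ** 2).sum(axis=1, keepdims=True))
    if (norm == 0).any():
        flat = [centroids.subtypes[i] for i in np.where(norm[:, 0] == 0)[0]]
        raise ValidationError(f"constant centroid rows: {flat}")
    return ranks / norm


def shared_genes(expr: ExpressionMatrix, centering: pd.Series | pd.DataFrame,
                 centroids: CentroidMatrix) -> list[str]:
    """Genes common to all three structures, in centroid gene order."""
    eg, cg = set(expr.genes), set(centering.index)
    return [g for g in centroids.genes if g in eg and g in cg]


def classify_single(
    sample_fpkm: pd.Series,
    centering: pd.Series,
    centroids: CentroidMatrix,
) -> tuple[dict[str, float], str]:
    """One NC classification of one sample against one centering vector.

    Returns the five Spearman correlations and the argmax subtype (first in
    the fixed subtype order on an exact tie). Raises
    :class:`DegenerateProfileError` when the centered profile is constant.
    """
    genes = [g for g in centroids.genes
             if g in sample_fpkm.index and g in centering.index]
    if len(genes) < 3:
        raise ValidationError(f"only {len(genes)} genes shared; need >= 3")
    sub = centroids.subset_genes(genes)
    x = np.log2(sample_fpkm.loc[genes].to_numpy(dtype=float) + 0.1)
    centered = x - centering.loc[genes].to_numpy(dtype=float)
    corr = _spearman_to_centroids(centered[:, None], _centroid_ranks_z(sub))[:, 0]
    if np.isnan(corr).any():
        raise DegenerateProfileError("degenerate profile: constant centered values")
    best = sub.subtypes[int(np.argmax(corr))]
    return {s: float(c) for s, c in zip(sub.subtypes, corr)}, best


def _majority_call(votes: np.ndarray, mean_corr: np.ndarray,
                   sample_id: str) -> str:
    """Majority vote; ties broken by mean correlation, then subtype order."""
    top = votes.max()
    cand = np.where(votes == top)[0]
    if len(cand) > 1:
        best_corr = mean_corr[cand].max()
        cand2 = cand[mean_corr[cand] == best_corr]
        if len(cand2) > 1:
            warnings.warn(
                f"sample {sample_id}: exact vote and correlation tie between "
                f"{[SUBTYPES[i] for i in cand2]}; using fixed subtype order",
                stacklevel=3)
        return SUBTYPES[int(cand2[0])]
    return SUBTYPES[int(cand[0])]


def _second_best(mean_corr: np.ndarray, nc_idx: int) -> tuple[str, float]:
    """Second-best subtype by mean correlation among the non-called subtypes.

    Returns ``("ambiguous", nan)`` when the 2nd and 3rd mean correlations tie
    exactly.
    """
    others = [i for i in range(len(SUBTYPES)) if i != nc_idx]
    order = sorted(others, key=lambda i: (-mean_corr[i], SUBTYPES[i]))
    if len(order) > 1 and mean_corr[order[0]] == mean_corr[order[1]]:
        return AMBIGUOUS, float("nan")
    second = order[0]
    return SUBTYPES[second], float(mean_corr[nc_idx] - mean_corr[second])


def classify_ensemble(
    expr: ExpressionMatrix,
    refsets: ReferenceSetCollection,
    centroids: CentroidMatrix,
) -> EnsembleClassification:
    """Run the NC classifier once per reference set and aggregate.

    PAM50_NC is the majority vote over runs (ties broken by mean correlation,
    then fixed subtype order, with a warning); PAM50_NC_2nd is the subtype
    with the highest mean correlation among the four non-called subtypes,
    or ``"ambiguous"`` on an exact 2nd/3rd tie. Samples whose centered
    profile is constant in any run are excluded with a warning.
    """
    genes = shared_genes(expr, refsets.centering, centroids)
    if len(genes) < 3:
        raise ValidationError(f"only {len(genes)} genes shared; need >= 3")
    sub_centroids = centroids.subset_genes(genes)
    cz = _centroid_ranks_z(sub_centroids)
    log2 = expr.log2().loc[genes].to_numpy()
    centering = refsets.centering.loc[genes].to_numpy()
    n_sets = refsets.n_sets
    n_samples = expr.n_samples

    corr_runs = np.empty((n_sets, len(SUBTYPES), n_samples))
    for k in range(n_sets):
        corr_runs[k] = _spearman_to_centroids(log2 - centering[:, [k]], cz)

    degenerate = np.isnan(corr_runs).any(axis=(0, 1))
    excluded = [s for s, d in zip(expr.samples, degenerate) if d]
    if excluded:
        warnings.warn(f"excluding degenerate profiles: {excluded}", stacklevel=2)

    run_calls = corr_runs.argmax(axis=1)             # n_sets x n_samples
    mean_corr = corr_runs.mean(axis=0)               # subtypes x n_samples

    rows = []
    keep = [s for s, d in zip(expr.samples, degenerate) if not d]
    for j, sample in enumerate(expr.samples):
        if degenerate[j]:
            continue
        votes = np.bincount(run_calls[:, j], minlength=len(SUBTYPES))
        mc = mean_corr[:, j]
        nc = _majority_call(votes, mc, sample)
        nc_idx = SUBTYPES.index(nc)
        second, delta = _second_best(mc, nc_idx)
        row = {"pam50_nc": nc, "pam50_nc_2nd": second, "delta": delta}
        row.update({f"corr_{s}": mc[i] for i, s in enumerate(SUBTYPES)})
        row.update({f"votes_{s}": int(votes[i]) for i, s in enumerate(SUBTYPES)})
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(keep, name="sample_id"))
    return EnsembleClassification(table=table, n_sets=n_sets, excluded=excluded)


def centroid_intercorrelation(centroids: CentroidMatrix) -> pd.DataFrame:
    """Pearson correlations between subtype centroid rows (symmetric, unit diagonal)."""
    C = centroids.values.to_numpy()
    corr = np.corrcoef(C)
    return pd.DataFrame(corr, index=centroids.subtypes, columns=centroids.subtypes)


def crosstab_nc_vs_2nd(
    cls: EnsembleClassification,
    grouping: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """5x5 PAM50_NC x PAM50_NC_2nd contingency tables, overall and per subgroup.

    Samples with an ambiguous second-best subtype are excluded from the
    tables; their count is reported under the key ``"n_ambiguous"`` of the
    returned dict's ``.attrs``-like companion entry (a 1x1 DataFrame).
    """
    t = cls.table
    unambiguous = t[t["pam50_nc_2nd"] != AMBIGUOUS]

    def _tab(sub: pd.DataFrame) -> pd.DataFrame:
        tab = pd.crosstab(sub["pam50_nc"], sub["pam50_nc_2nd"])
        return tab.reindex(index=SUBTYPES, columns=SUBTYPES, fill_value=0)

    out = {"all": _tab(unambiguous)}
    if grouping is not None:
        grouping = grouping.reindex(unambiguous.index)
        for sg in sorted(grouping.dropna().unique()):
            out[sg] = _tab(unambiguous[grouping == sg])
    out["n_ambiguous"] = pd.DataFrame(
        {"count": [int((t["pam50_nc_2nd"] == AMBIGUOUS).sum())]})
    return out
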