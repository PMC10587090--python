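"""End-to-end pipeline orchestration with a single structured config.

Stages run in order: simulate (optional) -> full-gene ensemble
classification -> gene-set partition (file or clustering) -> background
classification (sweep baseline) -> leave-one-set-out perturbation sweep ->
K0 refinement -> survival analyses. One master seed fans out to per-stage
sub-seeds through ``numpy.random.SeedSequence`` spawn keys, so each stage is
independently reproducible and a rerun with the same config reproduces all
outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    build_reference_sets,
    classify_ensemble,
    crosstab_nc_vs_2nd,
    default_composition,
)
from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    ValidationError,
    clinical_subgroups,
)
from .genesets import cluster_genes, gene_set_scores
from .io import (
    load_default_centroids,
    load_default_partition,
    read_centroid_matrix,
    read_clinical_table,
    read_expression_matrix,
    read_gene_set_partition,
    write_centroid_matrix,
    write_clinical_table,
    write_expression_matrix,
    write_gene_set_partition,
)
from .k0 import build_k0_centroids, classify_k0, transition_table
from .perturb import perturbation_sweep, switch_summary
from .simulate import SimulationConfig, simulate_cohort
from .survival import cox_univariate


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see ``from_yaml`` for the file layout."""

    seed: int
    output_dir: Path
    simulate: dict | None = None          # SimulationConfig overrides, or None
    expression_path: Path | None = None
    clinical_path: Path | None = None
    truth_path: Path | None = None
    centroids_path: Path | None = None    # None -> shipped synthetic fixture
    partition_source: str = "file"        # "file" | "cluster"
    partition_path: Path | None = None    # None -> shipped fixture
    cluster_corr_threshold: float = 0.5
    n_sets: int = 100
    set_size: int = 50
    composition: dict[str, int] | None = None
    centering_statistic: str = "median"
    refset_labels: str = "truth"          # "truth" | "first_pass" | a file path
    include_unassigned: bool = False
    k0_subgroup: str = "ERpHER2n"
    min_k0_per_subtype: int = 5
    run_sweep: bool = True
    run_k0: bool = True
    run_survival: bool = True
    survival_endpoint: str = "drfi"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValidationError("pipeline config requires a seed")
        cfg = cls(
            seed=int(raw["seed"]),
            output_dir=Path(raw.get("output_dir", "pam50stab_run")),
            simulate=raw.get("simulate"),
            expression_path=_opt_path(raw.get("expression")),
            clinical_path=_opt_path(raw.get("clinical")),
            truth_path=_opt_path(raw.get("truth")),
            centroids_path=_opt_path(raw.get("centroids")),
            partition_source=raw.get("partition", {}).get("source", "file"),
            partition_path=_opt_path(raw.get("partition", {}).get("path")),
            cluster_corr_threshold=float(
                raw.get("partition", {}).get("corr_threshold", 0.5)),
            n_sets=int(raw.get("classifier", {}).get("n_sets", 100)),
            set_size=int(raw.get("classifier", {}).get("set_size", 50)),
            composition=raw.get("classifier", {}).get("composition"),
            centering_statistic=raw.get("classifier", {}).get(
                "centering_statistic", "median"),
            refset_labels=raw.get("classifier", {}).get("refset_labels", "truth"),
            include_unassigned=bool(raw.get("sweep", {}).get(
                "include_unassigned", False)),
            k0_subgroup=raw.get("k0", {}).get("subgroup", "ERpHER2n"),
            min_k0_per_subtype=int(raw.get("k0", {}).get("min_per_subtype", 5)),
            run_sweep=bool(raw.get("sweep", {}).get("enabled", True)),
            run_k0=bool(raw.get("k0", {}).get("enabled", True)),
            run_survival=bool(raw.get("survival", {}).get("enabled", True)),
            survival_endpoint=raw.get("survival", {}).get("endpoint", "drfi"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            if self.expression_path is None or self.clinical_path is None:
                raise ValidationError(
                    "either a simulate block or expression+clinical paths required")
            for p in (self.expression_path, self.clinical_path, self.truth_path,
                      self.centroids_path, self.partition_path):
                if p is not None and not Path(p).exists():
                    raise ValidationError(f"input path does not exist: {p}")
        if self.partition_source not in ("file", "cluster"):
            raise ValidationError("partition.source must be 'file' or 'cluster'")


def _opt_path(value) -> Path | None:
    return None if value in (None, "") else Path(value)


def _stage_seed(root: np.random.SeedSequence, index: int) -> int:
    return int(root.spawn(index + 1)[index].generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all configured stages; returns the run directory.

    Every stage writes tab-delimited outputs under the run directory; a
    ``manifest.json`` records the package version, seed, config hash, and
    sha256 of every output so reruns can be verified byte-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    manifest: dict = {
        "package": "pam50stab", "version": __version__, "seed": config.seed,
        "stages": [], "outputs": {},
    }

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = hashlib.sha256(path.read_bytes()).hexdigest()

    # --- inputs / simulation -------------------------------------------------
    centroids = (read_centroid_matrix(config.centroids_path)
                 if config.centroids_path else load_default_centroids())
    truth = None
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate,
                                      "seed": _stage_seed(root, 0)})
        cohort = simulate_cohort(centroids, sim_cfg)
        expr, clinical, truth = cohort.expression, cohort.clinical, cohort.truth
        _write("expression.tsv", lambda p: write_expression_matrix(expr, p))
        _write("clinical.tsv", lambda p: write_clinical_table(clinical, p))
        _write("truth.tsv", lambda p: truth.to_csv(p, sep="\t", index=False))
        manifest["stages"].append("simulate")
    else:
        expr = read_expression_matrix(config.expression_path)
        clinical = read_clinical_table(config.clinical_path)
        if config.truth_path is not None:
            truth = pd.read_csv(config.truth_path, sep="\t",
                                dtype={"sample_id": str})
    subgroups = clinical_subgroups(clinical)

    # --- reference sets and full-gene classification -------------------------
    labels = _provisional_labels(config, expr, centroids, truth)
    composition = config.composition or default_composition(
        labels, config.set_size)
    refsets = build_reference_sets(
        expr, labels, composition, n_sets=config.n_sets,
        seed=_stage_seed(root, 1), statistic=config.centering_statistic)
    cls_full = classify_ensemble(expr, refsets, centroids)
    _write("nc_results.tsv",
           lambda p: cls_full.table.to_csv(p, sep="\t", index_label="sample_id"))
    tabs = crosstab_nc_vs_2nd(cls_full, subgroups)
    _write("crosstab_nc_vs_2nd.tsv",
           lambda p: tabs["all"].to_csv(p, sep="\t", index_label="pam50_nc"))
    manifest["stages"].append("classify")

    # --- partition ------------------------------------------------------------
    if config.partition_source == "cluster":
        partition = cluster_genes(expr, corr_threshold=config.cluster_corr_threshold,
                                  seed=_stage_seed(root, 2))
    else:
        partition = (read_gene_set_partition(config.partition_path)
                     if config.partition_path else load_default_partition())
    _write("partition.tsv", lambda p: write_gene_set_partition(partition, p))
    scores = gene_set_scores(expr, partition)
    _write("gene_set_scores.tsv", lambda p: scores.to_csv(p, sep="\t"))
    manifest["stages"].append("partition")

    results = {"expression": expr, "clinical": clinical, "truth": truth,
               "subgroups": subgroups, "classification": cls_full,
               "partition": partition, "refsets": refsets}

    # --- perturbation sweep ---------------------------------------------------
    if config.run_sweep:
        bg = [g for g in partition.background_genes(config.include_unassigned)
              if g in expr.values.index and g in centroids.values.columns]
        cls_bg = classify_ensemble(expr.subset_genes(bg),
                                   refsets.subset_genes(bg),
                                   centroids.subset_genes(bg))
        _write("nc_background.tsv",
               lambda p: cls_bg.table.to_csv(p, sep="\t", index_label="sample_id"))
        records, k0_flags = perturbation_sweep(
            expr, refsets, centroids, partition, cls_bg,
            include_unassigned=config.include_unassigned)
        _write("perturb_records.tsv",
               lambda p: records.to_csv(p, sep="\t", index=False))
        summary = switch_summary(records, cls_bg, subgroups)
        _write("switch_proportions.tsv",
               lambda p: summary["switch_proportion"].to_csv(p, sep="\t", index=False))
        _write("switch_matches_2nd.tsv",
               lambda p: summary["matches_2nd"].to_csv(p, sep="\t", index=False))
        _write("k0_flags.tsv",
               lambda p: k0_flags.to_csv(p, sep="\t", index_label="sample_id"))
        results.update({"cls_background": cls_bg, "records": records,
                        "k0_flags": k0_flags, "switch_summary": summary})
        manifest["stages"].append("perturb")

        # --- K0 refinement ----------------------------------------------------
        if config.run_k0:
            try:
                k0c = build_k0_centroids(
                    expr, cls_bg, k0_flags, subgroups,
                    subgroup_filter=config.k0_subgroup,
                    min_k0_per_subtype=config.min_k0_per_subtype)
                k0_calls, _ = classify_k0(expr, k0c)
                trans = transition_table(cls_bg, k0_calls)
                _write("k0_centroids.tsv",
                       lambda p: write_centroid_matrix(k0c.centroids, p))
                _write("k0_calls.tsv",
                       lambda p: k0_calls.to_csv(p, sep="\t", index_label="sample_id"))
                _write("k0_transitions.tsv",
                       lambda p: trans.to_csv(p, sep="\t", index_label="pam50_nc"))
                results.update({"k0_centroids": k0c, "k0_calls": k0_calls,
                                "k0_transitions": trans})
                manifest["stages"].append("refine-k0")
            except ValidationError as exc:
                warnings.warn(f"K0 stage skipped: {exc}", stacklevel=2)

        # --- survival ---------------------------------------------------------
        if config.run_survival:
            cox = _switch_cox(records, clinical, subgroups, config)
            _write("cox_switch_vs_stable.tsv",
                   lambda p: cox.to_csv(p, sep="\t"))
            results["cox_switch"] = cox
            manifest["stages"].append("survival")

    cfg_repr = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(cfg_repr.encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    run_pipeline.last_results = results  # inspection hook for library callers
    return out


def _provisional_labels(config, expr, centroids, truth) -> pd.Series:
    """Label source for balancing reference sets (see docs/methods.md)."""
    if config.refset_labels == "truth":
        if truth is None:
            raise ValidationError(
                "refset_labels='truth' requires a simulated cohort or truth file")
        return pd.Series(truth["true_subtype"].to_numpy(),
                         index=truth["sample_id"].to_numpy())
    if config.refset_labels == "first_pass":
        # unbalanced first pass: one reference set = the whole cohort
        log2 = expr.log2()
        centering = log2.median(axis=1).to_frame("ref001")
        from .classify import ReferenceSetCollection
        rs = ReferenceSetCollection(sets=[expr.samples], centering=centering)
        return classify_ensemble(expr, rs, centroids).calls()
    labels = pd.read_csv(config.refset_labels, sep="\t",
                         dtype={"sample_id": str})
    return pd.Series(labels.iloc[:, 1].to_numpy(),
                     index=labels["sample_id"].to_numpy())


def _switch_cox(records, clinical, subgroups, config) -> pd.DataFrame:
    """Per gene set: Cox HR of switched vs never-affected tumors (reference)."""
    frames = []
    target = subgroups.index[subgroups == config.k0_subgroup]
    for gsid, sub in records.groupby("gene_set_id"):
        sub = sub[sub["sample_id"].isin(target)]
        switched = sub.loc[sub["switch"], "sample_id"].tolist()
        stable = sub.loc[~sub["switch"], "sample_id"].tolist()
        if not switched or not stable:
            continue
        try:
            res = cox_univariate(
                {"stable": stable, "switched": switched}, clinical,
                reference_label="stable", endpoint=config.survival_endpoint)
        except ValidationError:
            continue
        res = res.reset_index()
        res.insert(0, "gene_set_id", gsid)
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["gene_set_id", "stratum", "hr", "ci_lower",
                                     "ci_upper", "p", "n", "events", "unstable"])
    return pd.concat(frames, ignore_index=True)
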