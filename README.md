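# pam50stab

Ensemble nearest-centroid PAM50 subtyping of breast tumors and analysis of
its **stability under gene-set perturbation** — for computational biologists
who want to understand, stress-test, or refine intrinsic-subtype
classification on bulk RNA-seq (FPKM) data.

## The problem and the method

PAM50 assigns each breast tumor one of five intrinsic subtypes — Basal,
HER2E, LumA, LumB, Normal — by correlating the tumor's *relative* expression
of 50 signature genes against five subtype centroids and picking the nearest
(highest-correlation) centroid. "Relative" requires gene centering against a
reference, a step known to be fragile; and the runner-up centroid is often
nearly as close as the winner, so discrete calls hide a continuum.

`pam50stab` implements the full stability-analysis toolchain:

- **Ensemble NC classification.** Each tumor is classified `n_sets` times
  (default 100) with per-gene median centering vectors computed from 100
  balanced reference subsamples of the cohort. For sample *i*, reference set
  *r*, and centroid *c*:

  `rho(i, r, c) = SpearmanCorr( log2(FPKM_i + 0.1) − m_r , centroid_c )`

  The majority vote over runs is **PAM50_NC**; per-centroid means of the 100
  correlations define the second-best subtype **PAM50_NC_2nd** and the
  distinctiveness **delta = mean_rho(best) − mean_rho(second)**. No minimum
  correlation cut-off is applied.
- **Leave-one-gene-set-out perturbation.** The 50 genes partition into seven
  co-expressed core sets (proliferation; steroid response; basal keratins;
  *ERBB2*/*GRB7*; two small sets; *FGFR4*), with five genes unassigned. One
  set at a time is removed from centroids, centering vectors, and expression,
  and every tumor is reclassified 100 times. A tumor *switches* when its
  PAM50_NC subtype appears in ≤ 50% of the perturbed runs.
- **K0 refinement.** Tumors that never switch under any exclusion (K0) seed
  new FPKM-scale centroids (mean FPKM per gene per subtype, within a clinical
  subgroup such as ERpHER2n); all tumors are then reclassified single-sample
  by Spearman correlation of raw FPKM — no offset, no log, no centering.
- **Survival stratification.** Kaplan–Meier / log-rank and univariate Cox
  models (Efron ties) of classification-derived groups on OS or DRFI.
- **Synthetic cohorts.** A seeded generator produces expression + clinical +
  survival data with configurable subgroup composition (default 10.3% TNBC,
  4.1% ERnHER2p, 8.8% ERpHER2p, 76.8% ERpHER2n), subgroup-conditional subtype
  frequencies, centered-log Gaussian noise, and subtype-dependent exponential
  hazards — so the entire pipeline is testable without access to a real
  cohort.

The shipped centroid matrix is a **synthetic** Parker-style fixture (see
`docs/methods.md`); supply your own centroid TSV for real analyses.

## Worked example

```bash
pam50stab run --config config.yaml
```

with `config.yaml`:

```yaml
seed: 17
output_dir: demo_run
simulate: {n_samples: 300}
```

writes the simulated cohort, classification, sweep, and K0 outputs under
`demo_run/` plus a `manifest.json` of sha256 hashes. Re-running the same
config reproduces every file byte-identically. In Python:

```python
import pandas as pd
from pam50stab.pipeline import PipelineConfig, run_pipeline

out = run_pipeline(PipelineConfig(seed=17, output_dir="demo_run",
                                  simulate={"n_samples": 300}))
nc = pd.read_csv(out / "nc_results.tsv", sep="\t")
print(nc[["sample_id", "pam50_nc", "pam50_nc_2nd", "delta"]].head(3))
```

```
  sample_id pam50_nc pam50_nc_2nd     delta
0    S00001     LumA       Normal  0.344242
1    S00002    Basal        HER2E  0.624386
2    S00003     LumA       Normal  0.419315
```

Each row is one tumor: the winning subtype, the runner-up by mean centroid
correlation, and the correlation gap between them (larger = more distinct
call). `perturb_records.tsv` then holds one row per tumor × excluded gene
set with the perturbed call and switch flag, and `k0_flags.tsv` marks the
perturbation-stable tumors.

Individual stages are also available as subcommands
(`simulate`, `classify`, `cluster-genes`, `scores`, `perturb`, `refine-k0`,
`survival`) and as plain library functions.

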