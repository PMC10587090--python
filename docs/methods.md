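# Methods

This note documents the models, conventions, and numerical choices behind
`pam50stab`, in the order the pipeline runs them.

## Ensemble nearest-centroid classification

**Model.** A tumor's subtype is the PAM50 centroid with the highest Spearman
correlation to its *centered* log expression. Centering subtracts, per gene,
a reference statistic computed over a balanced subsample of the cohort
("reference set"); because a single reference is itself a noisy estimate,
the classifier is an ensemble: `n_sets` (default 100) reference sets are
drawn, each tumor is classified once per set, and the majority vote is the
PAM50_NC call.

Conventions, with defaults and rationale:

- **Log transform:** `log2(FPKM + 0.1)`, the offset applied uniformly
  everywhere (classification, gene-set scores, clustering). The pseudocount
  keeps zero-expression genes finite and compresses noise near zero.
- **Centering statistic:** per-gene *median* over the reference set's
  samples (configurable to mean). The median is robust to the skewed,
  heavy-tailed FPKM distributions of single genes.
- **Reference-set composition:** equal per-subtype counts (a balanced share
  of `set_size = 50`, capped by the number of labelled samples available per
  subtype), drawn without replacement and seeded. Balance matters: a
  cohort-proportional reference drags the per-gene median toward the
  majority subtype (LumA in a population cohort), which measurably distorts
  calls — even noise-free subtype prototypes can misclassify against a
  skewed reference. The labels used for balancing are provisional by
  construction; in simulation the generator's truth labels are used, on real
  data a first-pass classification with whole-cohort centering
  (`refset_labels: first_pass`) or an external label file.
- **Spearman ties:** mid-rank (average) convention, the standard choice.
- **No correlation cut-off:** the argmax subtype is returned even if all
  five correlations are negative.
- **Vote ties:** broken by higher mean correlation, then by the fixed
  subtype order (Basal, HER2E, LumA, LumB, Normal), with a warning. Exact
  ties essentially never occur with float correlations; the deterministic
  fallback exists so runs are reproducible bit-for-bit.
- **Second-best subtype:** the highest *mean* correlation (over the
  ensemble's runs) among the four non-called subtypes;
  `delta = mean_rho(called) − mean_rho(second)`. An exact tie between the
  2nd and 3rd mean correlations yields the label `ambiguous`, and such
  samples are excluded from second-best analyses.
- **Degenerate profiles:** a sample whose centered profile is constant in
  any run has no defined rank correlation; it is excluded with a warning
  rather than silently assigned.

## Gene sets and the perturbation sweep

The 50 signature genes partition into seven co-expressed core sets plus five
unassigned genes (*MYC*, *MMP11*, *BAG1*, *MDM2*, *BLVRA*). The shipped
fixture encodes the published core sets: set 1 = proliferation (21 genes,
e.g. *MKI67*, *CENPF*, *CCNE1*, *TYMS*, *KIF2C*), set 2 = steroid response
(9 genes, *ESR1*, *FOXA1*, *PGR*, …), set 3 = basal keratins (8 genes,
*KRT5/14/17*, *EGFR*, …), set 4 = the 17q12 amplicon pair *ERBB2*/*GRB7*,
set 6 = *GPR160*/*TMEM45B*, set 7 = the singleton *FGFR4*. Published
listings name sets 2, 3, 4, 6, 7 and the unassigned genes in full; the
remaining 23 genes were assigned here by biology — the canonical
proliferation genes to set 1 and the pair *ACTR3B*/*PHGDH* as set 5, whose
membership is not individually listed anywhere and is therefore this
package's own completion of the partition.

`cluster_genes` provides a clustering surrogate for deriving such partitions
de novo: average-linkage hierarchical clustering on distance
`1 − Spearman(gene, gene)`, cut at `1 − corr_threshold` (default threshold
0.5), with weakly co-expressed singletons (max |rho| < 0.3) and constant
genes placed unassigned. It is deterministic; cluster IDs are renumbered by
decreasing size. The original partition was produced by a different
unsupervised core-clustering method on a much larger cohort; the surrogate
exists because downstream stages depend only on the partition itself, which
is shipped as a fixture. Whether that method's core-membership criteria
would alter the partition on other cohorts cannot be assessed here.

**Sweep.** The background universe is the union of the seven core sets (45
genes); unassigned genes take no part (a flag can include them as a fixed,
never-removed background for sensitivity analysis). For each set, centroids,
centering vectors, and expression are restricted to the identical remaining
gene list and the ensemble classifier is re-run with the *same* 100
reference sets (centering vectors are sub-selected, not re-estimated —
matching the design of reusing one fixed reference panel). A sample
*switches* when its baseline subtype is observed in `≤ n_sets/2` of the
perturbed runs — the literal count comparison, so 50 of 100 is a switch and
51 is not. The sweep's baseline classification is computed on the unreduced
45-gene background (not all 50 genes), which makes the identity perturbation
exactly stable; the pipeline reports the full 50-gene classification
separately for the NC/second-best analyses. `corr_delta` is the mean
perturbed correlation to the perturbed call minus the mean unperturbed
correlation to the baseline call (positive = the perturbed call correlates
better). Combinations of gene sets are deliberately not excluded: removing
most of the gene content leaves correlations too uninformative to interpret.

## K0 refinement

Tumors that never switch under any single-set exclusion (K0) are treated as
core representatives of their subtype within a clinical subgroup (default
ERpHER2n, the largest). New centroids are the arithmetic **mean FPKM** per
gene over the K0 tumors of each subtype — the mean, not the median, so the
centroid is the expected FPKM profile of a core tumor rather than a robust
summary. A subtype row is built only from at least
`min_k0_per_subtype` (default 5) contributors; the guard avoids
single-tumor centroids and is configurable to 1 for literal replication,
since the original construction drops small groups only at the
survival-plot stage. All tumors of the subgroup are then reclassified in
single-sample mode: Spearman correlation of the raw FPKM profile against
each available K0 centroid, no offset, no log, no centering. Rank
invariance makes this classifier exactly insensitive to any strictly
increasing per-sample transform — the property that removes the fragile
centering step. Tumors whose baseline subtype lacks a K0 centroid are still
classified against the available rows (the available-subtype set is recorded
in the centroid provenance). The procedure is single-pass; K0 status is not
re-derived from K0 calls.

## Survival analysis

Kaplan–Meier estimation and the two-sided log-rank test compare strata on
OS or DRFI; univariate Cox proportional-hazards models (lifelines, Efron
tie approximation, Wald CIs) estimate hazard ratios against a designated
reference stratum — for the sweep, tumors unaffected by a perturbation.
Strata must not overlap; empty strata are dropped with a warning; the
log-rank test requires two usable strata (with fewer, curves are returned
and the test fields are `None`); a non-reference stratum with zero events is
flagged `unstable` rather than fitted. Swapping the reference inverts the
hazard ratio, which is verified in tests.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested:

- **Composition:** subgroup proportions default to 10.3% TNBC, 4.1%
  ERnHER2p, 8.8% ERpHER2p, 76.8% ERpHER2n, and the subgroup-conditional
  subtype table to the corresponding observed frequencies (e.g. 73.3% Basal
  within TNBC); rows are renormalised from their printed rounding. ER/PR/
  HER2 markers are drawn consistently with the subgroup.
- **Expression:** on the centered-log scale, a sample of subtype *s* is
  `centroid(s, g) + N(0, noise_sd)` per gene (default `noise_sd = 0.2`),
  mapped to FPKM as `max(0, 2^(x + b + j) − 0.1)` with a fixed per-gene
  baseline `b = 3` log2 units (≈ 8 FPKM) and per-sample library jitter
  `j ~ N(0, 0.15)`. Noise is additive on the centered-log scale, where the
  centroids live and where rank-based classification operates.
- **Survival:** exponential event times with per-day subtype hazards
  (defaults order LumA < Normal < LumB < HER2E < Basal for OS, giving
  ≈ 86% vs ≈ 56% ten-year survival at the extremes), independent random
  censoring calibrated so ≈ 20% of event-free patients censor before the
  administrative horizon of 3650 days. Weibull shapes are a possible config
  extension, not implemented.
- **Planted-module cohorts** (`simulate_module_cohort`) add a shared latent
  factor per module for validating the clustering surrogate.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: full-transcriptome context, tumor purity and
stromal admixture, histology–expression correlations, batch effects, and
realistic inter-subtype overlap. The synthetic centroid fixture (below) has
wider margins between subtypes than real tumors, so synthetic cohorts are
easier to classify and markedly more perturbation-stable than a real
population cohort; switch proportions and K0 fractions from the acceptance
run characterise the pipeline's mechanics under these conditions, not
breast-cancer biology.

## The synthetic centroid fixture

The published centroid values are not redistributable here, so the package
ships `data/synthetic_pam50_centroids.tsv`: 50 genes × 5 subtypes built
from gene-set-level subtype prototypes (proliferation high in Basal/LumB,
low in LumA/Normal; steroid response high in luminal subtypes, low in
Basal; basal keratins high in Basal/Normal; the *ERBB2*/*GRB7* and *FGFR4*
values elevated in HER2E; set 6 reduced in Basal) plus seeded per-gene
jitter (sd 0.18) frozen into the file. The design reproduces the
qualitative inter-centroid correlation structure of PAM50 — Basal most
correlated with HER2E, LumB with LumA, Normal with LumA — and, by
construction, the property that each subtype's modal second-best call on
noise-free prototypes equals its most-correlated other centroid. Real
analyses should substitute the licensed centroid file via the
`centroids` input; all readers accept the legacy gene symbols (*CDCA1*,
*KNTC2*, *ORC6L*) used in older centroid files.

## Determinism and numerics

One master seed fans out to per-stage sub-seeds via `SeedSequence.spawn`,
so stages are independently reproducible and a rerun of the same config
reproduces every output file byte-identically (verified by sha256 in the
run manifest). Spearman correlations are computed as Pearson correlations
of mid-rank vectors via standardized matrix products; the test suite checks
agreement with naive per-pair computation to 1e-12. Exact correlation ties
between centroids (possible with few genes, where rank correlations take
rational values) are broken by the fixed subtype order. Problem sizes in
the shipped tests and the acceptance script (cohorts of 150–1000 samples,
100 reference sets, 2000 per survival arm) were chosen as the smallest
sizes at which the statistical properties under test are stable.

## Known limitations

- The clinical subgroup rules leave ER−/PR+/HER2− tumors (and any tumor
  with an unknown required marker) `unclassified`; they pass through
  classification but join no subgroup analysis.
- The risk-of-recurrence (ROR) score is an external input, not computed.
- No multivariable or adjusted survival models.
- The ensemble's provisional balancing labels are circular with
  classification on real data; the package accepts any label source and
  records which was used.
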