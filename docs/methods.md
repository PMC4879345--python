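# Methods

## Scope and model

`ifnmod` analyses gene-level, already-normalized log2 expression
matrices, one per purified leucocyte subset (CD4+ T, CD8+ T, monocyte,
neutrophil by default), with shared per-sample annotation (subject,
subset, diagnosis, centre, batch). Upstream array or sequencing
preprocessing is deliberately out of scope: the pipeline begins at a
validated genes × samples matrix with no missing values. Gene
identifiers are opaque case-sensitive strings; all interchange formats
are plain text (TSV matrices, CSV annotation, GMT signatures).

The analysis chain per subset is: soft-thresholded correlation network
→ topological overlap → hierarchical module detection → module
eigengenes and kME → IFN-1 module identification → per-sample
interferon scores → healthy-reference threshold → IFN-high
classification and nonparametric group tests. Cross-subset steps
(membership Venn partition, core genes, expression summaries, Ward
clustering) run after every subset completes. All randomness flows
from a single root seed (`numpy` `SeedSequence`, split per stage), and
re-running an identical configuration reproduces the run report
bitwise.

## Network and module parameters

* **Adjacency.** Unsigned, `|r|^β` on Pearson correlations. The IFN
  program is positively coherent, so an unsigned network loses nothing
  here; a signed option (`((1+r)/2)^β`) is provided. Zero-variance
  genes get zero off-diagonal adjacency (with a warning) rather than
  being dropped, keeping gene indices aligned.
* **Power β.** `pick_soft_threshold` implements the scale-free sweep:
  candidates 1–20, signed R² of the log10 frequency vs log10
  connectivity regression over 10 equal-width connectivity bins,
  target 0.8, fallback 6. A candidate additionally requires mean
  connectivity ≥ 1: on unstructured data high powers drive
  connectivity toward zero and the few largest correlations then
  produce a spuriously good log-log fit, so a vanishing network must
  never be "selected". The *pipeline default* pins β = 6 (the
  conventional unsigned choice) for every subset instead of sweeping:
  across random cohorts the sweep picks anywhere between 4 and 19, a
  low draw over-densifies the network (the static cut then absorbs
  tens of spuriously correlated genes into each module), and
  per-subset powers would make TOM and kME scales incomparable across
  subsets — which the cross-subset comparisons depend on. `power:
  auto` restores the sweep.
* **TOM.** Standard unsigned topological overlap,
  `t_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
  `ℓ_ij = Σ_{u∉{i,j}} a_iu a_uj`; verified against a triple-loop oracle
  in the tests.
* **Tree cut.** Average linkage on `1 − TOM`, static cut at height
  0.99, clusters below 30 genes unassigned (label 0), then iterative
  merging of modules whose eigengene dissimilarity `1 − cor` is below
  0.25. The merge step recovers the main practical effect of the
  dynamic hybrid cut (fragmented branches of one program reuniting)
  while keeping the procedure deterministic and dependency-free.
  Labels are re-indexed 1..K by decreasing size.
* **Eigengene.** PC1 (economy SVD) of the samples × genes matrix of
  gene z-scores; per-sample score = `u₁ s₁`, gene loadings unit-norm,
  sign oriented positively against the module mean profile so a higher
  score always means higher module expression. If the orientation
  correlation is exactly zero (perfectly opposed members) the first
  loading is forced positive. Eigengene score units therefore scale
  with module size; thresholds and scores are only compared within a
  subset, never across subsets.
* **kME.** Pearson correlation of every gene (member or not) with the
  eigengene; zero-variance genes get kME 0 with a warning.

## IFN-1 module identification

Per subset, each module is scored by (a) overlap with the curated ISG
signature, (b) Spearman correlation of its eigengene with the 0/1
target-diagnosis indicator (midranks), and (c) Spearman correlation
with the curated IFN score. Selection takes the largest-overlap module
satisfying overlap ≥ `min_overlap_fraction` × signature size (default
0.5), positive diagnosis correlation, and curated correlation ≥ 0.6;
ties break towards higher curated correlation. The thresholds are
config-exposed; 0.5/0.6 sit between a clearly rejectable generic
activation module (curated r ≈ 0.2–0.3) and a clearly acceptable IFN
module (curated r ≈ 0.99 on synthetic cohorts). An empty selection is
a recorded outcome, not an error. The curated score averages
*gene-scaled* expression by default so genes with different dynamic
ranges contribute equally; raw averaging is a config option.

## Dispersion summaries and clustering

MAD is the unscaled median absolute deviation `median(|x − median|)`
(no 1.4826 consistency factor); a mean-absolute-deviation variant is
kept as a sensitivity option. Group summaries flag groups with fewer
than 3 samples instead of erroring. The core-gene heatmap pools
samples across subsets (healthy volunteers by default; the sample
universe is a parameter), scales by gene over the pooled samples, and
orders genes and samples by Ward linkage with Euclidean distance using
the standard recursive leaf order (no leaf-optimal reordering, for
determinism).

## Threshold, classification, tests

Outlier removal is a single pass: z-scores against the healthy
mean/SD (n−1), two-sided normal p, Holm adjustment across the healthy
set (Bonferroni optional), removal below α = 0.001. The threshold is
the linear-interpolation 99th percentile of the retained scores,
calibrated per subset, and "IFN-high" means strictly above it — so
with a continuous score roughly 1% of the healthy calibration samples
exceed their own threshold by construction, and only samples removed
as outliers can push the healthy IFN-high fraction above that. Group
comparisons: Kruskal–Wallis (midranks, tie correction) over diagnosis
groups with ≥ 2 samples; all pairwise two-sided Wilcoxon rank-sum
tests via the normal approximation with continuity correction
(uniformly, avoiding a discontinuous exact/asymptotic switch), Holm
adjusted as one family; stars at 0.05/0.005/0.0005 on adjusted p.

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` draws, per subject, a latent IFN activity from a
per-diagnosis two-component mixture (baseline N(0,1), elevated
N(shift,1)); subjects are reused across subsets, so activity is
paired. Expression is additive: per-gene/subset baseline (+ a basal
boost for responsive genes in myeloid subsets), activity × loading for
responsive genes, latent factors for background modules, per-batch
gene offsets, and iid Gaussian noise. The planted IFN-high flag is
membership of the elevated component (including sporadic activation).

The default configuration (`default_paperlike_config`) encodes the
study conditions: 150 samples per subset (24 SLE, 10 AAV, 10 IBD, 6
Behçet's, 100 HV subjects × 4 subsets = 600 arrays); 1500 genes;
responsive counts neutrophil 300, monocyte 250, CD4 80, CD8 70 sharing
a 60-gene core (myeloid-only blocks 310 genes vs 26 T-cell-only);
elevated fraction 0.85 in SLE and 0.10 in the other diseases, shift
4.5 SD; loadings uniform on [0.8, 2] for core genes and reaching lower
in myeloid subsets ([0.4, 2] vs [0.7, 2]) so myeloid modules carry
more weak members; basal boosts +2/+3 log2 units for responsive genes
in monocytes/neutrophils, matching the much higher basal ISG
expression of myeloid cells; 8 background modules of 60 genes; noise
SD 1; batch SD 0.2. Healthy-volunteer activity is baseline except for
*sporadic activation* confined to neutrophils: probability 0.012 per
HV subject of an acute +12 SD activity spike, modelling the occasional
strong innate ISG induction (e.g. subclinical viral infection) that
makes healthy neutrophil interferon scores untrustworthy. The spike
magnitude is deliberately extreme and the rate deliberately rare: such
samples are exactly what the adjusted-normal-p outlier trim exists to
remove from threshold calibration, and a *broad mild* activation
cluster would instead inflate the healthy SD, mask itself (single-pass
z-based removal cannot remove a sizeable contaminated cluster), and
push the 99th-centile threshold into the pathological range. The 100
HV subjects are the minimum at which that removal step has useful
power.

What the simulation does **not** emulate: probe-level artefacts,
intensity-dependent noise, non-Gaussian expression marginals,
cell-type contamination from imperfect sorting, correlated batch
structure across genes, or treatment effects. Passing recovery tests
therefore demonstrates that the algorithms do what they claim on data
with planted linear-factor structure — not that real microarray
cohorts will yield modules this clean, nor that the paper-scale gene
counts would be reproduced on patient data.

## Numerical choices and degenerate inputs

Scaling uses the n−1 standard deviation; zero-variance genes become
zero rows (warning) everywhere. Correlations are clipped to [−1, 1];
TOM is symmetrized and clipped to [0, 1] against float drift. Quantiles
and percentiles use linear interpolation between order statistics.
Label ties (equal module sizes) break by original label for
determinism. Constant score vectors make rank correlations undefined
and raise errors rather than returning NaN silently. `detect_modules`
requires min_size ≥ 2; thresholds require ≥ 5 healthy scores; group
tests require ≥ 2 groups with ≥ 2 samples.

## Problem sizes

The default synthetic cohort (1500 genes × 150 samples × 4 subsets)
runs the full pipeline in a few seconds on one CPU; the validation
suite analyses five such cohorts end-to-end and adds 1000-replicate
null calibrations, completing in a few minutes. These sizes were
chosen so the planted structure is recovered with comfortable
statistical margins while the whole validation remains quick enough to
run routinely.

## Known limitations

* Static tree cut plus eigengene merging approximates, but is not, the
  dynamic hybrid cut; very close module pairs may stay merged.
* Unsigned networks fold anticorrelated genes into one module; use the
  signed option where repression matters.
* Eigengene score units depend on module size and sample count;
  cross-subset score comparisons must go through per-subset thresholds
  or ranks.
* The healthy-reference threshold assumes approximately Gaussian
  healthy scores for its outlier step; heavy-tailed healthy
  distributions will under-trim (masking) and inflate the threshold.
* Per-patient repeated arrays are treated as independent samples in
  proportions and tests (samples, not patients, are counted).
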