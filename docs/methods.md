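# Methods

## Overview

The pipeline has two branches sharing one cohort. The proteomic branch
relates plasma protein abundance to global myelin water fraction (MWF) and
characterizes the hits (cell-type specificity, gene-set enrichment); the
transcriptomic branch relates regional MWF to regional expression of a
canonical myelin gene measured in donor brain samples. Both branches are
exercised end to end on synthetic data with planted truth.

## Association scan

Per aptamer, OLS of MWF on log2 abundance with covariates age at protein
measurement, age², sex (0/1), and eGFR. Design choices:

- **Regression direction.** MWF is the dependent variable and log2
  protein the predictor. The covariate set (age² is an MWF-trajectory
  adjustment) reads most naturally this way; since t and p of the shared
  term are identical under exchange of response and predictor, only the β
  scale depends on the choice. `--swap-direction` fits the alternative.
- **Hits** are defined by unadjusted p < α (default 0.05). BH q-values
  (`q_bh`) are emitted for the user but do not gate the lists.
- **Complete-case per protein**: subjects with a missing or non-positive
  abundance are dropped for that aptamer only, preserving n elsewhere;
  `n_used` is recorded per record.
- **Aptamer→gene collapse at the list stage.** Aptamers are fitted
  individually (multiple aptamers can target one gene product); a gene
  enters a hit list if any of its aptamers qualifies. A gene with
  conflicting significant aptamers is assigned by its most significant
  one, keeping the positive and negative lists disjoint.
- **Numerics.** QR with column pivoting; a rank-deficient per-protein
  design (e.g., a constant abundance column) produces a null record
  rather than aborting the scan, and `fit_ols` itself raises an error
  naming the offending columns. When the residual variance is numerically
  zero (relative tolerance 1e-20, the exact-fit limit), SEs are 0 and p
  is 0 for nonzero coefficients, 1 otherwise.

## Cell-type specificity

z-scores of log(nTPM + ε) per gene across *all* available cell types
(brain and peripheral alike enter the mean and SD), with ε = 0.1 — small
relative to the conventional 1-nTPM detection cutoff — guarding
against zero expression. Natural log is used (z-scores are base
invariant); the SD uses the n−1 denominator; an all-equal row yields
z = 0 by convention (with a 1e-12 relative tolerance absorbing float
rounding). Enrichment requires z ≥ 2 (ties at exactly 2.0 count) and is
restricted to a configurable brain-related vocabulary (default:
oligodendrocyte, OPC, astrocyte, microglia, excitatory/inhibitory neuron,
endothelial — overridable via YAML, since no canonical list exists).
Categories: `none`, `single`, `oligoMultiCell` (≥ 2 enriched brain types
including the oligo lineage), `multiCell` (≥ 2, excluding it). Genes
absent from the nTPM matrix are `unannotated` and excluded from the
cell-specific denominator.

## Enrichment

Right-tail Fisher exact p = Σ_{i≥k} C(K,i)·C(N−K,n−i)/C(N,n), computed
as a log-space sum of hypergeometric point masses (gammaln + logsumexp).
One-sided only: over-representation is the question, not depletion.
Background defaults to the genes assayed on the panel — the defensible
universe for a panel-based query — overridable with `--background`.
Query genes outside the background are dropped (logged); sets that vanish
after intersection (K = 0) are omitted. Results sort by ascending p, ties
by descending overlap then set name; reporting takes the first
min(5, #{p < 0.05}) rows per library. Odds ratio uses no continuity
correction; a zero denominator cell with k > 0 reports infinity as a
sentinel. No rank-based "combined score" is computed — it would require
permutation reference tables that are not part of this method.

## Spatial stage

- **Assignment**: "within 2 mm of a parcellation" is operationalized as
  distance to the nearest *labeled voxel center* (not an interpolated
  boundary surface) — simple, honest to atlas resolution, and exhaustively
  checkable. In-voxel samples (nearest voxel by index rounding is labeled)
  are assigned at distance 0; ties at equal distance break by smaller
  region id then lexicographic voxel index. Enlarging the radius never
  changes or removes an existing assignment.
- **Differential stability**: per probe, Spearman correlation (midranks)
  of regional mean profiles over every unordered donor pair, restricted to
  regions present in both donors' profiles; pairs with < 3 common regions
  are skipped with a warning; DS is the mean over valid pairs; a probe
  with no valid pair gets NaN and is never selected; ties break by probe
  order.
- **Aggregation** is donor-first (mean of donor means), so donors with
  many samples do not dominate.
- **Correlation**: OLS with regional mean MWF as the response and mean
  mRNA as the predictor; r is the signed Pearson coefficient (identical
  to the standardized simple-OLS slope), p two-sided from
  t = r·sqrt((n−2)/(1−r²)); `--spearman` gives the rank alternative.
  At least 3 common regions are required; zero variance on either axis is
  an error. Regional MWF normally comes from the per-region cohort table;
  a voxelwise MWF map + label volume path (`mwf_map_to_regional`) is also
  provided.

## Synthetic generator

One master seed spawns fixed per-component child streams (truth, cohort,
proteome, nTPM, donors, gene sets), so each artifact is independently
reproducible and regenerating one never shifts another.

**Cohort (n = 85 by default).** Age uniform on [22, 94] (mean 58,
SD ≈ 20.8, matching the emulated cohort's reported moments); sex
Bernoulli(0.56 male); eGFR ~ Gamma(25, 3) (mean 75, SD 15, strictly
positive). Global MWF = 0.30 − 2·10⁻⁵·(age−55)² + trait + noise, where
the inverted-U age trend motivates the age² covariate, the *trait* term
(SD 0.02) is biological between-subject variation, and the noise term
(SD 0.01) is measurement error. The distinction matters: only measurement
scales are zeroed by `zero_noise()`. If all subject-level variation were
"noise", the zero-noise limit would make MWF an exact function of age and
every protein design collinear; keeping the trait preserves the
identifiable signal that the zero-noise recovery property requires.

**Proteome (500 aptamers by default, a desk-speed reduction of a ~6,400-
protein panel; ~5% of genes carry two aptamers).** log2 abundance =
intercept + β·MWF_std + nuisance·(age, sex, eGFR) + N(0, 1), exported on
the linear scale. Planted effects (default 25 positive + 25 negative, on
distinct single-aptamer genes) have |β| equal to 3× the minimal
detectable standardized effect at the configured n (80% power, α = 0.05,
noncentral-t power analysis; ≈ 0.92 at n = 85) — strong enough that
recovery failures indicate bugs, not chance.

**nTPM (14 cell types: 7 brain + 7 peripheral).** Log-normal gene
baselines with per-cell-type log-noise (SD 0.15); planted enriched types
get a +3 log boost. The cell-type count is a deliberate design point:
with a flat baseline, the geometric z-score of k jointly boosted types
among n cell types is bounded by √((n−k)(n−1)/(kn)) regardless of boost
size — 1.90 for k = 2, n = 10, i.e., *below* the 2.0 cutoff, so planted
two-type categories would be unrecoverable on a 10-type matrix. At n = 14
the bound is 2.36 (k = 2) and 3.47 (k = 1), leaving headroom for noise.

**Atlas & donors.** The label volume is a lattice of disjoint axis-aligned
boxes (6 white-matter + 6 deep-gray regions, 2 mm voxels) with background
gaps — geometry is irrelevant to the statistics, but the NIfTI affine
handling is real. Latent regional myelin is uniform on [0.60, 0.90] (WM)
and [0.10, 0.35] (DGM), so WM strictly exceeds DGM. Six donors by default
contribute 36 samples each, jittered up to ±2 mm per axis around labeled
voxel centers so in-voxel, near-miss, and unassignable cases all occur.
Probe expression is gain·myelin + offset + noise with a 1:5 stable:unstable
noise ratio (SD 0.05 vs 0.25); the planted stable probe is the *first*
probe id, which keeps the zero-noise limit (all probes DS = 1, tie broken
by probe order) consistent with "the planted probe is selected".

**Gene sets.** Per library: one pathway enriched for planted-positive
genes, one for planted-negative (70% of the planted genes plus a few
background fillers), and 8 uniform decoy sets of size 10–40.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: assay batch effects and QC artifacts,
non-Gaussian abundance distributions, correlated protein modules,
blood–brain-barrier attenuation of plasma–brain associations, donor-level
expression normalization differences, hemispheric asymmetry, and spatial
autocorrelation of expression within regions (permutation nulls here are
exchangeable, not autocorrelation-preserving). All noise is Gaussian on
the modeling scale (log2 for proteins, identity for MWF) — the simplest
model consistent with the linear analyses.

## Problem sizes and verification

The test suite verifies each primitive against an independent oracle
(rational-arithmetic hypergeometric tails; normal-equation OLS plus a
statsmodels cross-check; explicit geometric-mean z recomputation; brute
force nearest-voxel search; midrank Pearson-on-ranks Spearman) and the
statistical properties by Monte Carlo at generator scale: 20-seed null
calibration and planted-recovery sweeps (500 proteins × 85 subjects),
200-seed category and probe-selection recovery, and a zero-noise run in
which the hit lists, selected probe, and spatial r = 1 are recovered
exactly. These sizes keep the default suite under a minute while leaving
the Monte-Carlo margins (≥ 90% / ≥ 95% recovery) far from their observed
rates (~99–100%).

## Known limitations

- Cross-sectional OLS only; no mixed-effects or longitudinal modeling.
- One nTPM reference per run; no multi-reference consensus calls.
- The enrichment stage reproduces Fisher-test ranking semantics, not any
  web service's combined score.
- The spatial stage performs no donor intensity normalization, gene-level
  filtering, or hemisphere mirroring; its null is a raw permutation.
- With ~12 regions the spatial p-value rests on the usual t approximation
  for Pearson r at small n.
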