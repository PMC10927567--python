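# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `trexkit`. It states no empirical result that the test
suite and `scripts/acceptance.py` do not themselves compute.

## Probe design

The designer tiles a target region of length `L` with `n` contiguous,
non-overlapping antisense DNA oligos, where

    n = round-half-up(L / target_len),  clamped to [ceil(L/max_len), floor(L/min_len)]

with defaults `target_len = 60`, `min_len = 30`, `max_len = 90`. The region
is split into windows whose lengths differ by at most 1 nt (longer windows
first), so the clamp guarantees every probe lies within the length band.
Round-half-up is computed in integer arithmetic (`(2L + t) // 2t`) to avoid
float boundary errors at exact halves. This rule reproduces the standard
tiling designs: 3 probes for a 164-nt target, 223 for 13,400 nt. Note that
for small probe counts the mean probe length can deviate from the target
length by up to `target_len/(2n)` — e.g. 54.67 nt for the 164-nt/3-probe
design — which is inherent to even splitting, not an implementation
artefact.

Coverage is complete and gap-free by construction; coordinates are 0-based
half-open throughout. GC content is reported per probe for information
only: no melting-temperature model is used, because annealing in the
targeted-degradation protocol uses a slow 95→50 °C gradient that tolerates
a wide Tm range.

**Off-target screen.** For each probe, the longest exact match between the
probe's sense (target-strand) window and each screening transcript is
computed by k-mer seeding (`seed_k = 12`) with maximal extension: any
common substring of length ≥ k contains an aligned k-mer, so seed extension
is exact above k. When no seed hits, an exact vectorised
dynamic-programming fallback computes the true longest match, so reported
lengths are exact at every scale. A probe is flagged when its longest match
to a non-target transcript is ≥ `flag_len = 18` nt. The 18-nt rule is a
deliberate, configurable stand-in for an unquantified "strong BLAST match"
criterion: 18 exact nucleotides is roughly the length at which an RNA:DNA
hybrid supports RNase H cleavage at the annealing temperatures used.

## Quantification input

MaxQuant-style proteinGroups tables are parsed with explicit conventions:
zeros mean "not quantified" and become missing (never 0.0); rows flagged
Reverse / Potential contaminant / Only identified by site are dropped by
default (standard Perseus practice; `filter_flagged=False` disables);
duplicate protein ids keep the first row with a warning; sample-to-group
assignment comes only from an explicit sample sheet, never from
column-name guessing. LFQ intensity columns are used by default
(configurable via `intensity_prefix`).

iBAQ divides a protein's summed intensity by its count of theoretically
observable tryptic peptides: cleavage after K/R except before P, no missed
cleavages, peptide length 6–30 aa (both bounds configurable). A protein
with no observable peptides has undefined iBAQ rather than infinite.

## Differential release statistics

The chain mirrors the Perseus defaults for label-free enrichment analysis.

* **log2 transform**: present values must be positive (zeros must already
  be encoded as missing); missing stays missing.
* **Filter**: keep proteins with ≥ `min_valid = 3` observed values in at
  least one group. The 3-replicate rule is applied to proteomics as well as
  RNA-seq tables.
* **Imputation**: per sample column with observed mean `m` and standard
  deviation `s` (ddof = 1), missing cells are drawn independently from
  `Normal(m − 1.8 s, (0.3 s)²)`. Downshift 1.8 and width 0.3 are the
  conventional parameters for left-censored proteomics missingness.
  Imputation is per column (each sample's own distribution), deterministic
  given the seed, and refuses columns with fewer than 2 observed values.
* **S0 test**: `d = (mean_A − mean_B) / (se + S0)` with the pooled-variance
  (Student) standard error, not Welch — matching the Perseus default. With
  `S0 = 0` this is exactly the classical two-sample t statistic. p-values
  use the Student t tail at `d` with `n_A + n_B − 2` df; because `d ≤ t`,
  these p-values are conservative approximations and are reported for
  plotting only — significance rests solely on the permutation q.
  Degenerate case: zero difference with zero spread gives `d = 0, p = 1`.
* **Permutation FDR**: group labels are permuted over all `C(n, n_A)`
  distinct label splits when that number is at most `n_perm` (default 250;
  the identity split is included in the exhaustive enumeration), otherwise
  `n_perm` splits are drawn uniformly from the non-identity splits. For
  each threshold c among the observed |d|,
  `FDR(c) = mean_perm #{|d_perm| ≥ c} / #{|d_obs| ≥ c}`, and a protein's q
  is the minimum FDR over thresholds at or below its own |d| (monotone,
  capped at 1). This ratio estimator is a documented stand-in for the
  unpublished Perseus internals (no side-specific cutoffs, no pi0
  correction), so significant-hit counts on real deposited data may deviate
  slightly from Perseus output.
* **Volcano boundary**: a point (x, p) on the volcano implies a standard
  error `se = x / t_p`; the boundary is the contour `|d| = d_cut`, i.e.
  `t_p = x / (x/d_cut − S0)` for `x > d_cut·S0` and unreachable (infinite
  −log10 p) below. `d_cut` is taken from the fitted result as the smallest
  |d| among significant proteins.
* **PCA QC**: principal components of the centred sample × protein matrix
  (full SVD). A replicate is flagged when its (PC1, PC2) distance to its own
  group centroid exceeds 3× the median within-group centroid distance, with
  a small absolute tolerance so exactly-duplicated replicates are never
  flagged. This formalises by-inspection outlier removal; flags are
  advisory and nothing is removed automatically.

`ReleaseEnrichment` / `ReleaseEnrichmentResults` package this chain in a
model/results interface; all steps are also callable individually in
`trexkit.stats_core`.

## Affinity estimation

`Ka = iBAQ_TREX / iBAQ_total` with
`iBAQ_TREX = mean(+RNase H) − mean(−RNase H)`. Missing-value policy (not
specified by the underlying protocol, chosen here): a missing −RNase H iBAQ
is treated as 0 before averaging (no detectable background release); a
protein with no observed +RNase H or total iBAQ, or with non-positive
`iBAQ_TREX`, has undefined Ka and is excluded from ranking — a negative
release estimate is noise, since the quantity models released material.
Ka is scale-invariant (multiplying all iBAQ matrices by a constant changes
nothing) and strictly increasing in the +RNase H abundance. Ka values are
computed for all proteins, not only significant hits; significance is
carried separately.

## Regional integration

Proteins significant in ≥ 1 region form the rows of a t-score matrix; a
retained protein absent from some region's table gets 0 ("no measured
enrichment") plus an explicit absence mask — raw d scores are clustered,
and the (0, 2, 6, 10) colour bins are applied only for display. Clustering
is seeded k-means pre-grouping (default `k = min(300, n/2)`) followed by
complete-linkage Euclidean hierarchical clustering of the centroids; flat
clusters are cut at a requested count or, by default, at the largest gap
between consecutive merge heights. Rows are canonically ordered before
k-means so the partition is invariant to input row order for a given seed.

A protein significant in ≥ `multiregion_min = 3` regions is classified
multiregional; otherwise region-specific with primary region = argmax
t-score (ties broken by region order and recorded). The threshold of 3 is
chosen so that binders spanning a single processing junction — significant
in the two adjacent regions — remain region-specific.

## QC

Relative qPCR expression is `2^−(Ct_target − mean(Ct_housekeeping))`;
housekeeping Cts are combined by arithmetic mean of cycles (geometric mean
of expression). Depletion efficiency is `1 − treated/control`. Melt-curve
corrections for non-specific amplification products are out of scope —
inputs are assumed to be corrected Cts.

The transcriptome specificity test consumes a TPM table processed by the
same log2/filter/impute chain as the proteomics data. Per transcript the
score is `mean(control) − mean(treated)` — the displacement from the
identity line of the group-mean scatter, computed on group means rather
than per-replicate points. The null is a robust Gaussian fitted from the
scores themselves: `sigma = quantile_q(|score − median|) / PhiInv((1+q)/2)`
with `q = 0.95`, so that for Gaussian scores sigma is exactly the null
standard deviation while planted outliers barely perturb it. Two-sided
normal tails are BH-adjusted; transcripts with q ≤ 0.05 are outliers. This
statistic is a documented stand-in for an unpublished "multidimensional
outlier test" and uses exactly the stated 0.95 quantile and BH correction.

## Category enrichment

Two-sided Fisher's exact test per annotation set on the 2×2 table of
hit/set membership over the universe of all quantified proteins (not the
whole proteome), with BH correction across sets; enriched means q ≤ alpha
and odds ratio > 1. The default alpha is 0.02; 0.05 is equally common in
practice and both are exposed. The two-sided p sums all outcomes whose
hypergeometric probability does not exceed the observed one, with the
standard relative-error guard of 1 + 1e-7 for floating-point tie detection
(the R `fisher.test` convention, shared by scipy).

## Synthetic data

The generators emulate a label-free TREX experiment:

* per-protein baseline log2 intensity `mu_i ~ Normal(26, 2.5)` — the
  typical location and spread of log2 LFQ intensities;
* replicate noise s.d. 0.15 log2 units (~11% CV), consistent with the
  replicate reproducibility of LFQ with match-between-runs on deep
  Orbitrap runs;
* release effect `delta = 0.6` log2 units by default — 4 replicate
  standard deviations, the canonical "clearly released" effect size; a
  released protein's delta relates to its true bound fraction f by
  `delta = log2(1 + f)`, since releasing a fraction f of the total on top
  of background multiplies the +RNase H abundance by (1 + f). Setting
  `bound_fraction_range` draws per-protein fractions instead;
* left-censored missingness: `P(missing) = logistic((threshold − value) /
  0.3)` with the threshold at the 15th percentile of all log2 values. The
  slope 0.3 concentrates the 10–90% missingness transition within ~1.3
  log2 units, matching the sharp detection-limit transition of real
  MaxQuant data, and yields ~15% missing values overall;
* iBAQ = intensity / peptide count with peptide counts `1 + Poisson(12)`;
* design: 5 vs 5 biological replicates plus 3 total-lysate replicates by
  default; 3 vs 3 and 4 vs 4 designs are plain config changes;
* the multi-region generator shares baselines across regions, plants
  region-specific binders in exactly one region and multiregional binders
  in 3–5 regions with independently jittered deltas;
* TPM tables are log-normal with treated values divided by the planted
  fold change; qPCR Ct tables invert the 2^−ΔCT estimator exactly at zero
  noise.

All generators are pure functions of config + seed (byte-identical tables
per seed).

**What the generators do not emulate** — and hence what passing tests do
not show about real data: correlated protein abundances (complexes),
peptide-level intensity structure, ratio compression from match-between-
runs, batch effects and chromatography drift, contaminant proteins, and
intensity-dependent (heteroscedastic) replicate noise. Calibration and
recovery results on synthetic data therefore validate the statistical
machinery, not instrument-specific behaviour.

## Validation conventions and problem sizes

The end-to-end checks in `tests/test_acceptance.py` use: null calibration
over 20 seeds of 1000-protein 5v5 tables; power over 3 seeds of the default
50-planted design, with recovery measured among planted proteins that pass
the minimum-valid filter (a protein with fewer than 3 observed replicates
in every group is invisible to any downstream statistic by the filter rule
itself); Ka recovery over a dedicated 200-planted / 800-background design
with bound fractions Uniform(0.05, 0.9), restricted to planted proteins
with complete iBAQ observations and defined Ka — a censored −RNase H cell
is zero-filled by the policy above and would corrupt Ka for proteins below
the detection limit, which is a property of the data, not the estimator;
an 8-region, 300-planted layout with 5% multiregional binders for the
classifier; exhaustive 4-vs-4 enumeration (70 label splits) for the
permutation-FDR oracle; and all 2×2 tables with total ≤ 60 (up to the
symmetries of the table) for Fisher exactness. These sizes keep the full
suite fast while leaving every estimator in its intended regime.

## Known limitations

* The permutation-FDR estimator and the transcriptome outlier statistic
  are documented stand-ins for unpublished Perseus internals; counts on
  deposited datasets may differ slightly.
* The off-target screen uses exact-match length as a hybridisation proxy;
  it does not model mismatched or gapped hybrids.
* p-values attached to the S0 statistic are approximations (see above).
* No batch correction, moderated-variance shrinkage or multi-group ANOVA;
  the analysis is strictly two-group per region.
* The qPCR module assumes 100% amplification efficiency (the exact 2^−ΔCT
  model).
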