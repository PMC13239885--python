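# Methods

`nichesig` implements an analysis chain that links cell subsets defined
in annotated single-cell RNA-seq data — the motivating case is
CD4+CD8+ double-positive T (DPT) cells in hepatocellular carcinoma — to
patient prognosis, treatment response, tissue distribution and spatial
architecture.  This note records the statistical procedures, the
parameters that matter, what the synthetic data generators do and do not
emulate, and the numerical choices made where the design was open.

## Signature derivation

Cells pass quality control when the total UMI count is strictly below
10 000, the detected-gene count lies in [500, 6000] (inclusive at both
ends), and the mitochondrial count fraction is strictly below 5%.  The
strict/inclusive boundaries follow the usual reading of these filters:
"below 10 000" and "below 5%" as open bounds, "ranged from 500 to 6000"
as a closed interval.  Counts are then depth-normalised to 10 000 per
cell and natural-log1p transformed — the de-facto default of the
standard single-cell workflow; no formula beyond that is assumed.

A subcluster's signature is the intersection of two rank-sum
differential-expression comparisons: the subcluster against the other
cells of its own major cell type, and the subcluster against all
remaining cells in the dataset.  A gene enters the signature when, in
*both* comparisons, its Benjamini–Hochberg-adjusted p value is below
0.05 and its log2 fold change exceeds 0.5.  The two comparisons are
adjusted as separate families, mirroring two independent runs of a
marker test.  The fold change is computed on de-logged normalised
values with a pseudocount of 1 in numerator and denominator:
`log2((mean(expm1 x_a) + 1) / (mean(expm1 x_b) + 1))` — the convention
of the common marker-finding tools; because conventions differ between
tool versions, the formula lives in one helper and the thresholds are
arguments, both recorded in the signature's provenance.  Genes are
ordered by descending fold change of the global comparison.

Rank-sum p values use the Mann–Whitney machinery of SciPy: exact
enumeration for small tie-free groups, otherwise the tie-corrected
normal approximation without continuity correction.  Fully tied genes
(identical values in both groups, typically all-zero) have zero rank
variance and are assigned p = 1.  A subcluster that is the only member
of its major type raises an explicit error directing the caller to the
global comparison — the within-type comparison is degenerate and is
never substituted silently.

The risk-gene prioritisation intersects three plain gene-symbol sets
(up-regulated in short-term survivors, univariate Cox risk screen, a
curated set such as cytokines or chemokine receptors).  Matching is
exact and case-sensitive; symbols that would match only after case
folding are reported as unmatched rather than merged, because silent
case-folding hides curation errors.

## Single-sample enrichment (ssGSEA)

For a sample with `N` genes and a set of `m` member genes, genes are
ranked by descending expression and the score is the sum over ranked
positions of the difference between a weighted in-set ECDF and a
uniform out-of-set ECDF:

    ES = sum_k [ cum(w · 1_in)(k) / sum(w · 1_in) − cum(1_out)(k) / (N − m) ]

with weights `w = rank^alpha` (the most expressed gene has rank `N`)
and `alpha = 0.25`, the method's canonical exponent.  The statistic is
the full running sum, not the maximum deviation.  Expression ties are
broken by ascending gene index under a stable sort so that scores are
bit-reproducible.  With `normalize=True` (default) the whole score
matrix is divided by its range (max − min across all samples and
signatures), which rescales but never reorders samples within a
signature; both settings are recorded on the output.  Because the score
depends only on within-sample ranks, it is invariant to any strictly
increasing per-sample transform of expression — a property the tests
assert directly.  Signature genes absent from the matrix are dropped
with a warning; a signature matching nothing, or covering the entire
gene universe (out-of-set ECDF undefined), is an error.

## Survival analysis

Kaplan–Meier estimation uses the product-limit estimator with the
standard convention that subjects censored at an event time remain at
risk for that time.  The two-group log-rank test accumulates
observed-minus-expected deaths with the hypergeometric variance and
refers the squared standardised sum to chi-square(1).

The Cox proportional-hazards fit maximises the Efron-corrected partial
likelihood by Newton iterations with step-halving, declaring
convergence at gradient sup-norm below 1e-8 and failing after 50
iterations.  Two failure modes are distinguished: plain non-convergence,
and monotone likelihood (perfect separation), detected by a coefficient
diverging past |beta| = 50 on the standardised scale.  Continuous
covariates are standardised to mean 0, SD 1 by default so hazard ratios
read "per 1 SD"; 0/1 covariates (sex, treatment, HBV status) are left
unscaled so their ratios stay per-category.  Scaling is applied in both
univariate and adjusted models for comparability, and the choice is
stored on the fit.  Wald 95% intervals and p values are reported; the
univariate per-gene screen BH-adjusts across genes and flags each gene
risk (HR > 1) or protective (HR < 1), reporting rather than dropping
genes that fail to converge.

The optimal cutpoint is the maximally selected rank statistic: every
midpoint between consecutive distinct score values whose induced split
keeps at least `minprop = 0.1` of the samples on each side is scored by
the standardised log-rank statistic, and the threshold maximising its
absolute value is returned, ties resolving toward the smaller
threshold.  The log-rank p of the induced split is flagged as
selection-biased — the threshold was chosen to maximise exactly that
statistic — and a seeded permutation-corrected p (scores permuted
against the survival data, the max-statistic recomputed) is available.

For survival-group labels on synthetic cells, patients dying within 24
months are "short-term" survivors and patients followed beyond 24
months "long-term" — the conventional two-year dichotomy for this
disease setting.

## Tissue preference

The primary statistic is Ro/e, the cell of the chi-square decomposition
of a subsets × strata contingency table: `expected(i,j) = row_i total ×
col_j total / grand total`, ratio = observed / expected.  Ratios above
1 mark over-representation.  By construction the column-total-weighted
mean of each row's ratios is exactly 1, an invariant the tests assert.
Cells are pooled across patients, matching the pooled-count convention;
as a complementary strategy guarding against a few patients dominating
the pooled table, per-patient subset fractions are compared across
survival groups by rank-sum.  Survival-group enrichment within one
tissue is summarised as the 2×2 odds ratio (subset vs other cells,
short vs long survivors) with the Haldane–Anscombe 0.5 correction when
any cell is zero (flagged in the output), Fisher-exact p up to 10^4
cells and chi-square beyond.  The odds-ratio reading of "relative
enrichment between survival groups" is an interpretation — the heatmap
convention it mirrors has no closed-form definition — and is labelled
as such in the output provenance.

## Spatial niches

Spot scores are plain sums of the signature genes detected in the grid,
on raw stored values (a per-spot depth-normalisation option exists but
is off by default, since binned data are typically summed raw).
High-enrichment seeds are spots scoring strictly above the 97.5th
percentile of all spots, with the percentile computed by linear
interpolation between order statistics (the common "type 7" default);
the strict inequality means an all-equal score vector yields no seeds.
Each seed is dilated by Chebyshev distance 1 — the 3×3 coordinate
window on integer bin indices — and the union over seeds, restricted to
coordinates that exist in the grid (tissue boundaries leave holes, not
errors), forms the niche.  The association test compares the target
signature's spot scores between niche and non-niche spots with a
two-sided Mann–Whitney test after excluding, from both groups, spots
whose target score is not strictly positive (the inclusion rule applies
to spots as such, not to one group).  When several context niches are
tested, unadjusted and BH-adjusted p values are both reported.

## Synthetic data

The generators plant exactly the structure the downstream stages assume
and nothing more.

*Single cell.*  Counts are negative binomial in the mean/size
parameterisation (variance = mu + mu²/size), with per-gene baseline
means drawn once from a gamma distribution around `baseline_mean = 0.5`
and `dispersion = 2` — values giving roughly 500–1500 UMI and several
hundred detected genes per cell at 2000 genes, a realistic droplet-data
regime that also exercises the QC filters.  Each subcluster's marker
genes (disjoint blocks by construction) have their means multiplied by
the planted fold inside that subcluster only.  Cells are assigned
round-robin to 3 pseudo-patients per survival group, enabling
per-patient analyses without modelling patient effects.  Not emulated:
batch effects, doublets, ambient RNA, patient-level random effects —
passing tests therefore show correctness of the statistics, not
robustness to those artefacts.

*Bulk cohort.*  A per-sample latent factor (shifted by
`response_effect` SD in responders) loads log-linearly on the signature
genes of an otherwise lognormal FPKM-like matrix.  The planted score is
then *defined* as the standardised mean expression of the signature
genes, and event times are exponential with rate `baseline_hazard ·
exp(log_hr_per_sd · score)` — so the proportional-hazards property
holds exactly for the realised score and Cox recovery is a genuine
parameter-recovery check.  Censoring is an independent exponential
clock (`baseline_hazard = 1/40`, `censor_rate = 1/80` per month,
censoring roughly a third of samples); administrative censoring and
informative dropout are not modelled.

*Spatial grid.*  Every bin of a `width × height` lattice (40×40
default) is a spot.  Each signature owns a set of discs (3 discs of
radius 4 by default) inside which its genes' NB means rise from
`background_mean = 1` to `niche_mean = 3` (`dispersion = 10`).
`colocalization` is the fraction of a later signature's disc centres
that reuse the first signature's centres; unshared centres are placed
uniformly at random, *independently* of the other signatures.
Independence — rather than mutually exclusive placement — is deliberate:
excluding one signature's discs from another's admissible area induces
negative spatial dependence between the fields, so a "no association"
simulation would not actually satisfy the null hypothesis the
Mann–Whitney test evaluates.  For the same reason the type-I
calibration study uses a target signature with *no* planted discs (flat
background): niche membership is then independent of the iid target
scores and the nominal level is the correct reference.  A target with
its own discs placed independently of the context is *not* a calibrated
null — both fields are spatially clustered, and a clustered selection
of a clustered field overdisperses the rank statistic.  This is a known
limitation of niche-vs-rest rank tests on real tissue too: spatial
autocorrelation inflates their effective significance, which is why the
co-localisation conclusions should rest on effect sizes and replication
across sections, not on the p value alone.

## Verification strategy

Deterministic primitives are checked against independent oracles that
share no code with the implementation: a direct loop evaluation of the
running-sum score (agreement to 1e-9 on random instances), brute-force
Chebyshev enumeration for the window dilation, exhaustive-search
cutpoint selection using an external log-rank implementation, the
external Cox fitter for Efron-tied coefficients (1e-6), and hand-
enumerable rank statistics (the 3-vs-3 exact p = 0.1; the two-subject
log-rank chi-square = 1).  Stochastic behaviour is checked by seeded
simulation at stated sizes: Cox recovery of HR 2 per SD (n = 500, 100
replicates), log-rank type-I over 2000 null cohorts, niche type-I over
200 null grids, marker recovery over 20 planted datasets, and
co-localisation power over 100 grids.  `scripts/acceptance.py` reruns
all of these from scratch under a caller-supplied seed.

## Known limitations

- The Cox layer has no time-varying covariates, competing risks, or
  proportionality diagnostics.
- Ro/e pools cells across patients; the per-patient complement is a
  rank test on fractions, not a mixed-effects abundance model.
- The niche test treats spots as exchangeable units; it does not model
  spatial autocorrelation (no Moran's I or spatially-aware nulls).
- Signature derivation consumes provided cluster labels; clustering,
  annotation, doublet removal and integration are out of scope.
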