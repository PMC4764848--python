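# Methods

This note documents the models and procedures `hybridmet` implements,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Study design and domain objects

The workflow targets a *complete diallel without selfs*: n inbred
parents crossed in every ordered combination, n(n−1) hybrids, each
unordered pair present in both reciprocal orientations (A×B and B×A
differ only in the cytoplasm donor). Parents carry a subspecies label
(indica/japonica) and optionally an indica-content fraction F_i in
[0, 1] supplied as input. Hybrids are labelled i, j, or ij according to
their parents' groups. The canonical orientation of a pair is ascending
parent position in panel order; the `pair_key` (sorted ids joined by
`|`) is shared by reciprocals.

## Preprocessing

Relative metabolite levels are analyte peak area divided by the ribitol
internal-standard area *of the same replicate run*; this cancels any
per-run scale factor exactly (scale equivariance is tested). Replicates
are averaged on the relative scale, then the matrix is log2-transformed
for the structural analyses. The order matters — mean-then-log is an
arithmetic mean, log-then-mean a geometric one — and the pipeline fixes
mean-then-log: averaging physical quantities precedes the variance-
stabilizing transform. Pair encodings are computed on the *untransformed*
mean-stage levels, since the sum/difference/ratio formulas are defined on
relative levels; the log2 matrix feeds distance, clustering and PCA.
Missing cells are a hard error (no imputation): the workflow presumes a
panel in which every analyte was detected in every line. Duplicated
annotations are suffixed `-1`, `-2`, ... by ascending retention time;
ties fall back to column order with a warning.

## Heterosis and combining ability

Per hybrid and trait: LPH = (F1 − P_low)/P_low, MPH = (F1 − P_mean)/P_mean,
BPH = (F1 − P_high)/P_high, dimensionless. For heading date, earlier
heading is favorable, so the computed values are negated (toggle
`hd_sign_flip`). GCA is reported on the conventional scale
GCA_i = P_i· − P··, with P_i· the mean over all hybrids containing
parent i in either role. SCA is the residual of the additive
least-squares fit to the no-self diallel:

    SCA_ij = P_ij − P·· − g_i − g_j,   g_i = (n−1)/(n−2) · (P_i· − P··).

The (n−1)/(n−2) factor corrects for the missing diagonal; without it a
purely additive table (P_ij = g_i + g_j) has nonzero "SCA" and the
per-parent SCA sums equal GCA_i rather than zero. With it, ΣGCA = 0 and
Σ_j SCA_ij = 0 hold exactly on any complete diallel (tested at 1e-10
relative on 200 random tables). Incomplete diallels are tolerated with
cell-mean estimators and a warning; the zero-sum identities then hold
only approximately.

## Feature encoding

For each unordered pair with canonical values (a1, a2) per analyte:
sum = (a1+a2)·0.5, difference = a1−a2, ratio = a1/a2. One row per pair;
reciprocal hybrids map to that single row (`duplicate` mode aligns one
design row per ordered hybrid with its own response; `average` mode
collapses to one row per pair with reciprocal-averaged response).
Ratio-only is the default encoding — it is the one with predictive
power in this workflow — giving 525 features at the default analyte
count. The canonical orientation is an arbitrary but fixed convention;
the reciprocal-set evaluation quantifies that it is inconsequential.

## Population structure

Metabolic genetic distance is squared Euclidean distance on the log2
matrix. Hierarchical clustering uses unweighted average linkage,
implemented directly (naive O(n³), n is a parental panel) so the tie
rule is contractual: among minimum-distance cluster pairs the
lexicographically smallest merges first. It is cross-checked against
scipy's average linkage on tie-free fixtures. PCA is an
eigendecomposition of the column correlation matrix (standardized
columns, no rotation); components with eigenvalue > 1 (Kaiser rule) are
retained. An iteration cap is a factor-analysis software artifact and is
not needed by a direct eigensolver.

## PLS regression and VIP selection

Single-response NIPALS PLS1 on autoscaled data (centering + unit
variance; coefficients are back-transformed, so prediction equations are
on the original feature scale). One model per response — 15 in the
standard run: three traits per se, LPH/MPH/BPH and SCA for each.
Multi-response PLS would force one latent number on all traits, which
the per-trait selection contradicts.

Latent number: fit up to k_max = min(n−1, p) factors once (deflation
makes the k-factor model a prefix of the k_max-factor model), compute
training R² per k and adjusted R² = 1 − (1−R²)(n−1)/(n−k−1), and keep
the smallest k attaining the maximum adjusted R² (parsimony on ties).
Extraction stops early when X or the response deflates to numerical
zero (relative tolerance 1e-12), e.g. on rank-deficient designs.

VIP of Factor 1: VIP_j = √p·|w_j1|/‖w_1‖. Its mean square is exactly 1,
making 1 the natural retention threshold; filtering keeps VIP ≥ 1
(boundary retained) and re-runs latent selection on the reduced design.
A cumulative, variance-weighted VIP over all fitted factors is exposed
as an alternative mode but is not the default. A second filtering round
is available by calling `filter_vip` again; it is not a default stage.
A leave-one-out Q² diagnostic exists but never drives selection.

Reported predictive ability is the *in-sample* Pearson correlation
(2-tailed p) between fitted and observed values — a training-set
statistic, stated as such everywhere. Predictions are computed once per
unordered pair and expanded to ordered hybrids, so reciprocal hybrids
receive bit-identical predictions in duplicate mode.

## Baselines

Parental-trait regression correlates one sum/difference/ratio encoding
of the parents' own phenotype with the hybrid trait and fits a
one-variable line. Stepwise regression is the SPSS-style
probability-of-F loop: forward entry of the smallest partial-F p-value
when ≤ 0.05, backward removal when ≥ 0.10, nested-model F tests from
residual sums of squares, ties to the lowest column index, an
oscillation guard (a variable bouncing in and out twice stops the loop),
and candidates that would collapse the design rank are skipped with a
warning.

## Synthetic-data generator

The generator emulates the study the pipeline is built for: 18 parents
in two groups of 9 (F_i drawn in 0.39–1 for indica, 0–0.33 for
japonica), 525 analytes, 3 replicate runs, 306 hybrids. Abundances are
log-normal: per-analyte base level uniform on log[1e4, 1e6], parental
biological effects with natural-log sd 1.2 (≈ 3× typical line-to-line
spread, in range for GC-MS metabolites across diverse germplasm),
multiplicative replicate noise (log-sd 0.1), positive ribitol areas per
run. A random 30% of analytes carries an indica-vs-japonica offset
(log-sd 1.0), which is what makes clustering and PCA separate the
groups; with the offset set to zero that structure disappears (tested).

Hybrid traits follow

    P_fm = μ_t + Σ_k β_k·ratio_k(pair) + gca_f + gca_m + sca_pair
           + rec_fm + ε,

with trait baselines μ = 40 g (YPP), 110 cm (MSPH), 100 d (HD). The
causal set (default 10 analytes per trait) is drawn from the half of
the analytes *least* differentiated between groups, subject to pairwise
|correlation| ≤ 0.10 among their ratio features. Both constraints are
identifiability conditions, not conveniences: with 18 parents the 525
ratio features are strongly collinear (near rank-17 in their linearized
form), and an unconstrained sparse "truth" is not recoverable by any
marginal-importance measure; group-neutral causal features additionally
keep prediction quality from merely recapitulating population
structure. Coefficients are ±Uniform[1, 2] on the unit-variance ratio
scale times a per-trait scale (1, 3, 2 trait units). GCA, SCA and
reciprocal effects are Gaussian with sds expressed as fractions of the
causal-signal sd (defaults 0.2, 0.1, 0 respectively). Residual noise is
calibrated so the ratio-feature signal explains `target_r2` (default
0.9) of the hybrid trait variance; setting `noise_sd` (and the gca/sca
sds) to zero puts the trait exactly inside the ratio-linear model
class, which the pipeline then fits to machine precision. All
randomness flows from one seed through a single generator.

What passing synthetic tests does *not* show about real data: real
metabolite-trait relations are not sparse-linear in ratios, real traits
have genotype-by-environment noise structure the Gaussian ε lacks, and
the generator omits chromatographic artifacts, retention drift and
missing peaks entirely. The tests certify the *machinery* — formulas,
selection logic, stratification, determinism — not field performance.

## Numerical choices and limitations

- NIPALS tolerances 1e-12 (relative) for weight/score/residual
  collapse; score orthogonality is asserted at 1e-8 on every fit, and
  k = rank(X) fits match least squares at 1e-8.
- Zero-variance predictor or PCA columns are dropped with a warning;
  constant responses are errors; constant vectors in correlations are
  reported as undefined rather than raised.
- CSV I/O is comma-separated UTF-8 with header, `.` decimal,
  `float_precision="round_trip"` on read, so write-then-read reproduces
  tables bit-exactly.
- Problem sizes in the default test and acceptance runs: full-scale
  studies (18×525, 306 hybrids) for end-to-end checks, 20 seeds for the
  recovery study; unit fixtures are 2–8 parents and ≤ 40 analytes.
- In-sample evaluation mirrors the workflow's definition of predictive
  ability; no cross-validated ability scheme is provided, by scope.
- Benjamini–Hochberg adjusted p-values accompany the metabolite–trait
  screen for transparency but gate nothing.
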