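# Methods

This note documents the models, defaults, and design choices behind
`lupusmod`, in the spirit of a package vignette: what each stage assumes,
which knobs matter, and what the synthetic cohorts do and do not emulate.

## Enrichment engine

The per-sample module score is a two-stage nonparametric statistic on a
genes × samples log2 expression matrix.

**Gene-level statistic.** For gene *i* in sample *j*,
`z_ij = Σ_k Φ((x_ij − x_ik)/h_i)`, the Gaussian-kernel estimate of the
within-gene expression CDF evaluated at sample *j*, scaled by N. The
bandwidth is `h_i = s_i/4` (sample SD of the gene), the convention of the
original gene-set variation method for continuous microarray intensities.
`z` is monotone in the expression value and invariant to per-gene location
and scale, which removes gene-specific dynamic range before ranking.
Zero-variance genes receive a bandwidth floor of 1e−8 (with a warning)
rather than exclusion, so the gene universe — and therefore the walk length
N — is identical for every sample.

**KS-like walk.** Per sample, genes are ranked by `z` descending; ties are
broken by gene-identifier lexicographic order, making scores invariant to
row permutations of the input. With symmetric rank weights
`r_l = |N/2 − l|^τ` (τ = 1 by default, the standard weighting),
walking down the list adds `r_l / Σ_{g∈G} r^τ` for module genes and
subtracts `1/(N − m)` otherwise. The default score is the sum of the
largest positive and largest negative walk deviations, each taken as zero
when the walk never crosses that side; this "magnitude difference"
statistic is bounded in [−1, +1] and is near zero for modules with no
coherent expression shift. A `mode="extreme"` flag returns the single
deviation of largest magnitude instead. The walk statistic itself is the
reported score; no cohort-level rescaling is applied afterwards. A module
covering the whole universe is rejected (the complement term is undefined),
and an unmeasured module is omitted with a warning rather than scored.

The implementation is vectorized but is verified in the tests against an
independently coded O(N) loop oracle to machine precision for N ≤ 50, and
bound/antisymmetry properties are fuzz-tested.

## Signature calls and group comparisons

The "normal range" per module is the HC mean ± 1 SD (sample SD, n−1
denominator) over the control columns; the default pools all supplied
controls into one range (a per-stratum range is obtained by fitting on a
subset), and the range object records the HC sex when given, since male
reference panels should be used for male analyses. Scores strictly above /
below the range call +1 / −1; boundary scores call 0 (only strict
exceedance is abnormal), so under a Gaussian null the non-zero call rate
converges to 2·(1 − Φ(1)) ≈ 31.7%, which the tests confirm by simulation.
Call frequencies per group are compared with two-sided Fisher's exact tests
(scipy), and score distributions with Welch's unequal-variance t using the
Welch–Satterthwaite df. Tukey's multiple-comparison test is not reimplemented; this package
provides Sidak-adjusted Welch contrasts (`1 − (1 − p)^m` over the
group-pair family per module) as the documented multiple-comparison
procedure.

## Moderated differential expression

Two-group DE uses the standard empirical-Bayes moderated t for array-style
data: per-gene pooled variance `s²_g` on `d = n₁ + n₂ − 2` df; prior
`(d₀, s₀²)` estimated by moment-matching the log-variance distribution
against a scaled log-F (digamma/trigamma closed forms, Newton inversion of
the trigamma); posterior `s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d)`; t on `d₀ + d`
df. The global-prior variant is implemented; an intensity-dependent
("local"/trend) prior is out of scope. Edge behavior: `d₀ = 0` recovers the
ordinary pooled t; when the between-gene spread of log-variances does not
exceed trigamma sampling noise the prior df is infinite and the common
variance is pooled with a warning. The test suite cross-checks t, p, and
fold changes against the reference R/Bioconductor empirical-Bayes
implementation on a shared fixture (agreement to ~1e−8 relative).

BH FDR adjustment is delegated to statsmodels (`fdr_bh`) behind
`bh_adjust`. The randomized-split null control re-runs the moderated t on a
random balanced half-split of a single group: on homogeneous data the
expected DEG count at FDR < 0.05 is zero in the large majority of seeds,
the negative control confirming ancestry contrasts are not splitting
artifacts. Gene-list
overlap significance is the two-sided Fisher test on the 2×2 membership
table over an explicit gene universe; the reported OR is the sample
(cross-product) odds ratio.

## SNOR derivation

"Patients that PCA does not separate from controls" is operationalized as:
compute the top principal component of the centered log2 matrix over
HC + SLE (covariance scaling: expression is
already on a common log2 scale, so no per-gene rescaling is applied);
select SLE samples whose PC1 coordinate lies within the HC min–max range
(configurable to a PC1–PC2 box). A moderated-t comparison of the selected
subset vs HC at FDR < 0.005 then yields the 7 most increased and 7 most
decreased transcripts ranked by log2 fold change — extremity is defined by
fold change, not by p. Short lists are returned unpadded with
a warning; provenance (selected IDs, parameters) is emitted as JSON.

## Stepwise logistic framework

Outcomes are binary indicators of a +1 call (or of a −1 call for "low"
signature outcomes; which outcomes are "low" is configurable metadata).
The 26 predictors: 3 ancestry indicators; 7 drugs (corticosteroids,
antimalarials, NSAIDs, AZA, MTX, MMF, cyclophosphamide); 5 manifestations
(rash, arthritis, mucosal ulcers, vasculitis, alopecia); 4 mutually
exclusive autoantibody-combination groups (RNP⁺dsDNA⁺, RNP⁺dsDNA⁻,
RNP⁻dsDNA⁺ — each possibly carrying Sm/SSA/SSB — and Sm/SSA/SSB-only) plus
low C3 and low C4; age > 50; 4 disease-duration bins (≤1y, 1–5y, 5–10y,
>10y). Collinearity screening computes tie-corrected Spearman rho for all
pairs and flags the later-listed column of any pair with |rho| > 0.5
(the rule under which a redundant Hispanic-ethnicity indicator would be
removed against NAA, the motivating case for the 0.5 threshold).

Selection is forward-by-Rao-score-test, backward-by-Wald — the SAS stepwise
convention — with entry and stay thresholds both 0.05 (the SAS stepwise
default, the documented choice here). The score test needs only the current null fit,
which keeps candidate scans cheap; duplicate or non-informative candidates
get p = 1 (no information gain). The final model is refit by ML
(statsmodels Logit) with Wald ORs and 95% CIs, and gated by the
Hosmer–Lemeshow decile-of-risk chi-square (g = 10 groups by fitted-
probability quantiles, ties kept together, df = groups − 2). Models with
HL p < 0.05 are marked discarded; the gate threshold is a documented
default, configurable per run. Perfect separation and
singular designs raise errors naming the offending predictor.

For display, ORs map to edges: OR < 1 becomes 1/OR with negative direction,
and width follows the display-OR intervals [1,2)→1pt, [2,3)→5pt,
[3,10)→10pt, [10,∞)→20pt (half-open intervals applied to the display
OR). The mapping is reciprocal-symmetric by construction.
Simple per-variable OLS (`simple_linear_fit`) reports slope, intercept, and
R² as the per-variable predictive value.

## Classification

The native engine minimizes mean logistic loss + `l1·‖β‖₁ + (l2/2)·‖β‖₂²`
on per-gene standardized inputs (delegated to scikit-learn with the exact
penalty reparameterization; a fixed solver seed makes coordinate updates
deterministic). A linear SVM engine plugs in behind the same contract; the
original SVM-vs-GLM accuracy comparison on the real cohorts is not
reproduced here. Evaluation protocol: stratified k-fold
(k = 10 default) assignment, standardization fit on training folds only,
out-of-fold class probabilities pooled for a single ROC/AUC (per-fold
averaging is available as a flag-equivalent by consuming `fold_metrics`),
and per-fold sensitivity/specificity/accuracy at threshold 0.5 averaged
across folds. AUC is computed by an explicit threshold sweep with
simultaneous tie steps and equals the normalized Mann–Whitney U statistic
(asserted in the tests). Gene importance is |coefficient on standardized
inputs| (the documented importance definition), with lexicographic tie-breaks for a stable top-25.

## Synthetic cohorts

The generator emulates: per-ancestry Bernoulli flags for 5 autoantibodies,
low C3/C4, 7 drugs, 5 manifestations, age > 50, and duration bins; SLEDAI
drawn as 6 + Poisson(4) for patients (the trial floor of 6) and 0 for
controls; and log2 expression as per-gene uniform baselines (means in
[6, 10], SDs in [0.3, 0.8]) plus additive module-level log2 shifts for
covariate carriers plus per-gene Gaussian noise. Default sizes are the
study's: 216 AA / 1118 EA / 232 NAA female patients and 17 female HC.
Default flag frequencies reproduce the printed rates (RNP 62/30/51%,
Sm 24/12% for AA/EA; corticosteroids 70/70/92%); where only composites are
printed, the per-flag defaults were solved once so independent draws
reproduce them: dsDNA (50/58/62%) × low-complement (C3 35/38/45%, C4
17/19.4/26.7%) gives the printed dsDNA-with-low-C joints 23/29/37%, and
the individual immunosuppressive rates give P(any IS) = 39/39/58%. Values
with no printed anchor (Sm in NAA 20%, SSA/SSB, NSAIDs 30%, vasculitis 5%)
are fixed plausible rates for an active-SLE trial population, chosen once
and documented here. Autoantibody flags are drawn independently per
antibody — the joint dependence structure is not reported — and joint
serology-group frequencies can be specified directly instead.

Effect magnitudes (0.2–0.8 log2 units on module genes) are artifact
defaults whose signs encode the reported directions: corticosteroids raise
LDG/granulocyte/monocyte/anti-inflammation signatures, MTX/MMF lower
plasma-cell/Ig, AZA lowers NK / cytotoxic T / B cells, RNP⁺dsDNA⁺ serology
raises IFN/plasma-cell/cell-cycle/Treg, AA ancestry raises the B cell axis
and lowers myeloid signatures. Effects are additive on the log2 scale and
uniform across a module's genes; optional per-gene heterogeneity
(`per_gene_effect_sd`) is off by default. The 34 default modules (~720
synthetic gene symbols, with small deliberate overlaps between LDG/
granulocyte and activated-T/T-cell) are synthetic stand-ins for the study's
module GMT, which is consumed as input when available.

What the simulator does **not** emulate: probe-level structure, platform/
batch artifacts, heavy-tailed noise, gene–gene correlation beyond module
co-shifts, and autoantibody dependence. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of planted
structure — not performance claims about real cohorts; in particular the
real-data headline numbers (e.g. 96–97% SVM accuracy, the cohort ORs) are
functions of the original controlled-access cohort data and are outside what synthetic cohorts can
certify.

## Numerical choices and problem sizes

Gene statistics are computed in gene chunks (512) to bound pairwise-matrix
memory. Logistic convergence: relative log-likelihood tolerance 1e−8, 100
iterations; elastic-net tolerance 1e−6. Coefficients |β| > 15 on binary
predictors are treated as separation failures. HL groups with numerically
zero expected counts merge into a neighbor with df adjustment. The
acceptance-style simulations use desk-scale sizes chosen as the package's
own defaults — 2,000 genes × 60 samples for score bounds, 10,000 genes for
moderated-t calibration, 500 replicates for stepwise null selection, 250
replicates at n = 2000 for Wald coverage — sizes at which the binomial
noise of each check is comfortably below the asserted tolerance.

## Known limitations

- The stepwise score/Wald loop matches the SAS convention but not SAS
  tie-breaking verbatim; a likelihood-ratio entry option is not yet wired.
- The "local" (intensity-trended) empirical-Bayes prior is a stub; only the
  global prior is implemented.
- One-vs-rest multiclass classification and hyperparameter search are
  intentionally out of scope.
- `derive_snor_modules` assumes the first one or two principal components
  capture the HC/SLE separation; pathological designs where separation
  appears in deeper components will select too many samples.
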