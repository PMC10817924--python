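# Methods

`crcdiet` implements an analysis chain linking food-frequency dietary
patterns, untargeted plasma metabolite profiles, and colorectal-cancer
(CRC) risk in individually matched 1:1 case–control pairs. Because cohort
data of this kind are not publicly shareable, the package ships a
synthetic-data generator that reproduces the *structure* of such a study
with known planted truth; every statistical guarantee quoted for the
pipeline is a statement about recovery of that truth.

## Synthetic cohorts

`simulate.generate_cohort` draws `n_pairs` matched pairs. Matching
factors (sex, sub-cohort, age) are drawn at pair level and are therefore
exactly equal within a pair. FFQ data arise from a linear latent-factor
model: each participant has independent standard-normal scores on the
planted dietary factors; a food's propensity is the loading-weighted sum
of scores plus Gaussian noise (default SD 0.6), standardised and cut at
fixed quantile points into the 9-level ordinal frequency scale
("never" … "≥ 4 times/day"). The fixed cut points make the
discretisation identical across seeds and keep the correlation structure
recoverable by factor analysis. Amounts (g/day) are frequency/day times a
deterministic per-food portion size; calcium and fiber totals are supplied
as precomputed columns (food-composition lookups are out of scope).
Lifestyle covariates (BMI, smoking, activity, education), total energy
and alcohol intake are drawn with marginals resembling a middle-aged
Scandinavian screening cohort; roughly 9% of participants are alcohol
non-consumers.

Case status is assigned *within* each pair by a Bernoulli draw with the
exact conditional-logistic probability
`exp(β'x₁) / (exp(β'x₁) + exp(β'x₂))`, where β are the planted per-SD
log-odds on standardised exposures. The generator is therefore exactly
the model the risk module fits, which is what makes confidence-interval
coverage a meaningful calibration check. Tumour site (proximal/distal
colon, rectum, rarely unknown) is assigned per pair; site-specific
log-odds can be planted to exercise the stratified analyses.

`generate_metabolome` produces log-normal feature intensities; planted
feature–exposure links add `effect × standardised exposure` on the log
scale, which makes the link monotone by construction. Pooled-QC (sQC)
injections replicate the mean study profile with multiplicative technical
noise of CV 0.10 (so realised per-feature QC CVs sit near 10%), inserted
every `qc_every` study samples. Missingness is MCAR on study cells only.
The generator makes no claim of distributional realism for intakes or
intensities — only structural fidelity (matching, ordinal scale, QC
replication, monotone links, conditional outcome model). Consequences:
passing tests demonstrate correct *recovery of planted structure*, not
robustness to intensity-dependent missingness, batch drift, or FFQ
measurement error, none of which are simulated.

## Diet preparation

Frequencies map to per-day values via a fixed monotone table; the scale
endpoints are 0/day and 4/day, the seven interior values (0.017, 0.067,
0.143, 0.357, 0.714, 1, 2.5) follow common FFQ conventions and are
configurable. Energy adjustment uses the energy-density method, intake
per 1000 kcal (kcal, not MJ, because energy is carried in kcal/day
throughout). A priori components are plain sums of constituent food
amounts, with duplicated constituents counted once. The alcohol covariate
has three levels — zero intake, and below/above the sex-specific median
of non-zero intakes — with values exactly at the median classified
"below" (an arbitrary, documented, configurable tie rule).

## Data-driven patterns

Pattern derivation combines exploratory and confirmatory factor analysis
in a repeated random half-split design (default 5 splits, factor counts
2–18; the analyses here use 2–6 because the synthetic scenarios plant at
most four factors):

1. **EFA** (`factor.efa_ml`): maximum-likelihood factoring of the sample
   correlation matrix, profiling the loadings out of the likelihood and
   optimising the uniquenesses by L-BFGS-B (bounded below at 0.005;
   hitting the bound raises a Heywood warning and flags the solution).
   Factor counts with negative model degrees of freedom are rejected as
   degenerate rather than silently fitted.
2. **Oblimin rotation** (`factor.oblimin_rotate`): oblique
   gradient-projection iteration minimising the oblimin criterion
   (γ = 0, direct quartimin — the conventional default). Column signs are
   fixed so each factor's largest-|loading| entry is positive, making
   solutions platform-reproducible. k = 1 is the identity.
3. **CFA** (`factor.cfa_fit`): foods with |loading| > 0.3 become the
   indicators of each factor; the confirmatory model (factor variances
   fixed at 1 so loadings are comparable, oblique factor correlations
   via a tanh parametrisation, log-parametrised uniquenesses) is fitted
   by minimising the ML discrepancy with an analytic gradient. Fit is
   summarised by CFI, TLI, RMSEA and SRMR against the independence
   baseline. Factor scores use the regression (Thurstone) method and have
   exactly zero mean.
4. **Stability** (`patterns.stability_select`): CFA fitness is combined
   into one scalar — the mean of (CFI, TLI, 1−RMSEA, 1−SRMR) — and
   averaged over splits per factor count; factor counts within
   `plateau_tol` (default 0.02) of the best form the plateau. A scalar
   rather than a rank average is used so that "similar fitness" can be a
   tolerance on a fixed scale. Candidate factors from plateau solutions
   are matched across splits (and across factor counts) by absolute
   Tucker congruence φ ≥ 0.85; the congruence threshold operationalises
   "the same construct appeared again" and is configurable. Constructs
   present in **every** split form the stable pattern set; a final CFA on
   all participants yields the participant scores used downstream. An
   empty pattern set is an explicit result, not an error.

Half-splits are simple random 50/50 at participant level (matching is
ignored during pattern discovery, which operates on individuals). The
final scores come from the single all-participant CFA, not from averaging
half-fits.

## Risk models

For 1:1 matched pairs the conditional likelihood reduces to no-intercept
logistic regression on within-pair covariate differences; `risk.fit_clogit`
fits exactly that (Newton, via statsmodels), which is the exact
conditional MLE. The equivalence with a generic conditional-likelihood
maximiser is enforced in tests. Exposures are standardised to unit SD
over all analysed participants (cases + controls, after pair-completeness
filtering; the controls-only alternative can be had by pre-scaling), so
ORs are per 1-SD increase. Adjustment covariates: BMI and total energy
continuous; smoking, activity, education and the 3-level alcohol category
as indicator contrasts with the first level as reference. Pairs with any
missing covariate are dropped whole. When the exposure is itself alcohol,
the alcohol covariate is excluded. CIs are Wald (±1.96·SE from the
observed information), α = 0.05, no multiplicity correction — the
analyses are exploratory by design. Covariate contrasts that are constant
or collinear within the analysed pairs are dropped before fitting so that
sparse strata remain estimable; an exposure with no within-pair contrast
returns OR = 1 exactly with an infinite CI. If no finite maximiser exists
(complete separation) the fit raises with a diagnostic.

`risk.stratified_analysis` partitions pairs by sex (pairs are
sex-matched, so the sex strata partition all pairs) and/or by the case's
tumour site (unknown-site pairs are excluded from site strata). Strata
with fewer than 10 pairs are returned flagged `stable=False` rather than
suppressed.

## Metabolite preparation

`metabolites.cv_filter` computes per-feature CV = sd/mean over sQC
injections on the raw intensity scale (the conventional definition; a
log-scale CV can be had by transforming first) and keeps features with
CV ≤ 0.30 by default. Features whose sQC mean is zero are removed with
reason "undefined CV". Filtering is idempotent and monotone in the
threshold. `metabolites.rf_impute` is a missForest-style scheme: missing
cells start at feature medians; features are revisited in order of
increasing missingness, each regressed on all others by a random forest
(default 100 trees, seeded) trained on its observed rows; iteration stops
when the normalised change in the imputed cells increases (the previous
iterate is kept) or after `max_iter = 10`. Observed cells are never
modified, bitwise. Positive- and negative-mode features are processed
jointly under RP_/RN_ id prefixes.

## Diet–metabolome models

`dietmetab.rdcv_rf` is a repeated double (nested) cross-validation around
random-forest regression with recursive variable elimination: outer folds
are held out entirely; within each outer training set, an inner CV
evaluates a shrinking ladder of feature counts (keeping `var_ratio` of
features per step, ranked by accumulated forest importance), and the
smallest count attaining the minimum inner validation error — the
minimal-optimal size — is refitted on the whole outer training set to
predict the held-out fold. Q² = 1 − PRESS/TSS on the out-of-fold
predictions, averaged over repetitions. Because held-out samples never
touch tuning or training, Q² is an honest predictive estimate; on null
data its mean is ≤ 0. The consensus selected set contains the features
chosen in at least half of the outer-fold models. Reference defaults are
10 repetitions, 6 outer and 5 inner folds, elimination ratio 0.75 and
300 trees; the desk-scale analyses and tests use smaller, explicitly
stated settings (e.g. 1–2 repetitions, 4–5 outer folds, 25–100 trees)
chosen so that whole-pipeline runs remain interactive — the scheme's
properties (fold hygiene, null calibration) do not depend on these sizes.

Models with Q² > 0.15 proceed to a permutation test (default n = 50):
the full rdCV is re-run on permuted responses; the empirical
p = (1 + #{Q²_perm ≥ Q²_obs}) / (n + 1) is floor-bounded at 1/(n+1), so a
parametric p from a normal fit to the permuted null is reported alongside
it (this is how p-values far below the empirical floor can legitimately
be quoted from only 50 permutations). Under the null the empirical p is
uniform, which the acceptance suite verifies by a KS test.

Selected features are validated by partial Spearman correlation with
their exposure: feature, exposure and all covariate columns are
rank-transformed (average ranks on ties), the feature and exposure ranks
are residualised on the covariate ranks, and ρ is the Pearson correlation
of the residuals, with p from the t approximation on n − 2 − q degrees of
freedom. Rank-transforming the covariates as well (the standard
rank-based partial correlation, as in R's `ppcor`) is essential: ranks
are a nonlinear transform, and residualising them on *raw* covariates
leaves shared nonlinear leakage that fabricates association under pure
confounding. Zero residual variance yields an explicit null record.
`select_diet_features` takes the union, over exposures passing the Q² and
permutation thresholds, of selected features that also validate by
partial Spearman (p < 0.05), collapsing duplicates to unique features
with all exposure tags.

## Triplot integration

`triplot.pca_selected` autoscales the selected-feature matrix (zero mean,
unit variance — LC–MS features span heterogeneous intensity scales, so
correlation-scale PCA is the defensible default) and decomposes it by
SVD. The pipeline drivers pass log intensities into the PCA: LC–MS
features are log-normal, and on the raw scale a handful of extreme values
of a strongly diet-driven feature can dominate a linear component while
contributing almost nothing to its ranks, making the component's rank
correlation with the exposure meaningless. (The rank-based and
tree-based stages are invariant to this monotone transform.) loading columns are orthonormal and component signs follow the same
largest-entry-positive convention as the factor code. The first three
components (configurable) are then treated as exposures in their own
right: conditional-logistic ORs overall and per stratum, and partial
Spearman correlations with every dietary exposure, assembled into
plot-ready tables (loadings, correlations, ORs with SEs) plus an optional
static overlay figure. Because the generator can plant a
diet→metabolome link with no risk effect, the pipeline's ability to
*separate* exposure reflection (high component–exposure ρ) from risk
association (component OR CI covering 1) is directly testable.

## Numerical conventions

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; forests receive seeds drawn from the local
generator, so every stage is reproducible and whole-pipeline reruns are
byte-identical (fixed `%.12g` float formatting in all TSVs). Tucker
congruence is undefined for zero vectors and raises. EFA requires
complete data and positive per-food variance. The CFA optimiser treats a
non-positive-definite implied covariance as a large penalty; `fit_clogit`
treats an estimated SE above 10³ as numerical separation. Problem sizes
in the shipped analyses (400–2000 pairs, 16–24 foods, 20–200 features)
were chosen so the full test suite and the acceptance script each run in
minutes on a single core.

## Known limitations

* MCAR missingness only; intensity-dependent (left-censored) missingness
  is a documented non-goal, as are batch drift and its correction.
* Pattern derivation treats ordinal frequencies as continuous (Pearson
  correlations), matching standard FFQ practice; polychoric or ordinal
  factor models are out of scope.
* The rdCV elimination uses impurity-based forest importances; strongly
  correlated features share selection credit, which the consensus
  frequency partially mitigates.
* Matched sets beyond 1:1, time-to-event outcomes, and multiple
  imputation of covariates are out of scope.
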