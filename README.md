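# crcdiet

Dietary patterns, plasma metabolite profiles and colorectal-cancer risk
in individually matched case–control pairs.

## The problem

Nutritional epidemiology increasingly analyses *dietary patterns* —
latent combinations of foods — rather than single nutrients, and pairs
self-reported intake with untargeted plasma metabolomics to obtain
objective exposure markers. `crcdiet` implements, as a tested and
reusable pipeline, the full analysis chain for a nested 1:1 matched
case–control study of diet and colorectal cancer (CRC):

1. **Data-driven dietary patterns** from food-frequency questionnaire
   (FFQ) data by repeated random half-split exploratory / confirmatory
   factor analysis (ML factoring, oblimin rotation, loading > 0.3
   membership), keeping only constructs that reproduce — Tucker
   congruence φ ≥ 0.85 — across every split and across neighbouring
   factor counts;
2. **Hypothesis-driven components** (energy-adjusted amounts: red meat,
   fruit & vegetables, …) and the 3-level alcohol covariate (zero /
   below / above the sex-specific non-zero median);
3. **Risk models**: conditional logistic regression for matched pairs —
   for 1:1 matching, maximising
   `Σ_pairs [β'(x_case − x_control) − log(1 + e^{β'(x_case − x_control)})]`,
   i.e. no-intercept logistic regression on within-pair differences —
   reporting odds ratios per 1-SD exposure increase with Wald 95% CIs,
   adjusted for BMI, smoking, physical activity, education, total energy
   and alcohol, overall and stratified by sex and tumour site;
4. **Metabolite preparation**: pooled-QC coefficient-of-variation
   filtering (CV = sd/mean ≤ 30%) and iterative random-forest imputation
   of missing intensities;
5. **Diet–metabolome models**: repeated double cross-validated (rdCV)
   random-forest regression with recursive importance-based variable
   elimination; predictive performance Q² = 1 − PRESS/TSS on out-of-fold
   predictions; models with Q² > 0.15 are confirmed by permutation
   testing, and selected features are validated by covariate-adjusted
   partial Spearman correlation;
6. **Triplot integration**: PCA of the diet-selected feature matrix,
   with component scores associated to CRC risk (conditional logistic)
   and to every dietary exposure (partial Spearman), exported as
   plot-ready tables and an overlay figure.

Cohort data of this kind are not publicly shareable, so the package
ships a first-class synthetic-data generator (`crcdiet.simulate`) that
reproduces the *structure* of such a study — matched pairs, ordinal FFQ
frequencies driven by planted latent factors, log-normal LC–MS-like
features with planted monotone diet links and QC replicates, and case
status drawn from the exact conditional-logistic model with planted
per-SD log-odds. Every stage is tested against that known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a seeded
synthetic cohort (400 pairs, 16 foods with three planted dietary
factors, 40 metabolite features of which four reflect alcohol or
fruit/vegetable intake, and a planted protective per-SD log-odds of
ln 0.89 ≈ −0.117 on the breakfast-like factor):

```bash
python analysis/01_simulate_cohort.py     # cohort, diet, features -> results/data/
python analysis/02_prepare_diet.py        # exposures -> results/diet/
python analysis/03_derive_patterns.py     # stability-selected patterns
python analysis/04_risk_models.py         # conditional-logistic ORs
python analysis/05_prepare_metabolome.py  # CV filter + RF imputation
python analysis/06_diet_metabolome.py     # rdCV models + validation
python analysis/07_triplot.py             # PCA integration
```

Printed output (abridged):

```
stable patterns: 3 (plateau k = [2, 3, 4, 5, 6], splits = 5)
  pattern_01: foods=['food_06', ..., 'food_09'] -> planted 'meat'            (Tucker phi 0.999)
  pattern_02: foods=['food_01', ..., 'food_04'] -> planted 'breakfast'       (Tucker phi 0.999)
  pattern_03: foods=['food_11', ..., 'food_13'] -> planted 'alcohol_pattern' (Tucker phi 0.997)
per-SD odds ratios (overall, covariate-adjusted):
  pattern_02     OR 0.81 (0.70-0.94) p=0.005 n=400 pairs
  pattern_03     OR 1.12 (0.97-1.31) p=0.129 n=400 pairs
  alcohol        OR 0.97 (0.84-1.12) p=0.674 n=400 pairs
  ...
```

Reading this: the half-split stability procedure recovered exactly the
three planted dietary factors (congruence ≈ 1 to truth). The
breakfast-like pattern — the only exposure with a planted effect — is
the only one with a CI excluding 1, and its interval (0.70–0.94) covers
the planted OR of 0.89; every null exposure sits near OR 1. Downstream,
the rdCV models flag alcohol and fruit/vegetables as metabolome-
predictable (Q² ≈ 0.6, permutation p at the rank floor), recover the
planted marker features, and the triplot separates "reflects diet" (high
component–exposure ρ) from "predicts disease" (component OR CI covering
1, since no diet→metabolome→risk effect was planted).

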