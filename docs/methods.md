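# Methods

`metalage` implements an analysis pipeline for mixture epidemiology with
biological aging as a mediator: nine urinary metals (Ba, Cd, Co, Cs, Mo, Pb,
Sb, Tl, Tu) measured in spot urine, self-reported osteoarthritis (OA) as the
binary outcome, and three aging markers — leukocyte telomere length (T/S
ratio), Klemera–Doubal biological age, and phenotypic age — as mediators.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic benchmark does and does not establish.

## Exposure handling

Urinary concentrations below the detection limit are replaced by
LOD/√2, the standard substitution for left-censored biomarkers with high
detection rates. Concentrations are creatinine-corrected to µg/g
(µg/L divided by creatinine in g/L) to adjust for urine dilution, then
Ln-transformed for continuous models or cut at the sample 25/50/75
percentiles for quartile models (intervals (−∞,c1], (c1,c2], (c2,c3],
(c3,∞), Q1 as reference). Quartile cutpoints are computed on the whole
analysis sample, unweighted by default; a weighted-percentile option exists.

## Aging scores

**Klemera–Doubal biological age.** Each biomarker `x_j` (Ln-CRP, serum
creatinine, HbA1c, albumin, total cholesterol, urea nitrogen, alkaline
phosphatase, systolic blood pressure) is regressed on chronological age (CA)
in a training sample, giving slope `k_j`, intercept `q_j`, residual RMSE
`s_j` (ddof = 2) and signed Pearson correlation `r_j`. The uncorrected score
is the precision-weighted combination BA_E = Σ(x_j−q_j)k_j/s_j² / Σ(k_j/s_j)²;
the corrected score shrinks BA_E toward CA with weight 1/s²_BA, where s²_BA
is the training variance of (BA_E − CA) minus
((1−r²_char)/r²_char)·(CA_max−CA_min)²/(12m) and r_char is the
characteristic correlation Σ r_j²/√(1−r_j²) / Σ r_j/√(1−r_j²). Numerical
choices:

- s²_BA can go negative in weakly informative samples; it is clamped to a
  floor of `1e-4·(CA range)²` with a logged warning (the corrected estimator
  requires positivity). If it is still non-positive the score falls back to
  BA_E with a warning.
- r_j² is clipped below 1−1e-12 so r_char stays finite when a biomarker is
  (nearly) collinear with age; an exactly age-linear biomarker gets a
  symbolic RMSE of 1e-12 rather than zero.
- Zero-variance biomarkers are dropped with a warning; fewer than 30
  training rows or a degenerate CA range is an error.
- Parameters are fitted on the analysis cohort itself by default (no
  external reference population is assumed); externally fitted parameters
  can be supplied and serialised to YAML.
- CA enters the score in exact years, even though the regression surfaces
  adjust age as a <60/≥60 dichotomy.

**Phenotypic age.** A fixed closed form over nine biomarkers plus CA:
xb = −19.907 − 0.0336·albumin + 0.0095·creatinine + 0.1953·glucose +
0.0954·LnCRP − 0.0120·lymphocyte% + 0.0268·MCV + 0.3306·RDW +
0.00188·ALP + 0.0554·WBC + 0.0804·CA, then
141.50 + Ln[−0.00553·Ln(exp(−1.51714·exp(xb)/0.0076927))]/0.09165.
The inner Ln(exp(·)) is evaluated analytically (it is the identity), which
keeps the expression finite when exp(xb) underflows; the result is bitwise
indistinguishable from the literal nesting over the physiological input
range. Units follow the source formula: albumin g/L, creatinine µmol/L,
glucose mmol/L, CRP Ln(mg/dL), lymphocytes %, MCV fL, RDW %, ALP U/L, WBC
10⁹/L; conversion helpers from common survey units are provided.

## Regression surfaces

Single-exposure models are maximum-likelihood logistic (OA) or linear
(aging markers) fits via statsmodels. Survey weights enter as normalised
frequency weights with HC0 sandwich standard errors; this replaces the
survey's Taylor-linearised strata/PSU variance, which the synthetic design
has no analogue for (point estimates are weight-driven; a hook accepts
externally computed SEs for real-data replication). The adjustment set is
age (<60/≥60), sex, race/ethnicity, education (toggleable), family
income-to-poverty ratio, marital status, BMI, physical activity, alcohol,
and serum cotinine; missing categorical covariates become an explicit
"missing" level, missing continuous covariates take the column median.
Trend tests refit the quartile model with the integer score 1–4 and report
that Wald p. Trend p-values are Benjamini–Hochberg adjusted across the nine
metals of one results surface (the smallest family consistent with one
figure).

## Weighted quantile sum regression

Written from scratch (no suitable mixture package is assumed). Exposures
are quantile-scored (default quartiles, scores 0–3); the index is Σ w_j q_j
with w on the simplex. For each of B bootstrap resamples (default 100) of a
random training split (default 40%), the weights, the sign-constrained index
coefficient and the covariate coefficients are estimated jointly by
maximum likelihood; the simplex is handled by a softmax reparameterisation
and the sign constraint by `b1 = direction·exp(η)` (clipped at e^±30 for
line-search safety), solved with L-BFGS and an analytic gradient. Covariates
are standardised inside the optimiser only — weight estimates are invariant
to affine rescaling of the adjustment block, and L-BFGS conditioning is not.
Converged bootstrap weight vectors are averaged (default; a
significance-weighted mean using the index term's z² is available); < 50%
convergence is an error. The final inference regresses the outcome on the
fixed-weight index in the held-out validation split (default 60%), so the
reported CI is not contaminated by the weight search; this also keeps the
validation-split test near nominal size under a permuted outcome despite
the directional constraint. Direction defaults to "positive" for OA
(adverse joint effect expected).

## Mediation

Quasi-Bayesian Monte Carlo with normal approximation (default 1000 draws,
seed mandatory in the CLI). Component models: mediator ~ exposure +
covariates (OLS) and outcome ~ exposure + mediator + covariates (logistic or
linear). Parameter vectors are drawn from each fit's asymptotic normal;
counterfactual mediators include residual noise (common draws across the
two exposure levels within a simulation — a variance-reduction device that
leaves the estimands unchanged); effects are evaluated on the response
scale (average risk differences for a logistic outcome). The exposure
contrast is mean(x) → mean(x)+1 (one Ln-unit, or one quantile for the WQS
index, which is recomputed on the full sample from the final weights before
entering mediation). IE and DE are the t-averaged potential-outcome
contrasts, so TE = IE + DE holds exactly and the proportion mediated is
IE/(IE+DE) = IE/TE.

Serial mediation fits the chain m1 ~ x, m2 ~ x + m1, y ~ x + m1 + m2 and
reports the path-specific effect through m1 then m2 (only the m1 input of
the m2 model switches exposure levels); in an all-linear chain this is the
coefficient product a1·d21·b2. DE is reported as TE − IE (the non-serial
remainder), keeping the same proportion definition. The three component
models' parameter draws are sampled as independent blocks although the
models share data; this is standard practice for the normal approximation
and a documented limitation. Point estimates are draw means, intervals
2.5/97.5 percentiles, p-values two-sided tail proportions.

## Synthetic cohort generator

The generator is the test bed: every downstream stage must be checkable
against a known truth without external data. Defaults:

- **Metals**: multivariate lognormal, Ln-scale geometric means and SDs
  loosely matching U.S. adult spot-urine surveys; pairwise Ln correlations
  0.15 background with Cs–Tl = 0.58, Ba–Co = 0.41, Cd–Pb = 0.40; detection
  limits placed so detection rates stay above ~75%, then LOD/√2
  substitution applied.
- **Chain**: metals shorten telomeres (Ln T/S deficit), telomere deficit and
  metals feed a latent whole-body age acceleration (years; Gaussian noise
  SD 4), and OA risk is Bernoulli with logit = baseline + 0.06·acceleration
  + direct metal terms + covariate terms. Default per-Ln-unit effects
  (Cd 2.2, Co 1.0, Cs 1.2, Pb 0.6, Tl 0.5 years on aging; Cd 0.10, Co 0.10,
  Cs 0.08 direct log-odds) give Q4-vs-Q1 ORs near 1.5–2, a WQS index OR
  near 1.25, an OA prevalence near 11%, and a latent via-aging share of the
  Cd effect of 0.132/0.232 ≈ 57%.
- **Biomarker panels** are generated by inverting the aging scores: each
  panel variable is linear in the latent biological age plus independent
  noise with clinically plausible slopes and RMSEs, so the scoring module
  recovers the latent mediator (r > 0.9 at the defaults) and parameter
  recovery for mediation is well defined. Ln-CRP and ALP are shared between
  the two panels (same analyte).
- **Covariates** have marginals loosely matching the study population
  (~51% female, 68% non-Hispanic White, BMI ~N(28.4, 5.5²)); survey weights
  are i.i.d. gamma(2, 0.5), independent of everything, so weighted and
  unweighted estimands coincide for testing. Optional MCAR missingness per
  column exercises the imputation rules (off by default).
- All randomness flows through one `numpy` generator seeded by the config;
  identical configs give byte-identical cohorts.

**What the benchmark does not show.** The generator has no survey strata or
PSUs, no age trend in the metals (exposures are independent of the
covariates by construction, which keeps downstream null fits at nominal
size), no differential missingness, and no telomere assay error structure.
One visible consequence: mediation proportions estimated with the *measured*
aging scores are attenuated relative to the latent structure, because the
biomarker noise in measured biological age (≈10 years around the latent
value at the default panel RMSEs) shrinks the mediator→outcome coefficient.
The acceptance script therefore reports both the measured-marker proportions
(~9% parallel, ~4% serial at the defaults) and the latent-mediator
diagnostic (~45%), the upper bound the measured analyses are attenuated
against. Real-data proportions sit between these depending on the true
marker reliability, which a synthetic benchmark cannot fix.

## Problem sizes

Unit and property tests run on cohorts of 800–20,000 rows. The recovery
benchmarks use the sizes the estimators are meant for: WQS component
recovery on 20 replicate cohorts of n = 5,000 with 100 bootstraps;
mediation-proportion recovery on 20 replicate chains of n = 10,000 with 500
draws; the acceptance script runs the full pipeline once at n = 12,584 (the
study's enrolment count) with 100 WQS bootstraps and 1000 mediation draws.
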