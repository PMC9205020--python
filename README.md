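# metalage

Urinary metal mixtures, biological aging, and osteoarthritis risk — a tested,
reusable analysis pipeline for environmental epidemiology.

Exposure to heavy metals is an emerging, modifiable risk factor for
osteoarthritis (OA), and biological aging is a plausible pathway: metals can
accelerate cellular senescence (telomere attrition) and whole-body aging,
both of which drive joint degeneration. `metalage` packages the full
analytic chain needed to study this on NHANES-style cohort data:

- **Exposure handling** — LOD/√2 substitution for non-detects, urinary
  creatinine correction (µg/g), Ln transforms and quartile coding.
- **Aging scores** — Klemera–Doubal biological age (per-biomarker
  regressions on chronological age combined as
  BA = [Σ(x_j−q_j)k_j/s_j² + CA/s²_BA] / [Σ(k_j/s_j)² + 1/s²_BA]),
  the phenotypic-age closed form over nine clinical biomarkers, and
  telomere T/S pass-through.
- **Single-exposure models** — survey-weighted logistic/linear regressions
  with sandwich SEs, integer-score trend tests, Benjamini–Hochberg FDR,
  Pearson correlations among Ln metals.
- **Weighted quantile sum (WQS) regression** — from scratch: bootstrap
  estimation of simplex-constrained weights w (w_j ≥ 0, Σw_j = 1) for the
  index Σ w_j q_ij with a sign-constrained coefficient, final inference on a
  held-out validation split.
- **Causal mediation** — quasi-Bayesian Monte Carlo (normal approximation)
  for parallel (one mediator) and serial (telomere → whole-body aging)
  designs, reporting IE, DE, TE and proportion mediated = IE/(IE+DE) on the
  risk-difference scale.
- **Synthetic cohorts** — a generator with a configurable
  metal → aging → OA mediation structure, correlated lognormal metals,
  LOD censoring, age-dependent biomarker panels and survey weights, so
  every stage is testable against known truth without any data download.

It is aimed at epidemiologists and biostatisticians who want the whole
pipeline scripted and unit-tested rather than stitched together ad hoc.

## Worked example

```python
import pandas as pd
import metalage as ml
from metalage.exposure import creatinine_correct, design_matrix

cohort = ml.attach_aging_markers(
    ml.generate_cohort(ml.SimulationConfig(n_participants=5000, seed=1)))
cov = design_matrix(cohort)
creat = cohort["creatinine_mgdl"].to_numpy()
metals = pd.DataFrame(
    {m: creatinine_correct(cohort[f"metal_{m}"].to_numpy(), creat)
     for m in ml.METALS})

wqs = ml.fit_wqs(cohort["oa"].to_numpy(), metals, cov, n_bootstrap=100, seed=2)
print(wqs.summary())
```

```
Weighted quantile sum regression
  direction=positive, quantiles=4, bootstraps=100 (converged 99%), train fraction=0.4, seed=2
  index OR per one-quantile increase: 1.340 (95% CI 1.179, 1.524), p=7.85e-06
  weights:
    cd       0.7944
    ba       0.0855
    cs       0.0414
    ...
```

Each one-quantile increase of the metal mixture raises the odds of OA by
34% in this synthetic cohort, and cadmium carries most of the mixture
weight — consistent with the cadmium-dominated structure the generator was
configured with. Feeding the fixed-weight index into mediation:

```python
index = ml.quantile_score(metals, 4) @ wqs.weights.to_numpy()
med = ml.mediate_parallel(index, cohort["biological_age"].to_numpy(),
                          cohort["oa"].to_numpy(), covariates=cov,
                          n_sim=1000, seed=3)
print(med.summary())
```

```
Quasi-Bayesian mediation (parallel), outcome family logistic, n_sim=1000, seed=3
  exposure exposure: contrast 1.500 -> 2.500; mediators: m1
  IE                0.00278  (95% CI 0.00117, 0.00456)  p=0
  DE                0.03129  (95% CI 0.02055, 0.04145)  p=0
  TE                0.03407  (95% CI 0.02333, 0.04463)  p=0
  prop_mediated     0.08161  (95% CI 0.03449, 0.13827)  p=0
```

A one-quantile increase in the mixture raises OA risk by 3.4 percentage
points, of which 0.28 points (~8%) flow through measured biological age.
(The measured-marker proportion is attenuated by biomarker noise relative
to the generator's latent mediation share; see `docs/methods.md`.)

The same stages are available from the shell:

```bash
metalage simulate --n 5000 --seed 1 --out cohort.csv
metalage score-aging --cohort cohort.csv --out scored.csv
metalage fit-single --cohort scored.csv --out single.csv
metalage fit-wqs    --cohort scored.csv --out weights.csv --seed 2
metalage mediate    --cohort scored.csv --exposure biological_age \
                    --mediator phenotypic_age --seed 3 --out med.csv
```

Real cohort tables are read from CSV (documented schema in
`metalage.cohort.REQUIRED_COLUMNS`) or from SAS transport (XPT v5) file
sets with a variable-name mapping — see `metalage.read_cohort`.

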