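# transientcmr

Transient-aware capture–mark–recapture (CMR) analysis and its demographic
consequences, built around a long-term resighting study of Audouin's gull
(*Ichthyaetus audouinii*), a long-lived colonial seabird.

**Who this is for.** Population ecologists working with open-population
resighting data who find a *transience* signal in their goodness-of-fit
tests — newly marked animals that are never re-encountered because they die
or emigrate permanently after first capture (here, after the first breeding
attempt) — and who want to (i) detect and quantify that signal properly and
(ii) carry it through to population-level consequences with a structured
projection model.

## What the package computes

**Detection.** Test 3.SR cross-classifies, at each occasion *t*, the animals
encountered at *t* by {newly vs previously encountered} × {re-encountered
after *t* vs never again}. A directional excess of never-reseen new animals
(signed statistic *z* > 0) signals transience. The companion memory test
3.Sm and the overdispersion factor ĉ = Σχ²/Σdf are included.

**Estimation.** A transient Cormack–Jolly–Seber likelihood over the m-array
split by time-since-marking class: a newly marked animal of age-class *g*
released in year *t* is a transient with probability τ<sub>gt</sub>, so its
first-interval apparent survival is (1 − τ<sub>gt</sub>)·φ while re-released
(previously marked) animals survive with the resident φ. τ is estimated
directly on a logit scale and may depend on the age at first breeding
(groups 3, 4, 5, 6, >6 years) and on a density-dependence covariate
(food per capita). Model selection by AIC; ANODEV attributes the temporal
variance in τ to the covariate.

**Projection.** A 17-state pre-breeding-census matrix model (states N1, N2,
and breeder / first-time-breeder / non-breeder at ages 3–7+) in which every
recruit passes through a first-time-breeder state with reduced fertility F′
and survives out of it with φ<sub>A</sub>·(1 − τ<sub>i</sub>) — the matrix
analogue of the CMR transient structure. From it: λ (dominant eigenvalue),
stable structure, reproductive values, entry- and vital-rate-level
sensitivities and elasticities, a fixed-design LTRE decomposing the λ
difference between a good and a bad season, and a λ response surface over
density × transient intensity.

The field data themselves are not publicly deposited, so the estimation half
runs on a synthetic generator (`transientcmr.simulate`) calibrated to the
published study conditions (25 annual occasions, five age classes, τ rising
with age and density-dependence, e.g. 0–17% for age-4 recruits and 37–81%
for >6-year recruits across the covariate support).

## Worked example

```bash
python analysis/01_simulate.py 1     # synthetic case-study dataset
python analysis/02_gof.py            # transience GOF + c-hat
python analysis/03_fit_transients.py # transient-CJS fits, AIC, ANODEV
python analysis/04_matrix_model.py   # lambda, sensitivities, elasticities
python analysis/05_ltre.py           # LTRE decomposition
python analysis/06_lambda_surface.py # lambda over density x transience
```

`04_matrix_model.py` prints (published values in brackets):

```
good season: lambda = 1.0881 (entry elasticities sum to 1.000000)
 bad season: lambda = 0.9443 (entry elasticities sum to 1.000000)

  good-season elasticity of adult survival: 0.843  [0.849]
  good-season elasticity of resident fertility: 0.074  [0.074]
```

The good-season (weak density-dependence) matrix grows at ~9% per year; the
bad season shrinks at ~6%. `05_ltre.py` decomposes the difference:

```
lambda good = 1.0881, bad = 0.9443, delta = -0.1438

contributions to the lambda decline (bad - good):
  adult survival               -0.061
  first-year survival          -0.019
  resident fertility           -0.044
  first-time-breeder fertility -0.002
  transience (pooled total)    -0.066  (per-age sum -0.005)
  recruitment (pooled total)   -0.043  (per-age sum -0.014)
```

The summed transience effect (−0.066) outweighs the adult-survival effect
(−0.061) even though adult survival has by far the largest sensitivity
(0.95): rates that actually vary between seasons — transience, recruitment,
fertility — drive the realized change in λ. On the statistical side,
`03_fit_transients.py` recovers the generating τ ranges (e.g. 0.001–0.170
for the age-4 group) and attributes ~90% of the temporal deviance in τ to
the density-dependence covariate on this synthetic dataset (the real-data
figure was 56%, with more unexplained year effects).

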