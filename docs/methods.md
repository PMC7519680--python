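# Methods

## Transience in open-population CMR

A *transient* is an animal marked once and never re-encountered because it
dies or permanently emigrates immediately after first capture. When first
captures coincide with first breeding attempts, transience measures the
local survival cost of first reproduction (mortality and permanent dispersal
are observationally equivalent at the scale of one colony). Transients
violate the CJS assumption that newly and previously marked animals share
one survival probability; ignoring them biases apparent survival downward.

### Test 3.SR and 3.Sm

For each interior occasion *t*, animals encountered at *t* are classified
into a 2×2 table: {first encounter at *t*, encountered before *t*} ×
{re-encountered after *t*, never again}. Per-occasion Pearson χ² statistics
(1 df) are summed; when any expected cell is below 2 the occasion's
contribution comes from Fisher's exact test converted to a 1-df χ² deviate,
with the method recorded per occasion. The directional statistic *z* is the
signed square root of the χ² of the occasion-summed table (uninformative
occasions excluded), positive when newly encountered animals are
under-re-encountered — the transience direction. Test 3.Sm conditions on
previously encountered animals seen at *t* and tests whether time since the
previous encounter (lags 1, 2, 3+) predicts re-encounter; under the
memoryless CJS null it does not. The overdispersion factor is
ĉ = Σχ²/Σdf over the supplied components, with each component's share of
the total χ² reported. Only the transience and memory components are
implemented; trap-dependence components (2.CT/2.CL) are out of scope, so ĉ
here reflects those two sources only.

Calibration is verified by simulation: under the no-transience null the
3.SR rejection rate at α = 0.05 stays within [0.03, 0.07] (500 replicates),
and power is monotone in τ.

### Transient-CJS likelihood

The sufficient statistic is the m-array split by time-since-marking class:
for each age-group *g*, mark class (newly vs previously marked) and release
occasion *t*, the counts of first recaptures at each later occasion *j* and
of animals never seen again. For residents,

    P(t, j) = φ_t · Π_{k=t+1}^{j-1} [(1 − p_k) φ_k] · p_j ,

and a newly marked cohort's first-interval survival is multiplied by
(1 − τ_gt); the likelihood is the product of cohort multinomials. This
m-array form is verified against an exhaustive enumeration of individual
latent fates (transient flag × death interval) on all small datasets — the
two agree to 10⁻¹⁰.

τ is parameterized directly on the logit scale (τ stays in [0, 1] and
covariate models are natural); the classic two-class-survival form (free
first-interval survival, τ = 1 − φ_new/φ) is available and agrees at the
optimum, as a reparameterization must. Structures: φ and p constant or
time-dependent; logit(τ) additive in age-group intercepts, a standardized
per-occasion covariate (shared or group-specific slopes), or year factors.
The covariate is standardized before entering the design for Hessian
conditioning. With both φ and p time-dependent the terminal product
φ_{K−1}·p_K is confounded and the fit is flagged. Deviance is reported
against the saturated multinomial, which makes ANODEV ratios invariant to
constants:

    pct = (Dev_constant − Dev_covariate) / (Dev_constant − Dev_time) ,

with an F statistic on (np_cov − np_cst, np_time − np_cov) df.

Optimization: L-BFGS-B on the link scale from a zero start plus random
restarts; covariance from a central-difference Hessian (the package carries
its own small finite-difference module); Wald CIs on the link scale,
back-transformed. Estimates with |logit| > 12 are flagged as boundary.
Identifiability is screened before fitting (parameter count vs informative
cells, design-matrix rank, the two-occasion φ·p confounding).

## Synthetic study conditions

The gull resighting data are not deposited, so the generator emulates the
published study conditions and is itself first-class, tested code:

- 25 annual occasions, five age-at-first-breeding classes (3, 4, 5, 6, >6),
  ~60 newly marked first-time breeders per occasion and class (matching
  ~8 400 adults over 25 years in five classes);
- transience acts exactly once, at first release; residents never become
  transients later, and re-detections do not change an animal's class (no
  trap-dependence — those GOF components are out of scope);
- logit(τ_gt) = α_g + β_g·x_t against a standardized food-per-capita
  covariate, calibrated so τ spans the published per-class ranges across
  the covariate support (age 4: ~0–0.17, with 0.005 standing in for the
  unrepresentable 0; >6: 0.37–0.81; intermediate classes anchored at the
  published good/bad-season values). Group-specific slopes are required:
  the published class ranges differ by a factor of ~2 on the logit scale,
  which a shared slope cannot produce;
- resident survival 0.93, constant across ages post-recruitment (age
  effects enter through τ and the grouping, as in the case-study model);
  detection 0.55 — the study does not report a resighting probability, so
  this is an assumed plausible value for intensive colony resighting.

What the generator does *not* emulate: individual heterogeneity in
detection or survival, trap response, density feedback on the covariate
(it is exogenous), carnivore-intrusion year effects, and emigration with
return. Passing recovery tests therefore shows the estimator is correct
under the transient-CJS model, not that real data meet its assumptions.

## Life cycle and projection matrix

Seventeen states: N1, N2, and (B, T, NB) for ages 3–7, with 7 standing for
7+. Pre-breeding census, annual step:

- N1 → N2 with φ₂; from N2 onward survival is adult φ_A (the table of
  published rates has only φ₁, φ₂, φ_A, so third-year survival maps to
  φ_A — adults are "3+");
- a surviving pre-breeder recruits at age *i* with conditional probability
  γ_i (γ values are conditional on not having recruited yet, which is the
  only reading that keeps columns stochastic) into the first-time-breeder
  state N_iT; otherwise it moves to N_iNB;
- **every recruit passes through N_iT**: fertility there is the reduced F′
  (first-time breeders), and survival out of it into the experienced-breeder
  chain is φ_A·(1 − τ_i) — exactly the CMR transient first-interval
  survival. Experienced breeders N_iB survive with φ_A; N7B and N7NB are
  absorbing 7+ classes (γ₇ = 10⁻⁹ is a numerical placeholder — recruitment
  above age 6 is negligible);
- pre-breeding-census fertility credits F·x·φ₁ (or F′·x·φ₁ from T states)
  to N1: fledglings per pair × sex ratio × first-year survival.

This topology was chosen over the alternative in which resident first-time
breeders enter N_iB directly and only transients occupy T: with the
published good-season rates the all-recruits-through-T form reproduces the
published λ to 0.0008 (1.0881 vs 1.0889; bad season 0.9443 vs 0.9445), the
published LTRE contribution column to <0.001, and the published per-age
transience sensitivities, while the alternative misses the τ structure by
a factor of ~5. It also matches the published description of F′ as the
fertility of first-time breeders.

Asymptotics: λ is the Perron root (the spectral radius must be attained by
a real, numerically simple eigenvalue; the nilpotent λ = 0 limit is handled
explicitly), w and v the right/left eigenvectors (w summing to 1,
⟨v, w⟩ = 1), entry sensitivities s_ij = v_i w_j, entry elasticities
(a_ij/λ)s_ij (they sum to 1 — asserted). Lower-level sensitivities use the
chain rule dλ/dp = Σ_ij (∂a_ij/∂p)s_ij; every matrix entry is multilinear
in the scalar rates, so the entry derivatives computed by differencing the
matrix builder are exact, and they are cross-checked against central finite
differences of λ itself.

## LTRE

Fixed design, Δ convention bad − good (matching the published
Δλ = 0.9445 − 1.0889 = −0.144). Contributions are Δp × (dλ/dp) with
sensitivities evaluated at the matrix built from parameter midpoints;
elasticities are reported from the good-season matrix. The first-order sum
of contributions reproduces Δλ to a residual of +0.0012, which is reported,
never hidden.

Aggregates over the age-structured rates are reported under two
conventions. The *per-age* sum Σ_i Δτ_i·s_i is the exact first-order Taylor
term and enters the overall sum and residual. The *pooled* product
(Σ_i Δτ_i) × (Σ_i s_i) — with ages whose rate is identical in both
scenarios (the γ₇ placeholder) excluded from the pooled sensitivity, since
they carry no contrast — is the headline aggregate: it treats "transience"
as one compound trait shifted by the total Δ, and it is the convention
under which the published aggregate rows (−0.063 for τ, −0.045 for γ) and
the headline ordering |transience total| ≥ |adult survival| are
reproducible. The two differ by an order of magnitude for τ here because
the large per-age Δτ values occur at ages whose individual sensitivities
are small; both are printed so the reader can see the gap.

### Known discrepancies in the published parameter table

Two printed values are internally inconsistent with the rest of the table
and are not reproducible by any single-pathway pre-breeding life cycle:

1. *First-year-survival elasticity (printed 0.039).* Every newborn enters
   fertility terms through φ₁ exactly once and passes N1 → N2 exactly once,
   so e(φ₁) = e(φ₂) = e(F) + e(F′) is a flow identity. The table itself
   prints e(φ₂) = 0.079 and e(F) + e(F′) = 0.079; this model gives 0.0785
   for all three. The printed 0.039 is exactly half — consistent with a sex
   ratio applied once too often.
2. *Mean-matrix adult-survival sensitivity (printed 0.968).* The table's
   own contribution arithmetic implies s(φ_A) = contribution/Δp =
   −0.061/−0.064 = 0.953 and s(F) = −0.044/−0.289 = 0.152; this model
   reproduces both implied values (0.953, 0.152) exactly, and likewise the
   per-age τ sensitivities printed in the τ rows (−0.021, −0.020, −0.010,
   −0.003, 0.000 vs computed −0.025, −0.023, −0.012, −0.003, −0.000). The
   printed sensitivity column apparently comes from a different (study-mean,
   unprinted) parameterization.

The acceptance suite asserts the printed values as given (one check stays
red on the two cells above) and separately asserts the self-consistent
values.

## λ surface

The density axis is normalized (0 = good season, 1 = bad season) and
linearly interpolates the rates that respond to density-dependence in the
case study — F, γ_i, τ_i — between their published anchors, keeping
survival and F′ at the scenario midpoint; the second axis overrides τ₄
(age 4 is the modal age at first breeding). Values interpolated or swept
outside [0, 1] are clipped cell-wise with a flag rather than raised. Both
axes depress λ, and λ is non-increasing in τ₄ at every density.

## Numerical choices and problem sizes

- Probabilities live on the logit scale everywhere (estimation and
  generation); logs are clipped at 10⁻³⁰⁰ to keep boundary evaluations
  finite.
- Simulation-based checks use: 500 replicates for the 3.SR type-I band,
  200 per τ level for power, 20 replicate studies for CI coverage, and
  datasets of ~7 200 individuals at the case-study scale — sizes chosen so
  each Monte-Carlo property is decided by its binomial error, not by the
  optimizer.
- Ties/degeneracies: a repeated (numerically identical) dominant eigenvalue
  raises; nearly coincident but distinct roots (the 7+ self-loops when
  fertility vanishes) are analyzable. Eigenvector signs are normalized and
  checked non-negative.
- The m-array retains releases at the final occasion for bookkeeping; they
  contribute no likelihood information.

## Limitations

- Uni-state model: transients are an absorbing fate; prospecting, skipped
  breeding with return, and state-dependent detection need multi-state or
  robust-design models, which are out of scope.
- ĉ excludes trap-dependence components by design.
- The LTRE is a two-scenario fixed design; temporal variance decomposition
  (random-design LTRE) is not implemented.
- The λ surface's density mapping is a linear interpolation between two
  printed anchors — the real mapping from density to vital rates is not
  published.
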