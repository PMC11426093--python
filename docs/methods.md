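# Methods

## The model

`cooccupy` implements the dominant/subordinate conditional two-species
occupancy model for single-season camera-trap data. Each site i carries two
latent Bernoulli occupancy states, z^A_i ~ Bern(ψ^A_i) for the dominant
species and z^B_i ~ Bern(ψ^B_i) for the subordinate. Detections are
recorded per survey occasion (a block of 10 consecutive active camera-days,
aligned to each site's first active day). The dominant species is detected
with probability p^A when present; the subordinate's per-occasion detection
probability can depend on the dominant's latent state and same-occasion
detection through three parameters — p^B (A absent), r^Ba (A present, not
detected that occasion), r^BA (A present and detected). Four nested
hypotheses (H1–H4) tie these together structurally: tied roles share one
coefficient vector, so a tie is a reduction in unknowns rather than a
runtime constraint.

Because cameras sample an area smaller than a home range, ψ and p are read
as probability of occurrence and intensity of use rather than strict
closure-based occupancy; nothing in the code depends on that reading.

All six probabilities are inverse-logit linear predictors. Occupancy uses
standardized latitude and longitude (to absorb broad spatial trends);
detection uses four standardized human-disturbance covariates: distance to
paved road (DR, m), distance to settlement (DS, m), and log(x+1)-transformed
relative abundance indices of humans (RH) and cattle (RC). The log offset
of 1 keeps the transform defined at the many zero-RAI sites (cattle are
absent from roughly half) and is configurable. Transform-then-standardize
order is fixed and the transform parameters ride along with every fit so
coefficients can be mapped back to raw units.

Assumptions worth stating: sites are independent given covariates (cameras
≥500 m apart in the emulated design); detection covariates are site-level
(no occasion-varying covariates); ψ^B is not conditioned on z^A — the
interaction enters at the detection level only; missing occasions (zero
active days) contribute a factor of 1 to the likelihood and are never
imputed.

## Likelihood and its evaluation

The observed-data likelihood marginalizes the four (z^A, z^B) combinations
exactly. Because detection probabilities are constant within a site, a
site's paired histories enter only through sufficient statistics: the
occasion counts in the four (D^A_t, D^B_t) cells plus the number of
surveyed occasions. The engine precomputes these once per dataset and
evaluates the per-site log-likelihood for a whole batch of coefficient
vectors (one per MCMC chain) with a handful of vectorized operations. The
exact marginal form is what enables brute-force enumeration oracles in the
test suite, outcome-space normalization checks, and the pointwise
log-likelihood matrix that LOO needs.

## Sampling

No Gibbs/JAGS-style engine is bundled; the sampler is a blockwise adaptive
random-walk Metropolis on the marginal posterior. Each coefficient vector
(ψ^A, ψ^B, p^A and the hypothesis's B-detection vectors, 3 or 5
coefficients each) is one proposal block with an isotropic Gaussian step
whose log-scale adapts by Robbins–Monro toward 0.35 acceptance during
burn-in; chains run vectorized, and per-block likelihood pieces are cached
so a proposal only recomputes what it changed. Priors are independent
Normal(0, SD 10) on every logit-scale coefficient — the common "vague
dnorm(0, 0.01)" choice — and configurable.

Protocol presets: the desk-scale default is 3 chains × 10,000 iterations
(burn-in 5,000, thin 5 → 3,000 retained draws); `MCMCConfig.field_protocol`
gives the full field protocol (3 × 100,000 / 50,000 / 5); `MCMCConfig.quick`
(2 × 4,000 / 2,000 / 2) serves replicate studies. Convergence is summarized
by split-R̂ per coefficient (classic between/within form, via arviz); any
R̂ ≥ 1.1 raises a warning on the fit. On 300-site simulations the desk
preset yields R̂ < 1.02 throughout and nominal interval coverage, which is
why it is the default; the sampler contract is behavioural (calibration and
agreement properties), not algorithmic.

Initialization draws all coefficients from N(0, 0.5); the posterior density
is finite for any finite coefficient vector (inverse-logit probabilities
are interior), so no restart logic is needed in practice, but a non-finite
start raises a diagnostic error with the offending state.

## Model comparison

Fits are ranked by elpd estimated with PSIS-LOO from the stored pointwise
log-likelihoods: importance ratios are inverse likelihoods, the upper 20%
tail is smoothed by a generalized-Pareto fit (arviz's `psislw`), elpd_i is
the log smoothed-weight average predictive density, SE = √n·SD(elpd_i), and
Δse uses the pointwise differences against the top model. Pareto k > 0.7
flags a site; any k > 1 triggers an automatic WAIC fallback for that
comparison (WAIC is also available directly as a cross-check). Selection:
the top model, unless a simpler model sits within 4 elpd of it, in which
case the simplest such model wins. Simplicity is the number of free
B-detection vectors (H1:1, H2:2, H3:2, H4:3) with the H2/H3 tie broken
toward presence-conditioning (H2) — a documented convention; the tie has no
effect on the H1-vs-H2 studies the package validates.

Sign convention for contrasts: `coefficient_contrast` reports
p^B − r^B (dominant-absent minus dominant-present) with equal-tailed 95%
and 85% BCIs; "significant" means the 95% interval excludes 0, "marginal"
that only the 85% does. Under H3 the conditional vector is r^BA; under H4
the default conditional vector is r^Ba with `r_vector="rBA"` as an option,
and SIF curves under H4 carry the same choice plus a warning — the SIF
formula has a single r^B, which is unambiguous only when r^Ba = r^BA (H2).

## Diagnostics

Site-sum residuals of the subordinate's detection: at posterior-mean
coefficients, each surveyed occasion's expected detection probability is
computed marginally over (z^A, z^B), with the z^A branch weights
conditioned on the site's observed A history (this decides whether r^Ba or
r^BA applies at each occasion); the residual is the per-site sum of
observed minus expected, raw by default with a Pearson-scaled option.
Plug-in at the posterior mean (rather than full posterior predictive) is a
deliberate simplification, adequate for a screening statistic.

Moran's I uses row-standardized inverse Euclidean distance weights by
default (k-nearest, k = 8, as an alternative), a two-sided permutation
p-value with the +1 correction (999 permutations by default), and the
analytic null expectation E[I] = −1/(n−1). Sites with missing residuals
are dropped; constant values or coincident coordinates are errors.

## The synthetic survey generator

The generator runs the model forward on a survey design emulating the
study conditions: 102 sites on a jittered ~2 km grid, one contiguous
deployment per site averaging 153 active days (SD 18, clipped to [30,
260]), a 10% chance of one 5–15-day mid-deployment outage, DR and DS
uniform on 305–4142 m, RH gamma-distributed around RAI ≈ 1.5 with a small
floor, RC zero-inflated (45% structural zeros) with a right-skewed gamma
positive part. Default coefficient truth puts leopard occupancy near 0.44
with per-occasion detection near 0.15, prey occupancy near 0.93 with
p^B ≈ 0.4 and r^B ≈ 0.65 (a ~1-logit intercept gap under H2), and slope
signs mirroring the reported human/cattle effects. Across replicates the
emitted surveys average naïve occupancies ≈ 0.39 / 0.92 / 0.93 / 1.00 /
0.52 for leopard / roe deer / wild boar / human / cattle and RAI of the
right magnitudes (leopard ≈ 0.7, prey ≈ 8, total effort ≈ 15.5k
camera-days).

Record emission is designed for exact round-tripping: every occasion-level
detection becomes one or more bursts of 3 images 10 s apart, bursts occupy
distinct (day, hour-slot) combos with start minutes ≤ 20, so within-burst
gaps are seconds and between-burst gaps always exceed 30 minutes — the
independence filter and occasion builder therefore reconstruct the latent
detection matrices exactly, and the realized human/cattle RAI recomputed
from the records equals the covariate values the detection probabilities
were generated from. Prey detections emit 1 + Poisson(0.7) bursts per
detected occasion to reach prey-like RAI; the human event count is floored
at one per site so human naïve occupancy is 1, as in the emulated design.
Two light simplifications relative to field data: no behavioral interaction
in the human/cattle streams (they are marginal Poisson processes, so the
covariates are exactly reconstructable), and no spatial autocorrelation in
the occupancy field beyond the lat/lon trend. Passing tests therefore
demonstrate correctness of the machinery and calibration under the model's
own assumptions — not robustness to model misspecification.

A fast path (`simulate_histories`) skips record emission and uses the drawn
RH/RC rates directly as covariates; replicate studies use it with fixed
150-day deployments (exactly 15 occasions).

## Calibration studies and problem sizes

`cooccupy.studies` packages the two replicate studies the test suite and
acceptance script run: (1) 95% BCI coverage of the generating H2
coefficients — 20 replicates of 300 sites × 15 occasions with the
desk-scale preset, pooled coverage expected in [0.85, 1.00] (observed
≈ 0.94); (2) H1-vs-H2 selection — 50 replicates alternating the generating
hypothesis, quick preset, expected ≥ 80% correct per truth (observed 100%).
These sizes give tight Monte Carlo error while keeping a full run in
minutes on one CPU.

## Numerical notes

Probabilities are computed with `expit` and log-terms with `xlogy`, so
structurally impossible events (a detection under ψ = 0) give −inf
log-likelihood cleanly and empty-count terms contribute exactly 0. An
all-missing site has likelihood 1 and is verified to leave the posterior
bit-identical. Equal-tailed quantile intervals (not HPD) are used
everywhere. Seeds are mandatory for the sampler, the generator and
permutation tests; identical seeds give byte-identical outputs.

## Known limitations

Two species per fit (no multi-species or multi-season dynamics); no
occupancy-level interaction (ψ^B independent of z^A by design); site-level
detection covariates only; no spatially explicit random effects (Moran's I
is a check, not a correction); the random-walk sampler, while calibrated at
these problem sizes, will mix more slowly than gradient-based samplers on
much larger covariate sets.
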