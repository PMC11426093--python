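# cooccupy

Conditional two-species occupancy analysis for camera-trap surveys, in
Python: from raw image records to Bayesian inference about whether a
subordinate species (e.g. an ungulate prey) uses space differently where a
dominant species (e.g. a large carnivore) is present, and how human
disturbance modifies that relationship.

## Who this is for

Ecologists with per-image camera-trap data (site, species, timestamp),
deployment calendars and site covariates who want the standard
co-occurrence occupancy workflow as reproducible, scriptable code:
independence filtering, relative abundance indices (RAI), occasion-level
detection histories, a latent-state co-occupancy model fitted by MCMC,
elpd-based model comparison, and spatial residual diagnostics.

## The model

Let z^A, z^B ∈ {0,1} be the latent occupancy states of the dominant
species A and subordinate species B at a site, with ψ^A = Pr(z^A = 1) and
ψ^B = Pr(z^B = 1). Detections per 10-day survey occasion t are Bernoulli:

    D^A_t ~ Bern(p^A · z^A)
    D^B_t ~ Bern(q_t · z^B),   q_t = p^B   if z^A = 0
                               q_t = r^Ba  if z^A = 1 and D^A_t = 0
                               q_t = r^BA  if z^A = 1 and D^A_t = 1

Four hypotheses tie B's detection parameters: H1 (p^B = r^Ba = r^BA,
independence), H2 (p^B ≠ r^Ba = r^BA, conditional on A's presence), H3
(p^B = r^Ba ≠ r^BA, conditional on A's detection), H4 (all free). Occupancy
probabilities are logistic in standardized site coordinates (lat, lon);
detection probabilities are logistic in four standardized human-disturbance
covariates: distance to road (DR), distance to settlement (DS), and
log-transformed RAI of humans (RH) and cattle (RC).

The likelihood marginalizes (z^A, z^B) exactly, so fits yield pointwise
log-likelihood matrices for PSIS-LOO model comparison (select by Δelpd > 4,
ties resolved by parsimony). The spatial relationship is summarized by the
species interaction factor,

    SIF = r^B / (r^B·ψ^A + p^B·(1 − ψ^A)),

which is 1 under independence, > 1 when B is detected with A more than
expected, < 1 when less. Posteriors are sampled with a blockwise adaptive
random-walk Metropolis sampler (Normal(0, 10) priors, split-R̂ convergence
checks); residual spatial autocorrelation is tested with permutation
Moran's I on site-sum detection residuals.

## Worked example

No field data ship with the package; the synthetic module generates a
survey with the same design (102 sites, ~153 active days/site, 10-day
occasions, five species streams):

```python
from cooccupy import (MCMCConfig, compare, default_survey_config, fit,
                      simulate_histories)

cfg = default_survey_config(seed=11, n_sites=300,
                            mean_active_days=150.0, sd_active_days=0.0,
                            gap_prob=0.0)
hist_a, hist_b, dm, truth = simulate_histories(cfg)   # H2 truth
pair = (hist_a, hist_b["roe_deer"])
fits = [fit(pair, dm, h, MCMCConfig(seed=5)) for h in ("H1", "H2")]
table = compare(fits)
print(table.table[["hypothesis", "elpd", "delta_elpd", "delta_se"]].round(2))
print("selected:", table.selected)
```

prints

```
  hypothesis     elpd  delta_elpd  delta_se
0         H2 -3716.23        0.00      0.00
1         H1 -3846.43     -130.19     18.73
```

and `selected: H2` — the comparison recovers the generating hypothesis, with
H1 about 130 elpd worse (Δse ≈ 19). The fitted H2 posterior covers the
generating coefficients (e.g. the p^B − r^B intercept gap of −1.03 logits);
its 95% intervals contained 21/21 true values in this run. The same objects
feed `coefficient_contrast`, `predict_detection`, `sif_curve`,
`site_sum_residuals` and `morans_i`.

A command-line pipeline wraps the same library:

```bash
cooccupy simulate --seed 1 --outdir demo
cd demo
cooccupy summarize --seed 1 --outdir .   # per-species detections / RAI / naive occupancy
cooccupy report --seed 1 --outdir .      # fit H1–H4, compare, contrasts, SIF curves
```

`report` writes the comparison table, detection contrasts, predicted
detection probabilities with leopards present vs absent, tidy SIF-curve
CSVs and a summary figure; a YAML config (`--config`) can replace the
flags for scripted runs.

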