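# sealforage

A tested, reusable Python pipeline for analysing archival biologging
records from benthic-foraging pinnipeds (grey seals instrumented with
time–depth–light Fastloc-GPS tags). It takes raw 10-s dive samples and
GPS fixes through to behavioural states and their association with
oceanographic conditions measured *by the animal itself*:

1. **Quality control** — satellite-count / residual-error screening and a
   10 m s⁻¹ great-circle speed filter for GPS fixes; parsing and
   validation of tag archives.
2. **Dive processing** — zero-offset correction of transducer drift,
   dive detection (max depth ≥ 5 m, duration ≤ 30 min), segmentation
   into descent / bottom / ascent (bottom = depths ≥ 80% of max depth),
   and plausibility filters (rates < 6 m s⁻¹ and > 0; duration > 20 s).
3. **In-situ environmental covariates** — from the ascent phase of each
   dive: mean upper-50-m temperature (T₅₀), mixed-layer depth, and
   diffuse light attenuation K_d (m⁻¹) from the slope of the tag's
   log-scaled light level (20 LL units per decade of irradiance) on
   depth; chlorophyll-*a* by inverting a bio-optical model
   K_d = K_w + χ·chl^e, restricted to ≥ 50 m dives within 10:00–14:00
   Atlantic Standard Time; mean bottom-phase depth and temperature.
4. **Behavioural decoding** — tracks regularized to a 3-h step and fit
   with a two-state hidden Markov model on the first-difference
   correlated random walk (DCRW),

       dₜ | dₜ₋₁, sₜ ~ N( γ_s R(θ_s) dₜ₋₁ , σ_s² I ),

   where γ is the autocorrelation in direction and speed and θ the mean
   turning angle. Directed *travelling* (θ ≈ 0, γ high) and tortuous
   *apparent foraging* (γ low) states are decoded by Viterbi, with
   forward–backward posteriors alongside.
5. **Association models** — binomial GLMMs on the logit scale linking
   the probability of apparent foraging to covariates, with a per-seal
   random intercept and continuous-time AR(1) residual correlation
   ρ^|Δt|, fitted by penalized quasi-likelihood (PQL). The *Water
   Column Model* uses chl-*a*, T₅₀, sex and season (all two-way
   interactions); the *Bottom Conditions Model* uses bottom duration,
   bottom temperature, log bottom depth, sex and season. Coefficients
   are reported as odds ratios with Wald 95% CIs.

A synthetic-data module generates tag archives, GPS fixes (with
realistic corruption), and GLMM observation tables with known ground
truth, so every stage is testable without any deployment data.

## Worked example

Simulate a 400-step track from the reference movement parameters
(travelling γ = 0.9, foraging γ = 0.2, θ ≈ 0 for both) and refit:

```python
import numpy as np
from sealforage import synthetic as syn, hmm

cfg = syn.SimConfig(seed=42, track_steps=400)
track, true_states = syn.simulate_track(cfg, "S00")
fit = hmm.fit_hmm(track[["x_km", "y_km"]].to_numpy(), n_restarts=10, seed=42)
print("gamma:", np.round(fit.params.gamma, 3))
print("accuracy:", np.mean(fit.states == true_states))
```

```
gamma (travel, forage): [0.923 0.186]
theta (travel, forage): [0.061 0.116]
decoding accuracy: 0.935
```

The fitted autocorrelations bracket the generating values (0.9 / 0.2)
and 93.5% of steps are decoded to the correct state. Next, simulate a
Water Column dataset (40 seals × 200 observations) from the reference
coefficient set and fit it by PQL with CAR(1):

```python
from sealforage import glmm
obs, truth = syn.simulate_glmm_dataset(
    syn.WATER_COLUMN_REFERENCE_COEFS, n_seals=40, n_obs_per_seal=200,
    re_sd=0.5, rho_step=0.5, seed=42)
gfit = glmm.fit_pql_glmm(obs, glmm.water_column_model())
print(glmm.odds_ratio_table(gfit).round(3).to_string(index=False))
```

```
      term   coef    se    or  ci_lo  ci_hi     p
 intercept -0.076 0.186 0.926  0.643  1.334 0.684
       chl  0.647 0.094 1.910  1.588  2.297 0.000
       T50  0.013 0.017 1.013  0.980  1.047 0.445
       sex  1.441 0.232 4.223  2.679  6.657 0.000
    season  0.334 0.196 1.396  0.950  2.051 0.089
   chl:sex -0.348 0.106 0.706  0.574  0.869 0.001
chl:season -0.968 0.107 0.380  0.308  0.468 0.000
   T50:sex -0.054 0.020 0.948  0.912  0.985 0.006
T50:season -0.001 0.020 0.999  0.961  1.038 0.952
sex:season -0.146 0.099 0.864  0.711  1.049 0.141
```

The odds ratio of 4.2 for `sex` means females are about four times as
likely as males to be in the apparent-foraging state at baseline
covariate values (generating value e^1.40 ≈ 4.06); `or = 1.91` for
`chl` is the multiplicative change in foraging odds per 1 mg m⁻³ of
chlorophyll-*a* (generating value e^0.68 ≈ 1.97).

A `sealforage` command-line tool wraps the pipeline
(`simulate`, `filter-gps`, `dives`, `enviro`, `hmm`, `glmm`); see
`sealforage --help`.

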