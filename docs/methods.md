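# Methods

This note records the models implemented in `sealforage`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down. No empirical claim here goes beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Location quality control (`tag_io`)

Fastloc-style GPS fixes are screened on satellite count (< 5 removed)
and residual error (> 30 removed; the residual is an opaque receiver
metric, treated purely as a threshold). The speed filter then removes
fixes greedily: while any consecutive-pair great-circle speed exceeds
10 m s⁻¹, the fix participating in the fastest violating segment whose
removal most reduces the local maximum speed is dropped and speeds are
recomputed. Greedy single-fix removal is deterministic, idempotent, and
guarantees all surviving pair speeds are ≤ 10 m s⁻¹; smarter global
filters (e.g. backward-forward averaging) were out of scope because
only the threshold, not the algorithm, is part of the protocol being
reproduced. Distances are haversine on a 6371.0088 km sphere, adequate
at foraging-trip scales.

## Dive processing (`dives`)

**Zero-offset correction.** Pressure-transducer drift is estimated from
near-surface readings (< 10 m): within consecutive 6-h windows, the
0.05 quantile of those readings is taken as the surface baseline. The
baseline knot is anchored at the *time of the sample where that
quantile occurs*, not the window centre — under a monotone drift the
blocked quantile systematically lags a centre-anchored baseline by
roughly half a window, while quantile-time anchoring places knots on
the drift curve itself. Knots are linearly interpolated (and linearly
extrapolated beyond the outermost knots); corrected depths are clamped
at 0. Windows with no surface readings carry the previous baseline with
a warning. On a synthetic 0→3 m drift over 24 h the residual surface
offset stays below 0.25 m.

**Detection and phases.** A dive is a maximal run of wet samples at
depth > 0. Dives with maximum depth < 5 m (surface splash, rolling) or
duration > 30 min (merged-dive artifacts of dive-splitting software)
are discarded at detection. The bottom phase is the contiguous envelope
from the first to the last sample at ≥ 80% of the dive's maximum depth
— wiggles above the 80% line inside the envelope stay in the bottom
phase, because "time at ≥ 80%" is a duration and contiguous phases
partition the dive exactly. Descent and ascent rates are max depth
divided by the phase duration (the vendor-summary convention; phase
durations are spans between boundary sample times, so the three phases
sum exactly to dive duration). Boundary conventions are taken strictly
as printed: shallower than 5 m = strict `<`; rate cut `>= 6`; duration
cut `<= 20 s`; long-dive cut `> 30 min`.

## Environmental covariates (`enviro`)

All upper-column estimates use the **ascent** phase (a flag exposes the
descent-phase variant for sensitivity checks): T₅₀ is the arithmetic
mean of ascent temperatures at ≤ 50 m; 50 m covers most of the local
mixed layer and phytoplankton biomass.

**Light attenuation.** The tag maps 10 decades of irradiance
(5×10⁻¹² – 5×10⁻² W cm⁻²) onto light level LL ∈ [25, 225], i.e. 20 LL
units per decade, so LL is linear in log₁₀ irradiance and
LA = −b·ln(10)/20 where b is the OLS slope of LL on depth (≤ 50 m).
Whether one regresses LL or ln-irradiance on depth differs only by this
fixed scale factor, which the conversion makes explicit. Samples pinned
at either sensor limit are clipped, not informative, and are excluded;
at least 5 unclipped samples and non-zero depth spread are required,
and negative attenuation estimates clamp to 0.

**Chlorophyll-a.** LA is inverted through K_d = K_w + χ·chl^e with
defaults K_w = 0.04 m⁻¹, χ = 0.0518, e = 0.428 (Morel-type open-ocean
coefficients). Locally calibrated coefficients differ by region and are
proprietary in some calibrations, so the model is fully configurable;
the synthetic generator uses the identical forward form, which makes
the round-trip tests self-consistent without asserting anything about
any particular regional calibration. Estimates are restricted to dives
reaching ≥ 50 m whose temporal midpoint falls in 10:00–14:00 Atlantic
Standard Time (fixed UTC−4, no DST) to limit solar-zenith effects;
LA ≤ K_w maps to chl = 0.

**Mixed-layer depth** (optional output, not a model covariate): the
shallowest ascent depth whose temperature departs from the ≤ 5 m
near-surface mean by ≥ 0.5 °C; profiles with no departure report the
deepest sampled depth flagged bottom-limited. The threshold criterion
is a conventional choice; MLD is computed because the ascent cast
supports it, but no downstream model consumes it.

**Bottom conditions.** Arithmetic means of depth and temperature over
the bottom-phase samples.

## Movement model (`hmm`)

Fixes are projected to planar km by a spherical azimuthal-equidistant
projection centred on the track centroid (exact ranges from the centre;
distortion negligible at few-hundred-km trip scales; forward and
inverse are closed-form). Tracks are regularized to a 3-h step by
linear interpolation within segments; gaps of ≥ 4 steps (12 h —
haulouts, tag outages) are never bridged, because interpolating across
a gap comparable to the behavioural step manufactures perfectly
straight pseudo-steps that the travelling state absorbs with spuriously
high autocorrelation. Large-gap data can alternatively be excluded
outright via configuration.

The two-state DCRW treats each displacement as a rotated, damped copy
of the previous one plus isotropic Gaussian noise; states follow a
first-order Markov chain. The first displacement of each segment is
conditioned on, not modelled, so a segment of n positions contributes
n − 2 modelled steps; the initial state distribution δ is a free
parameter shared across a seal's segments. Locations are conditioned on
as error-free: post-filter Fastloc accuracy (tens of metres) is far
below movement-process noise at 3-h steps, so a state-space observation
model would add parameters without information.

**Fitting.** Maximum likelihood by expectation–maximization
(Baum–Welch). The state-conditional mean γ R(θ) = [[a, −b], [b, a]]
with a = γ cos θ, b = γ sin θ is *linear* in (a, b), so the weighted
M-step is an exact least-squares update — closed form, monotone in
likelihood, and free of step-size tuning; γ = √(a² + b²) is clipped to
(10⁻⁶, 1 − 10⁻⁶) and θ = atan2(b, a) wrapped to (−π, π]. σ is floored
at 10⁻³ of the rms displacement so no state can collapse onto
exactly-interpolated points (the classic degenerate-likelihood spike).
Ten dispersed restarts (θ ∈ {0, π}, γ ∈ {0.8, 0.3}, each jittered)
guard against label-switching local optima; the best log-likelihood
wins, and states are relabelled so the larger fitted γ is travelling.
Convergence: relative log-likelihood change < 10⁻⁸ (minimum 5
iterations, maximum 500). Decoding returns both the Viterbi path and
forward–backward posteriors; all recursions run in log space with
per-step rescaling. Forward likelihood and Viterbi are verified against
exhaustive 2^T enumeration to 10⁻¹⁰.

## Association models (`glmm`)

For each decoded 3-h step, covariates are medians over the seal's dives
ending within the preceding step window (t − 3 h, t] — the window over
which "conditions leading up to" a step are summarized is configurable,
with one step as the default. Season is summer (Jun–Aug) or fall
(Sep–Dec); January steps are dropped (animals return to the colony and
location coverage collapses). Bottom depth is log-transformed. Rows
missing a required covariate are dropped listwise per model — the
two-model split (water column vs bottom conditions) is itself the
missingness strategy, since chl-a exists only for noon-window ≥ 50 m
dives. Covariates are left in natural units (no standardization), so
odds ratios are per 1 mg m⁻³, 1 °C, 1 s, or 1 log-depth unit. No
multiple-testing adjustment is applied.

**Estimation.** PQL: given current probabilities μ, fit the weighted
linear mixed model z = Xβ + ν_seal + ε to the working response
z = η + (y − μ)/(μ(1−μ)) with weights w = μ(1−μ), update
η = Xβ̂ + ν̂ (BLUP), and iterate to a relative coefficient change
< 10⁻⁶ (max 50). The inner fit is REML with a per-seal random
intercept and CAR(1) residual correlation ρ^|Δt| (time in hours, so
adjacent 3-h steps correlate at ρ³; the continuous-time form prices
haulout gaps exactly). Because the ordered CAR(1) correlation is a
Markov product correlation, its inverse is tridiagonal via the
innovation decomposition

    vᵀC⁻¹v = v₁² + Σₖ (vₖ₊₁ − rₖ vₖ)² / (1 − rₖ²),
    log det C = Σₖ log(1 − rₖ²),   rₖ = ρ^Δtₖ,

and the random intercept is a rank-one Woodbury update, so each REML
objective evaluation is O(N). The profiled objective is minimized over
(logit ρ, log λ) with λ = σ_b²/σ² by Nelder–Mead, warm-started across
PQL iterations; ρ is capped at 0.995 per hour for numerical positivity.
Either component can be fixed at 0 by the model spec; with both fixed
at 0, the algorithm reduces exactly to IRLS and reproduces ordinary
logistic regression to 10⁻⁴ (verified against an independent GLM fit).
Negative ρ is supported in the standalone correlation builder only on
integer lag grids, where ρ^Δt is real.

**Inference.** Wald t statistics use containment-style degrees of
freedom determined by detection: a design column constant within every
seal is tested against n_seals − (number of between columns), the rest
against N − n_seals − (number of within columns). This assigns
sex-by-season to within-seal df, as the innermost-variation rule would;
PQL p-value conventions vary across implementations, so p-values are
diagnostics here, not reproduction targets. |β̂| > 15 triggers a
separation warning. Odds-ratio tables are the elementwise exponential
of the coefficient table with exp(β ± 1.96 SE) intervals.

## Synthetic data (`synthetic`)

The generator emulates a grey-seal-style deployment on a temperate
shelf; its defaults are the study conditions under which the recovery
suites run:

- **Movement:** two-state DCRW with travelling (γ = 0.9, θ = 0,
  σ = 2.5 km) and foraging (γ = 0.2, θ = 0, σ = 1.5 km) at a 3-h step;
  transition matrix [[0.9, 0.1], [0.05, 0.95]], giving a stationary
  foraging fraction of 2/3 and rms speeds of roughly 0.8 m s⁻¹
  travelling and 0.2 m s⁻¹ foraging. The σ values are chosen for
  realistic speeds (they are not part of any reference estimate set).
- **Dives:** benthic trapezoids to the local seafloor (smooth synthetic
  bank-and-basin bathymetry, ~40–150 m), descent/ascent rates uniform
  (0.5, 2.5) m s⁻¹, bottom fraction uniform (0.4, 0.6) of duration —
  exercising the ≥ 80% bottom rule with realistic phase statistics —
  at ~5 dives per hour with 10-s sampling.
- **Profiles:** temperature from a tanh thermocline (12 °C surface,
  30 m thermocline) plus a 0.02 °C m⁻¹ deep warming (the slope-water
  intrusion typical of shelf basins) so bottom temperature genuinely
  varies across depths; LL decays linearly in depth on the log-light
  scale with slope (20/ln 10)·K_d, K_d from the chlorophyll field
  through the same bio-optical forward model the estimator inverts,
  clamped to [25, 225], with optional Gaussian noise (default SD 0.5)
  and quantization (default 0.1 units; both set to 0 for the noiseless
  round-trip checks).
- **Gaps and corruption:** 12-h haulouts every 120 h at sea (dry
  records, GPS suppressed after the first dry fix); 15-min GPS cadence
  with 10% dropout and 2% corrupt fixes (few satellites, residual
  > 30, or a displacement implying > 10 m s⁻¹).
- **GLMM tables:** covariates drawn iid per observation
  (chl ~ logN(ln 0.8, 0.5); T₅₀ ~ N(8, 2.5); bottom duration
  ~ N(180, 60) s clipped to (20, 600); bottom temperature ~ N(5, 2.5);
  log depth ~ N(4.0, 0.6)); linear predictor from the reference
  coefficient set; per-seal intercept SD 0.5; latent CAR(1) Gaussian
  noise with SD 0.5 and correlation 0.5 between adjacent 3-h steps,
  decaying as 0.5^(Δt/3 h) across the 12-h gaps inserted with
  probability 0.05 per step; seasons split each deployment in half.
  The latent-noise SD of 0.5 represents moderate unexplained
  autocorrelated variation — about as much extra-binomial structure as
  the random intercept itself contributes.

All randomness derives from one integer seed via independent
per-(seal, purpose) streams keyed by CRC32, so a fixed seed reproduces
every output byte for byte and adding a seal never perturbs another's
data.

**What the generator does not emulate** — and hence what passing tests
do not establish about field data: no currents, fronts or real
bathymetry (movement and the environment are independent unless
configured, so recovery results say nothing about confounding between
prey fields and state switching); seals keep "moving" while hauled out
(only the records and fixes are gapped); dive shape carries no
behavioural signal; covariates in the GLMM tables are iid rather than
spatially autocorrelated; and the binary response is generated from the
PQL model's own latent-Gaussian form, so the GLMM recovery quantifies
estimator behaviour under its assumed model, including PQL's
well-known attenuation for binary responses (observed at roughly 5–10%
on these designs, within the documented 10–15% band), not robustness to
misspecification.

## Recovery studies (`studies`, `scripts/acceptance.py`)

Problem sizes were chosen to characterize the estimators at desk scale:
30 tracks × 400 steps (≈ 50 days at 3 h) for the HMM, and 20 replicates
of 40 seals × 200 observations per GLMM. The headline regression tables
of a real multi-year, ~80-animal deployment are not reproducible at
this scale; the recovery studies instead use the published point
estimates as generative truth and measure how well the machinery
returns them.

## Known limitations

- PQL is approximate for binary data; coefficient attenuation of order
  10% is expected and documented rather than corrected (no bias
  correction or higher-order Laplace refinement is implemented).
- HMM state uncertainty is not propagated into the GLMMs (states enter
  as known 0/1), and quasi-likelihoods preclude information-criterion
  model comparison.
- The speed filter is greedy, not globally optimal; pathological fix
  clusters could in principle be pruned differently by other tools.
- Negative CAR(1) correlations are defined only on integer time lags.
- No ≥ 3-state movement models, no covariate-dependent transition
  probabilities, no Argos error models, no salinity/density.
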