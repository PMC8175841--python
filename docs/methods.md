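# Methods

This note records the models and procedures wearload implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## The load-rate estimator

The estimand is the mean magnitude of the load rate — the time derivative
of the weight-bearing force on the lower limbs — in N/s. From a triaxial
accelerometer sampled on a uniform grid with step Δt, the estimate is the
mean over first differences of

    m · sqrt( Σᵢ ((aᵢ,ⱼ₊₁ − aᵢ,ⱼ)/Δt)² ),  i = x, y, z,

with *m* the body mass in kg (`loadrate.mean_load_rate_from_accel`). The
force-plate analogue is the mean |ΔF|/Δt of the calibrated vertical
channel (`mean_load_rate_from_force`): the plate's load cells measure
vertical force only, so its statistic is the 1-D magnitude. Forward first
differences are used exactly as written — no central differences and no
filtering anywhere; averaging over the many steps in a 60-s window plays
the smoothing role. Differencing cancels any constant vector, so gravity
and static sensor bias drop out of the accelerometer estimate; this is a
tested invariant. Irregular wearable timestamps must be resampled to a
uniform grid first (`signal_io.resample_uniform`, linear interpolation);
the estimator refuses non-uniform grids rather than silently mixing Δt.

Each instrument's statistic is computed on its own sampling grid (50 Hz
wearable, 128 Hz plate); the mean-magnitude form does not require the two
series to be aligned. Their first-difference discretizations differ, which
contributes a few percent of device-dependent scale — absorbed by the
regression slope downstream.

## Trial structure and calibration

Trials last 90 s: the first 20 s are habituation, the next 60 s are the
analysis window, the final 10 s are discarded. The window is half-open,
[20 s, 80 s) relative to the first sample, so a uniform grid yields
exactly rate × 60 samples (7680 at 128 Hz, 3000 at 50 Hz); timestamps are
re-zeroed to the window start. Force-plate voltages (the four load-cell
channels summed into one signal) are mapped to newtons by an
ordinary-least-squares line fitted to known weights (force = weight · g,
g = 9.81 m/s²); the fit's R² is reported and the calibrated flag is
tracked so the load-rate stage cannot consume raw volts.

## Model specifications

With x the wearable estimate and y the force-plate value per trial, three
nested specifications are fitted per device:

- M1: y = α + βx (ordinary least squares);
- M2: adds a Gaussian per-participant random intercept aᵢ;
- M3: adds random intercept and slope (aᵢ, bᵢ).

Estimation is by maximum likelihood, not REML, so nested log-likelihoods
are comparable. Mixed fits go through statsmodels' MixedLM after both
variables are rescaled by mean |x|: load rates are O(10⁴) N/s while slopes
are O(1), and without rescaling the intercept- and slope-variance
parameters differ by eight orders of magnitude and stall the optimiser.
Reported effects and variance components are transformed back to the
original units. Two numerical safeguards apply:

- optimizer cascade — L-BFGS first, then BFGS, CG and Powell; candidates
  with non-finite parameters or non-finite log-likelihood are rejected,
  and because a mixed model nests OLS its ML log-likelihood can never fall
  below the OLS fit, any solution materially below that floor is treated
  as a failed fit;
- perfect-data shortcut — when the OLS residuals are numerically zero the
  profiled likelihood is undefined, so the fit returns the exact line with
  all variance components zero (the correct degenerate limit).

When a random-effect variance collapses to zero the covariance matrix is
singular and the corresponding predicted effects (BLUPs) are identically
zero; the fit reports them as such instead of failing.

## Agreement metrics and bootstrap cross-validation

R² is the squared Pearson correlation between conditional predictions
(fixed effects plus predicted random effects) and observations — the one
definition that puts M1–M3 on a single scale. RMSER is
sqrt(mean squared error) / mean(y); the name "root-mean-squared error
ratio" fixes the square root's position. Both are scale-invariant, a
tested property. R² is reported missing when either vector is constant;
RMSER is still computed.

Uncertainty: B resamples of the observation rows, drawn with replacement
to the original length; the model is refitted on each resample and scored
on the out-of-bag rows (rows never drawn, ~37% of the table). Out-of-bag
rows from a participant absent in the resample are predicted from fixed
effects alone and the event is logged; a resample with fewer than two
out-of-bag rows is redrawn. Point summaries are means over the B values;
intervals are 2.5/97.5 percentiles. Resampling individual rows (not
participant clusters) is the default, matching the described procedure; a
cluster-bootstrap mode is available via `cluster=True`. All draws come
from one seeded generator, so results are bit-reproducible.

Known limitation: out-of-bag evaluation is pessimistic. Each resample fit
sees ~0.632·n distinct rows, so the out-of-bag R² is biased below the
population conditional R², and percentile intervals of a biased statistic
under-cover that population value (measured ~0.66 rather than the nominal
0.95/0.80 in the replicate experiment the test suite runs). The bias
shrinks with table size. This is a property of the prescribed procedure,
not of its implementation; a .632-style correction would remove it but is
deliberately out of scope.

## Comparison statistics

One-way ANOVA over the B bootstrap values asks whether mean R² (or RMSER)
differs across models or devices; Bonferroni-corrected two-sample t tests
(family α divided by the number of unordered pairs: 0.05/3 for three
models — the thresholds 0.05/4 = 0.0125 and 0.05/6 = 0.0083 are exposed by
`bonferroni_alpha` for four and six comparisons) locate the differences. A
"best" model or device is declared only when all its pairwise comparisons
are significant. Normality of each bootstrap distribution is screened with
a one-sample Kolmogorov–Smirnov test against a normal with the sample's
own mean and SD; estimating both parameters from the sample makes the
nominal p-values conservative (the Lilliefors caveat), accepted and noted.
The ANOVA treats bootstrap values as plain samples and therefore inherits
their dependence; the package reproduces that procedure as described and
flags the caveat rather than replacing it.

## The synthetic generator

The generator replicates the study conditions: 12 participants (body mass
~N(71, 9²) kg), 6 bodyweight-support levels (30–110% of body weight) × 3
belt speeds (5/8/12 km/h), 90-s trials, wearables at 50 Hz, force plate at
128 Hz. Participant 12 completes only the 5 and 8 km/h trials; the
exclusion stage then removes participant 1 entirely and participant 2's
5 km/h trials, leaving 186 analysed trials per device out of 216 planned.

Two fidelity levels:

**Summary level** (`simulate_summary_dataset`) draws (x, y) pairs directly
from the M3 generative process: x is lognormal with location increasing in
speed and supported weight (scale 12 000 N/s at 8 km/h and 100%
bodyweight, shape 0.25), and y = α + βx + aᵢ + bᵢx + ε with defaults
α = 2000 N/s, β = 0.9, SD(aᵢ) = 1500 N/s, SD(bᵢ) = 0.20, SD(ε) = 2500 N/s.
These defaults place the out-of-bag R² of M1/M3 in the 0.6–0.9 band
typical of wearable-against-force-plate agreement while keeping all load
rates in the physiological 10³–10⁴ N/s range. Because a load rate is
positive, the Gaussian residual is left-truncated so y > 0; at the default
noise this touches well under 1% of draws and is negligible for parameter
recovery (a tested property).

**Signal level** (`simulate_trial`) synthesises the waveforms. The
vertical ground-reaction force is periodic at the step frequency
(cadence = step_freq_base + 0.12 · speed, ≈2.0 Hz walking to ≈2.8 Hz
running). Below 6.5 km/h the cycle shape is a smooth dual-peak profile,
1 + 0.15·cos(2πφ) + 0.35·cos(4πφ) — continuous loading with the M-shape of
walking; at and above it, a raised-cosine impulse with a flight phase
whose duty factor shrinks with speed (sharper impacts, higher load rate).
Both shapes have exactly unit mean over the cycle, so the time-averaged
force equals the supported weight (pct/100 · m · g) — conservation is a
tested invariant, and load rate grows monotonically with both speed and
supported weight. The wearable sees the same waveform divided by body
mass, scaled by a per-participant attenuation (~N(0.75, 0.08), the
soft-tissue/upper-body damping), multiplied by a per-trial lognormal
coupling jitter (shape 0.12 — strap tension and posture vary between
trials), mixed onto three axes (mostly vertical), offset by gravity on the
vertical axis, and corrupted with white noise per axis (0.25 m/s² for the
chest smartphone SP1, 0.55 m/s² for the wrist smartwatch SW1). With
attenuation 1 and all noise off, the accelerometer- and force-derived
statistics agree to within the two grids' discretization error — the
consistency check tying the two halves of the pipeline together.

What the generator does not emulate: horizontal force components,
treadmill vibration, musculoskeletal dynamics, wrist-specific
non-stationary motion (gesturing), or any speed-dependent calibration
curvature. Passing tests therefore demonstrate that the statistical
machinery recovers what this generative process encodes — not that real
wearable data meet the model's assumptions.

## Problem sizes and defaults

Bootstrap default is B = 100 for desk-scale runs and the end-to-end
replica (B = 1000 for a full replication; both are flags). The test suite
uses study-sized tables (12 × 18) for behavioural properties, 100
participants × 18 for parameter recovery (40 replicates), and 50
replicate experiments at B = 100 for interval coverage. Mixed-model
tolerance follows statsmodels' optimizer defaults with maxiter = 200.
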