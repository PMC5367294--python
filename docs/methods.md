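# Methods

## What the package measures

A peck is treated as a movement sequence anchored by three operational
events, all defined on marker coordinates after smoothing:

* **head fixation** — the first frame of the last pre-reach interval of at
  least `min_still_frames` (default 10) consecutive frames whose
  instantaneous head speed is below `speed_threshold_cm_s` (default
  2 cm s⁻¹), taken before the global speed peak of the reach. The thresholds
  are declared defaults, not estimates: the underlying behavioural notion
  ("a rapid standstill in front of the food") carries no canonical numbers.
* **grasping onset** — the first frame at or after fixation where the bill
  aperture (Euclidean distance between upper and lower bill-tip markers) has
  opened 20% of the way from its fixation-frame baseline to its maximum.
  The closed bill has nonzero marker separation, so the rule is applied to
  the baseline-subtracted aperture by default; an absolute-fraction-of-max
  variant is selectable (`onset_rule="absolute"`).
* **grasping offset** — the frame of minimal aperture after the aperture
  maximum. The minimal aperture is generally nonzero because the food is
  held between the tips.

Four per-peck parameters feed the models: grasping-onset time (s from
fixation), movement distance (total head path length), mean velocity (mean
of per-step speeds, fixation→onset) and mean acceleration (mean of per-step
speed differences, fixation→onset). Mean velocity times window duration is
exactly the fixation→onset path length, and mean acceleration telescopes to
(v_end − v_start)/duration; both identities are enforced by tests.

**Movement distance spans the whole peck (fixation→offset) by default**,
with the fixation→onset window available via `distance_endpoint="onset"`.
The whole-peck reading matters statistically, not just semantically:
distance is a covariate in the grasping-onset model, and a distance that
itself terminated at onset would be shortened mechanically by any advanced
onset — conditioning on it then absorbs or even sign-flips exactly the
timing effects the model is meant to expose (a post-treatment/mediator
artifact). With the whole-peck path the covariate reflects where the reach
happened, not when grasping started.

## Smoothing

Zero-phase (forward–backward) 4th-order Butterworth low-pass at 5 Hz,
applied independently to x and y before any detection. Zero-phase
application avoids the group delay that would bias every event time;
order 4 is the common kinematics default. Edges use odd-reflection padding
of at least three filter lengths. Events are therefore unbiased but not
noise-free: at the study's marker noise scale (σ = 0.05 cm) the onset frame
is recovered within ±2 frames (≈6.7 ms at 300 frames s⁻¹) in ≥95% of
simulated pecks.

## Statistical models

**Success GLMM.** Pecking outcome y_ij ∈ {0,1} for peck j of individual i:

    y_ij ~ Bernoulli(p_ij),  logit(p_ij) = x_ijᵀβ + u_i,  u_i ~ N(0, σ_u²)

with phase (seven levels, control as reference) as the fixed factor. The
marginal likelihood integrates each u_i out by adaptive Gauss–Hermite
quadrature: nodes are recentred at the conditional mode and rescaled by the
conditional curvature (a Laplace rescaling), 15 nodes by default. The
quadrature agrees with brute-force trapezoidal integration to 1e-6 per group
and estimates are stable from 7 to 25 nodes to 1e-4. With σ_u fixed at 0
the fit coincides with ordinary logistic regression to machine precision.

**Grasping-onset LMM.** onset_s ~ phase + distance + mean acceleration with
the same random-intercept structure. Mean velocity is excluded because it is
collinear with distance (their product identity above makes this exact up to
the duration). The fixed effects and residual variance are profiled out in
closed form, leaving a one-dimensional search over θ = σ_u²/σ_e²; a boundary
solution is reported as σ_u² = 0, where the fit equals OLS. ML and REML are
both available; ML is used wherever a likelihood-ratio test follows.

**Inference.** Fixed terms are tested by Type-II likelihood-ratio tests
(each term dropped from a model that respects marginality for interactions)
on ML fits; the phase factor with seven levels contributes 6 degrees of
freedom under reference coding. Per-phase comparisons use Wald 95% CIs of
the linear predictor at each phase with covariates held at their sample
means; a phase "differs from control" when the two intervals do not overlap
(a deliberately conservative, graphical-style rule; a CI-of-difference
variant is selectable). Under (quasi-)complete separation — e.g. a phase
with no failures — the Wald interval is meaningless; such phases are
reported with unbounded intervals and never flagged.

**Dispersion.** The binomial fit's Pearson ratio: squared Pearson residuals
at conditional fitted values (random intercepts at their modes) divided by
n − p − n_groups. For strictly binary rows a calibrated fit has ratio ≈ 1
by construction, so duplicated/clustered outcomes are invisible at the row
level; `dispersion(..., aggregate=True)` first pools rows with identical
fitted values and group into binomial cells, where such duplication does
inflate the ratio.

**R².** Nakagawa-style marginal and conditional R²:
σ²_f / (σ²_f + σ_u² + σ²_resid) and (σ²_f + σ_u²) / (same), with σ²_f the
population variance of the fixed-effect predictor and σ²_resid = π²/3 on the
latent scale for the binomial-logit model. With σ_u² = 0 the marginal R²
equals the classical OLS R² exactly (both use the ML variance convention).

**Standard errors and a small-sample caveat.** Fixed-effect SEs for the
GLMM come from the full observed information (β and log σ_u jointly);
conditioning on σ̂_u would understate intercept uncertainty further. Even
so, with only three individuals the Wald interval for the intercept
undercovers (~80% instead of 95% in simulation, largely independent of σ_u)
because the between-individual variance is barely estimable from three
draws. Coverage is near-nominal by ten groups. Conclusions that rest on the
intercept's absolute level with few individuals should be read accordingly;
phase *contrasts* are much less affected because the intercept uncertainty
is shared.

## The synthetic experiment

The generator emulates a sagittal 2-D peck toward food at the origin
(x positive toward the target, y up, cm, 300 frames s⁻¹):

* a pre-reach **approach** (min-jerk, 3–4 cm over 0.7 s) ending in a
  **standstill** of 58–63 frames (~200 ms) at the fixation point;
* a **reach** along a gently curved quadratic-Bézier arc with minimum-jerk
  displacement s(τ) = L(10τ³ − 15τ⁴ + 6τ⁵) over 0.50 s (pigeon) / 0.55 s
  (crow), from a fixation distance D ~ N(μ_D, σ_D) truncated to feasibility
  (pigeon μ 8.0, σ 0.7; crow μ 15.0, σ 1.2 cm);
* **bill tips** one effective bill length ahead of the head along the path
  tangent — 2.3 cm (+1 cm extension when attached) for pigeons, 6.5 cm
  (+2 cm) for crows — rotated symmetrically apart so the tip-to-tip distance
  follows a raised-cosine open–close aperture pulse (rest → peak → offset
  aperture, the offset floor set by the held food);
* **opening trigger**: the bill starts opening when the remaining head path
  drops below a species-typical distance (3 cm), so onset time covaries with
  movement distance as in real pecking; phase effects shift this time
  (delay under naive extension use, advance as the removal after-effect),
  the fixation distance, and the success logit;
* **success** ~ Bernoulli(logistic(base + phase shift + individual
  intercept)), base logit 2.2 (≈90% control success), individual intercepts
  N(0, σ_u) with σ_u = 0.4 by default;
* i.i.d. Gaussian **marker noise** (σ = 0.05 cm) added per marker per frame.

Ground truth is obtained by applying the operational event definitions to
the noiseless, unfiltered sampled kinematics with an independent minimal
run-finder, so truth is consistent with the emitted tracks by construction
while staying independent of the extraction code. Three design choices make
the discrete landmarks well-posed rather than artifacts of rounding: the
analytic 20% crossing is snapped to the centre of a frame interval (<½-frame
shift); the approach is slow enough that its deceleration tail lies deep in
the 5 Hz passband; and the standstill jitter is kept narrow, because a
widely varying standstill couples the fixation→onset window length into
mean acceleration and lets the acceleration covariate soak up phase timing
effects.

The two presets encode the study's qualitative contrast at the study's
per-phase peck counts (pigeons 118/49/221/218/231/84/53, total 974; crows
80/23/61/65/88/30/31, total 378, pooled over three individuals):
"pigeon-like" applies a persistent success deficit (−2.9 logits) and a
+30 ms onset delay across all extension phases, with a −2.5 logit deficit
and a −40 ms advanced onset (the motor after-effect) immediately after
removal; "crow-like" applies a transient S1-only deficit (−2.5 logits,
+20 ms) with reaches initiated ~1 cm closer through S5-7 and full recovery
thereafter, and no after-effect.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: head rotation and marker occlusion (gaps must be
injected explicitly), non-Gaussian tracking error, trial-to-trial variation
in reach vigor or aperture shape, within-session learning curves, 3-D
geometry projected to 2-D, and any online feedback control; the generated
success outcomes follow exactly the logistic model the GLMM assumes, so
model-recovery results certify the fitting machinery, not the model's
adequacy for real pecking.

## Problem sizes and numerics

The test suite simulates both species at full study scale (974 + 378 pecks)
for the qualitative-contrast checks, uses 30 groups × 200 observations for
GLMM parameter recovery, 900 observations for LMM slope recovery, 500
replicates for the null LRT size check, and 120 replicates per condition
for CI-coverage estimates; the acceptance script reruns both full-scale
presets end to end. Optimizer details: L-BFGS-B over (β, log σ_u) with
bounded restarts for the GLMM (IRLS logistic start), Brent's method on
log θ with an explicit boundary comparison for the LMM; quadrature modes by
damped vectorized Newton to |grad| < 1e-11; numerical Hessians by central
differences (h = 1e-4). Ties in the aperture maximum resolve to the
earliest frame; 20% crossings use the first frame at-or-above threshold
with no sub-frame interpolation. CSVs are written at %.17g and read with
round-trip float parsing, making report bundles byte-reproducible from the
manifest's config and seed.

## Known limitations

* The session structure within grouped phases (S2-4, S5-7, S8-10) is
  represented by one representative session index per phase; the phase
  factor therefore has 6 df, and no within-phase learning trend is modeled.
* Wald CIs only (no profile or bootstrap); see the small-sample caveat
  above.
* The fixation detector assumes a single reach per track window; multi-peck
  bouts must be segmented upstream.
* Random effects are a single intercept per individual; no crossed or
  nested structures.
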