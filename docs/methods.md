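# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the package, in the order data flows
through the pipeline.

## Study designs

Two designs are built in. The *real-environment* design has 9 aperture
widths from 35 to 75 cm in 5 cm steps, a randomized task (5 sequences of
one pseudo-random permutation of the 9 widths each) and an ordered task
(10 sequences, 5 increasing 1..9 and 5 decreasing 9..1, shuffled with no
more than two equal directions in a row) — 45 + 90 trials per participant.
The *virtual-environment* design repeats a randomized/ordered task pair
without and with a visible virtual body: 4, 8, 4, 8 sequences (36 + 72 +
36 + 72 trials). Sequence indices count globally across tasks and drive
the fatigue covariate.

## Generative posture law

The generator draws each trial's *scaled rotation* from

    y = TruncNormal( logistic(lp), σ_ε²; 0, 1 ),  clipped to (1e-6, 1-1e-6)
    lp = β₀ + β_ratio (A/S − 1.375) + Σ_f β_f code_f + u_i,  u_i ~ N(0, σ_u²)

with factor codes randomized/real/increasing/body-invisible = −1 and their
counterparts +1, and fatigue linear from −1 (first sequence) to +1 (last).
The order code of trial *n* comes from the width comparison with trial
*n − 1* (first trials get 0; they are excluded from every analysis, so the
choice is inert). The anchor 1.375 is the mean design ratio for a 40 cm
shoulder; it fixes the preset calibration while the analysis pipeline still
centers empirically. Noise is applied on the scaled-rotation scale and
truncated to the unit interval, which makes the generator the exact inverse
of the fitted observation model (see below).

**Presets.** Parameter sets are calibrated analytically against published
group-level critical ratios by solving the two-point logistic equations
logit(0.5) = lp(x₅₀), logit(0.05) = lp(x₀₅):

* `real_env`: x₅₀ = 1.024, x₀₅ = 1.207 → β_ratio ≈ −16.09, β₀ ≈ −5.65.
* `virtual_env`: x₅₀ = 1.245, x₀₅ = 1.428 (same slope).
* `combined`: critical ratio centered at 1.3175 with environment shifting
  it by ±0.1105 and order by ±0.0145, i.e. β_env = −β_ratio·0.1105 ≈ 1.78,
  β_order = −β_ratio·0.0145 ≈ 0.23 (the curve-shift identity −2β_f/β_ratio
  run backwards).
* `exp2_feedback`: slope −10.014 around a 1.580 critical center, with
  body-visibility (±0.040), order (±0.014), and fatigue (±0.077) shifts.

Defaults chosen once and documented as generator settings: σ_u = 0.5 on
the linear-predictor scale (≈ 0.03 between-participant SD in ratio units),
σ_ε = 0.05 on the response scale, per-trial failure probability 0.065 for
the virtual design and 0.0011 for the real design — in the real design a
failure aborts and flags the *whole* sequence (restarted with the same
plan), so ≈ 1% of trials are lost; in the virtual design only the failed
trial is dropped (≈ 6.5%). Anthropometry (no cohort values are published,
so these are declared defaults): shoulder width ~ N(40, 3²) cm, hip width
~ N(34, 3²) cm, both truncated at ±3 SD; maximum rotation ~ N(85, 5²)°.

## Marker-trajectory synthesis

Ten markers (LAC/RAC, C7/T8/IJ/PX, LASI/RASI/LPSI/RPSI) ride on one rigid
trunk/pelvis body whose template puts the acromion markers exactly one
shoulder width apart and the anterior pelvis markers one hip width apart,
at fixed declared heights. The walker traverses a 5 m walkway (aperture at
2.5 m) back and forth, one pass per trial, 3 s per pass at 100 Hz, with a
cosine pace profile. Trunk yaw follows a raised-cosine bump spanning the
central 40% of each pass, peaking exactly at the aperture crossing with the
trial's true rotation angle; its sign is a per-participant rotation side
drawn once (p = 0.5) and held fixed, mirroring the empirical consistency of
rotation direction within participants. The bump form is a convenience —
any smooth unimodal profile works — chosen for its closed-form peak. The
generator does **not** emulate gait-cycle detail (steps, arm swing, pelvis
list), soft-tissue artifact, marker dropout, or segment-specific yaw
differences (all three segments share the trunk yaw); passing kinematic
round-trip tests therefore validates the geometry/angle chain, not
robustness to real-world marker noise.

## Kinematics

Segment centers: SC = (LAC+RAC)/2, TC = (PX+IJ+C7+T8)/4, PC = mean of the
four pelvis markers. Direction vectors: v_shoulder = RAC − LAC; for thorax
and pelvis a forward support vector (front minus back marker midpoints) is
crossed with the global vertical, which projects it into the floor plane.
The pass frame per segment is the local minimum of |y_center − y_aperture|;
the series is smoothed with a 5-sample moving average and minima closer
than 1 s are suppressed (the pass spacing is ≥ 3 s, so this only removes
jitter), and the detector *requires* exactly the expected 9 minima per
sequence, failing loudly otherwise. α = |atan2(v_y, v_x)| in degrees, with
v negated first for passes toward the start position so a straight pass
reads 0° in both walking directions — the only reading under which α = 0
for straight passes holds across back-and-forth trials. Walking direction
is inferred from the center velocity just before the pass frame. Gaps are
not filled; a corrupt sequence is rejected rather than repaired.

## Trial preparation

Analyses assemble their own data sets — *combined* (all real-environment
trials plus body-visible virtual trials), *feedback* (all virtual trials),
and a single-environment *exp1* reduction — and recompute max-scaling and
ratio centering per assembled set (the alternative, global scaling, is not
self-consistent when sets overlap). Exclusions, in priority order: whole
aborted sequences (real), failed trials (virtual), and every sequence's
first trial (no predecessor for the order code). The participant × segment
maximum used for scaling is taken over included trials only. Fatigue in
the combined analysis is rescaled within each experiment (15 vs 24
sequences) so the covariate stays in [−1, +1] for both cohorts.

## Posture model

The response is a continuous proportion, for which a binomial GLMM is
ill-defined; the package instead fits a nonlinear mixed model with the
logistic mean *inside* the link and truncated-Gaussian observation noise:

    y | u ~ TruncNormal(logistic(Xβ + u), σ_ε²; 0, 1),  u ~ N(0, σ_u²)

The truncation matters: without it, the model is biased wherever the
logistic mean sits within ~2σ_ε of the bounds — which is the entire
wide-aperture half of the design, where participants walk straight — and
the truncated density also makes the likelihood the exact inverse of the
generator. The marginal likelihood integrates each participant's intercept
with adaptive Gauss–Hermite quadrature (9 nodes; Laplace-centered using a
Gauss–Newton curvature, with the participant modes warm-started across
objective evaluations). Optimization is bounded L-BFGS-B on (β, log σ_u,
log σ_ε) with three jittered restarts (log σ_u ∈ [ln 1e-4, ln 5], so a
vanishing random effect collapses gracefully to the fixed-effects limit);
responses are clamped to [1e-6, 1 − 1e-6]. Standard errors come from the
inverse observed information (numeric central-difference Hessian), p-values
from the two-sided normal approximation of the Wald z — no small-sample
degrees-of-freedom correction. BIC = −2ℓ + k ln n with k counting fixed
effects plus the two variance parameters. Effect sizes are odds ratios
exp(β). Interactions are products of the ±1 codes.

## Thresholds

The iso-level inversion x(L) = (logit(L) − β₀ − Σ β_f·setting_f)/β_ratio
(plus the centering mean) yields the point of change (L = 0.5) and critical
value (L = 0.05), both exposed as configuration. Factor shifts use the
translation identity −2β_f/β_ratio; interaction terms are excluded from
these formulas — justified when interactions are negligible (parallel
curves) — and a warning is emitted whenever a fitted interaction exceeds
10% of its larger main effect. The fatigue drift per sequence divides the
total −1→+1 shift by (n_sequences − 1) steps and is reported in percent of
body width.

## Variance model

SDs (n − 1 denominator) of the scaled rotation are computed per participant
× segment × aperture level × factor combination; fatigue is aggregated out
to obtain repetitions, and singleton groups are dropped (audited). The SD
model is a Gaussian random-intercept LMM fitted by REML (statsmodels
MixedLM) for estimates and by ML for the BIC used to compare fixed-effect
structures — REML log-likelihoods are not comparable across different
fixed effects. The expanded model adds the logit-derivative regressor
p(1−p), with (a, b) taken from the corresponding segment's posture fit at
reference factor settings (the stated purpose of the regressor is to align
the variance model with the posture curve; it is used unscaled, peaking at
0.25). The semi-partial R²_β is a documented approximation in the
marginal-R² style: var(Xβ̂)/(var(Xβ̂) + σ_u² + σ_ε²) for the full model,
minus the same quantity with the effect removed (ML refits), floored at 0 —
not a replication of any specific package's internals.

## Problem sizes and determinism

Simulation-based checks run at the designs' native sizes: the
real-environment study with 27 participants (15 sequences each) for the
full-pipeline critical-ratio recovery, and 24 + 24 participants for the
combined-preset parameter-recovery study (50 seeded replicates, each fit
on ≈ 5,000 trials). All randomness flows through per-stage generators
derived from a single seed; identical seeds reproduce byte-identical trial
tables and reports.

## Known limitations

* The absolute published critical values are data-dependent quantities of
  an unavailable raw data set; the package validates *differences* against
  published estimates analytically and absolute values against its own
  calibrated presets.
* One latent rotation drives all three segments in the generator, so
  synthetic thorax/pelvis analyses do not probe segment-specific effects.
* Thresholds carry no confidence intervals (delta-method or bootstrap
  extensions would slot into `thresholds.py`).
* The variance LMM treats SDs as Gaussian; very small groups (2–4
  repetitions) make individual SDs noisy, which the model absorbs in the
  residual rather than via a sampling-distribution-aware likelihood.
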