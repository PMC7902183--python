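# Methods

This note documents the models the package implements, the defaults it
ships, and the choices made where the underlying procedures left room for
interpretation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Psychometric model

Every simulated response comes from a logistic psychometric function

    p(correct | x) = γ + (1 − γ − λ) · F(β (x − θ)),   F(u) = 1/(1+e^−u)

with threshold θ (the 50 %-corrected point), slope β, guess rate γ and
lapse rate λ. The cumulative logistic was chosen over the cumulative
Gaussian because it is closed-form and only the midpoint and steepness
matter to any downstream quantity. Level axes follow "higher is better":
dB SNR for the speech tests, dB HL for tone audibility, and log2(gap ms)
for gap detection — temporal thresholds behave Weber-like, so a doubling
of the gap is one unit of difficulty. Default guess rates reflect task
structure: 0 for open-set sentence repetition, 0.1 per digit for the
closed set of ten digits, 0 for the gap task as configured (not a forced
choice). A `deterministic_step` mode (correct iff at-or-better-than
threshold) provides an exact oracle for every staircase. Psychometric
slopes of real subjects on these tests are unknown; simulation defaults
(≈1/dB for speech and tones, ≈4–6/octave for gaps) are free parameters of
the virtual listeners, not estimates of any cohort.

## Adaptive procedures

All levels are quantized to a 0.1-unit grid so tracks are bit-stable, and
every procedure is a pure function of (listener, config, seed).

**Békésy-like audiometry.** Pulsed 250 ms tones (20 ms rise/fall, 500 ms
ISI) descend 4 dB per presentation while "heard", switching to 2 dB after
the first reversal; unheard tones ascend 2 dB. "Six good reversals" is
read as all reversals after the first — the initial direction change still
reflects the 4 dB descent and is excluded — and the threshold is the mean
of the good-reversal levels rounded to the grid (the source procedure
counts reversals without printing a formula). Tracks that cannot collect
the required reversals within 400 presentations, or that pin against the
level floor/ceiling for 10 presentations, are flagged non-converged.

**Gap detection.** Single staircase: the gap shortens after two
consecutive correct identifications and lengthens after two consecutive
misses or a third cumulative miss. The published rule does not fix the
scope of the cumulative-miss counter; here it resets at each reversal
(default) or counts over the whole run (`miss_counter_scope="whole_run"`),
and in both scopes a lengthening consumes the accumulated misses so the
rule re-arms — without that, a single excursion past three misses would
drive the track upward forever, including on correct responses. The step
schedule (start 20 ms, step 4 ms halving at each reversal to a 1 ms floor,
stop at 6 reversals, estimate = mean gap at the last 4 reversals) is a
conventional parameterisation, config-exposed because the source cites
prior work without printing values.

**Sentence-in-noise (HINT).** Noise fixed at 65 dB(A); sentence level
moves down after a correct repetition and up after an incorrect one, 4 dB
for the first four sentences and 2 dB thereafter (the standard protocol's
step change, adopted because the study description omits step sizes). The
SRT is the mean presentation level of sentences 5–20, read literally: no
virtual 21st sentence is appended. The composite SNR is the unweighted
mean of the noise-front/right/left SRTs; the quiet condition can be
simulated but never enters the composite. A missing condition makes the
composite missing — nothing is imputed.

**Triple-digit test (TDT).** Presentations come in pairs of positive- and
negative-phase maskers at identical SNR, phase order randomized per pair,
masker fixed at 75 dB SPL. After each pair the target moves ±1.5 dB per
digit scored on the positive-phase presentation (−4.5…+4.5 dB per pair);
negative-phase responses are recorded but never drive the level or the
SRT. The count "30 total presentations with six practice presentations"
is interpreted as 6 practice + 30 test presentations (3 + 15 pairs): an
inclusive reading would leave only 12 positive-phase presentations, fewer
than the 14 the SRT window requires. The SRT is the mean SNR of the last
14 positive-phase test presentations.

## Ex-Gaussian response times

The response-time model is the convolution of Normal(μ, σ²) and
Exponential(τ); mean μ+τ, variance σ²+τ². The density is evaluated via
`scipy.stats.exponnorm` (shape K = τ/σ), whose erfcx-based form is stable
deep into the tail. Fitting maximises the exact log-likelihood over
(μ, log σ, log τ) — the log parameterisation enforces positivity without
constraints — by Nelder–Mead from moment-based starts
(τ₀ = s·(skew/2)^{1/3} clipped to [1 ms, s], μ₀ = m − τ₀,
σ₀² = max(s² − τ₀², (0.1 s)²)). The fitting algorithm is the
implementer's choice; MLE was selected as the standard, well-calibrated
default. When the sample skew is within ~2 standard errors of zero the
exponential component is unidentified and τ is pinned at a 10⁻³ ms floor
with a warning rather than letting the optimizer chase a boundary. Failed
optimizations return the moment estimates flagged non-converged. Both the
plain mean of correct-response times and the fitted μ are exported per
subject-visit.

## Selection rules

Four rules run in a fixed order on the long visit table: (1) drop visits
beyond 1278 days (3.5 years at 365.25 d/yr); (2) drop subjects with fewer
than four remaining visits ("3 or fewer" read literally); (3) drop
subjects with any retained-visit audiometric threshold > 25 dB HL at
0.5–4 kHz in either ear, tympanogram type outside {A, As, Ad}, peak
pressure outside [−100, +50] daPa, or static admittance outside
[0.3, 1.7] mmho; (4) drop subjects with any positive history flag. The
hearing/middle-ear screen is subject-level over any retained visit — the
conservative reading of "individuals were excluded" — and history flags
default to any-visit assessment with a baseline-only switch. Because
truncation precedes the visit count, a subject with four visits of which
one lies beyond the horizon is excluded; the audit attributes each subject
to the first responsible rule, with missing tympanometry reported under
its own label. The rules are idempotent.

## Scoring and grouping

Norms are the mean and SD of each variable over HIV-negative subjects'
reference visits — by default their *last* retained visit, matching the
visit used for grouping so both sides of the standardization sit at the
same stage of the learning curve (baseline is available as an
alternative). z-scores are sign-flipped for lower-is-better variables so
higher z is always better. The combination CAT score is the unweighted
mean of the three CAT z-scores at the subject's last visit and requires
all three (grouping is the primary classifier and must be unambiguous);
subjects missing a component are left ungrouped with an audit label.
Cut-points are empirical 0.20/0.80 quantiles with linear interpolation
over the entire cohort's scores (HIV-negative included) — the reading that
makes unequal extreme-group sizes possible — with boundary ties assigned
to the extreme group (≤ / ≥); a within-HIV-positive scope is available.
The global executive score averages the Cogstate subtests except One
Back; the global speed score averages the visual-attention speed measures
plus One Back; the global CAT score averages the three CAT z-scores.
Composites tolerate up to 50 % missing components (configurable); the
attention comparison score enters no composite and is analyzed standalone.
MoCA is analyzed on its raw scale.

## Trajectory model

For each outcome, `y_ij = β₀ + β_g + β_a age_i + (β_t + β_tg) t_ij +
β_ag age_i + b_0i + b_1i t_ij + ε_ij` with group fixed effects against the
HIV-positive reference, age fixed at each subject's age at last visit (as
specified, not time-varying), time in days from first visit, and subject
random intercept + slope with free 2×2 covariance. "Individual subject
result variation over time" is read as subject-specific trajectories; a
singular random-effects covariance triggers an automatic intercept-only
refit, flagged. Estimation is REML by default (ML available) via
`statsmodels` MixedLM; internally time is rescaled to years
(`time_scale=365.25`) purely for numerical conditioning — a day-scale
random-slope variance of ~10⁻⁷ square-units is poorly scaled against an
intercept variance near 1 — and all reported slopes are per day.
Inference is large-sample Wald z, the simplest defensible default at
~380 subjects; no degrees-of-freedom correction is applied. The report
table renders per-group slopes ×10⁻⁴/day with "Ref" in the reference
group's interaction cells, keeps the HIV-negative group in the model but
out of the headline contrasts, applies no multiple-testing correction to
the per-outcome p-values, and appends a Benjamini–Hochberg-adjusted
column clearly labelled as an extension.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: group
sizes 90/164/53/75; group age distributions Normal(25.9, 11.8),
(40.8, 13.6), (38.1, 12.8) and (42.1, 8.4) years clipped to [18, 70];
visits every 182 days with 14-day Gaussian jitter (minimum 90-day
spacing) truncated at 1278 days; and a 6 % per-visit geometric dropout
hazard. Outcomes follow the trajectory model's own generative equation.
Effect sizes are parameterised on a performance-z scale and mapped into
each outcome's natural units: a learning slope of +4×10⁻⁴ z/day for the
HIV-negative and HIV-positive groups (+4.5×10⁻⁴ for TopCATs), a
flat-to-declining −1×10⁻⁴ z/day for BottomCATs, an age effect of
−0.02 z/yr, random intercept SD 0.8 z and slope SD 5×10⁻⁴ z/day with
correlation −0.2, and residual SD 0.5 z. The ±3×10⁻⁴ z/day slope
difference used in the calibration checks gives the time×group Wald test
roughly 80 % power at the full design (75 vs 164 subjects over up to
8 visits); this is a deliberate calibration of the synthetic conditions,
not an estimate of any real cohort, whose learning-effect magnitude is
unknowable from the published record. Latent CAT ability and grouping are
linked — BottomCATs subjects are generated 1.3 z worse on every CAT, well
over one reference SD on the combination score — so the last-visit
quantile labels are recoverable rather than arbitrary. Audiometry,
tympanometry and history columns default to values inside all selection
rules so the filter stage runs without shrinking the designed groups;
abnormal subjects can be injected by editing those columns. In
adaptive-CAT mode the latent gap/HINT/TDT values become listener
thresholds and the staircase simulators produce the observed scores,
replacing the directly drawn columns; non-converged tracks yield missing
scores. All randomness derives from one master seed split into named
streams (ages, visits, outcomes, listeners, clinical).

What the generator does *not* emulate: outcome-specific covariance
between cognitive subtests beyond shared group structure, demographic
confounding beyond age, visit-level practice-curve nonlinearity (learning
is linear in time), and any acoustic-level phenomenon — masking lives
entirely in the psychometric function. Passing tests therefore show that
the estimators and inference machinery are correct and calibrated under
the stated generative assumptions, not that those assumptions hold for
any particular real cohort.

## Numerical choices and problem sizes

Levels quantize to 0.1 dB (0.1 ms for gaps) for bit-stable oracle
comparisons. Staircase non-convergence (trial caps, boundary pinning) is
flagged, never silently estimated. Reference SDs use ddof = 1. Quantile
ties go to the extreme groups. The calibration checks in the test suite
and acceptance script use reduced designs chosen to keep the full run in
the minutes range on one CPU: 116-subject single-outcome cohorts with 200
null replicates and 150 coverage replicates, 500 staircase-recovery runs
per procedure, 100 ex-Gaussian datasets of n = 2000, and a half-scale
(192-subject) end-to-end pipeline; the same code runs unchanged at the
full design.

## Known limitations

Wald z inference is mildly anticonservative in small samples (no
Satterthwaite/Kenward–Roger correction is offered). The ex-Gaussian fit
pins τ rather than reporting an interval when skew is absent. The
adaptive-CAT mode runs the staircases in pure Python and is the slowest
path through the generator. Group labels are treated as fixed per subject
(as in the analysis being modelled), so subjects whose latent ability
crosses a quantile boundary mid-study are not relabelled.
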