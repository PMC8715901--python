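# Methods

`gamemarkers` is a simulation-and-analysis pipeline for game-based digital
behavioral markers of social anxiety. A player's avatar repeatedly delivers
documents in a virtual lobby: it approaches a stranger (an NPC standing 10 m
in front of two elevator doors), stops at a self-chosen conversation
distance, asks for directions, then walks past the NPC to one of the doors.
Socially anxious people keep larger interpersonal distances and walk wider
detours around strangers, in physical and virtual spaces alike; the package
turns those behaviors into per-trial markers and asks whether they predict
trait social anxiety measured by questionnaire.

## The assessment task and its telemetry

One trial is: approach → conversation → bypass → elevator choice → rating
screen. Twenty trials per participant, balanced over 2 elevator sides × 2
NPC emotional reactions (friendly, angry) × 5 repetitions, each with a
distinct team name. Avatar ground-plane positions are logged with integer
millisecond timestamps; after the conversation they sit on an exact 50 ms
grid. The room is modelled with the NPC at the origin, the spawn point 10 m
in front of it and the elevator doors at (±4, +10) m. Only the 10 m
NPC-to-elevator depth is fixed by the task description; spawn depth and
door offset are free `RoomConfig` parameters, and the defaults above are
stated assumptions.

A cohort serializes to three flat CSV tables (`participants.csv`,
`trials.csv`, `samples.csv`) plus `room.yaml`, with fixed 6-decimal float
formatting and stable row order, so every stage is independently testable
and byte-reproducible.

## The seven markers

Per trial:

- **IPD** (explicit): Euclidean avatar-to-NPC distance at the sample where
  the conversation is initiated.
- **Time in room**: trial start to trial end in seconds, conversation and
  rating included.
- From the post-conversation 50 ms samples only: **path length** (sum of
  consecutive-sample steps), **minimum** and **mean** NPC distance, and the
  **skewness** and **kurtosis** of the per-trial distribution of NPC
  distances.

Moment conventions are a genuine free choice (the construction, not the
estimator, is what is usually reported): we use biased divide-by-*n*
central moments and Pearson (non-excess) kurtosis `m4/m2²`, so "narrower,
more consistent distance profile" reads as *elevated* kurtosis. The
convention string travels with the extraction output. Skew needs ≥ 3
samples, kurtosis ≥ 4, both need nonzero distance variance; otherwise that
feature is missing (NaN) for the trial while the others survive.
Missingness is per-marker, never listwise; participant-level values are
arithmetic means over the trials where the marker is defined. Since the
avatar does not move during the conversation, "path from where the
conversation started" and "path over the post-conversation samples"
coincide; we compute strictly over the post-conversation window.

## The synthetic cohort

No participant-level dataset is publicly deposited, so the generator is a
first-class, tested component that produces cohorts with the statistical
structure the analysis assumes. One standardized latent trait `z` per
participant drives everything that should correlate:

**Questionnaires.** The 24-item social-anxiety scale (each item rated 0–3
for fear and 0–3 for avoidance; total 0–144) is simulated with a
graded-response model: P(rating ≥ k | z) = logistic(a·(z − b_k)). The
default parameters (a = 1.0666, thresholds 0.4431 + {−0.9, 0, 1.0},
identical across the 48 ratings) were moment-matched by Gauss–Hermite
integration so that totals over z ~ N(0,1) have mean 58.7 and SD 28.65 —
the descriptives of the crowdsourced sample the analysis is designed for.
The strong common factor this implies reproduces the instrument's typical
internal consistency (simulated Cronbach's α ≈ 0.97). Identification
subscale ratings (similarity / embodied / wishful, 0–4) are generated
around their published sample means and are descriptive flavor only.

**Behavior.** The trait shifts two preferred distances linearly:

- stop distance: `d_stop = 2.0 + 0.6·z + η_ipd + ε` (m), clamped to
  [0.5, 8];
- bypass clearance: `c = 1.5 + 0.5·z + η_clr + ε_c` (m), clamped to
  [0.3, 0.9·d_stop].

`η` are person-level heterogeneity terms (SD 1.66 and 1.38 m) sharing a
common "proxemic preference" factor (correlation 0.7): most
between-participant variance in proxemic behavior is unrelated to the
trait. These SDs are calibrated so that, at the default cohort size of 102,
regressing the questionnaire total on a participant's mean marker yields
R² ≈ 0.10 — the effect-size order the analysis stage is meant to detect.
Trial-level jitter (ε: SD 0.3 / 0.25 m) is comparatively small. The 0.9
cap keeps the detour geometry away from the degenerate regime where the
clearance approaches the stop distance and the bypass curve balloons.

**Movement model.** An invention standing in for human steering, not a
claim about how people walk: a straight approach at 3 m/s to the stop
point; a stationary lognormal conversation dwell (median 12 s); a
quadratic Bézier bypass from the stop point to the chosen door, sampled at
equal 50 ms arc-length steps and traversed with per-step Gaussian heading
noise (SD 0.05 rad) via pursuit of the reference waypoints; a lognormal
rating dwell (median 4 s). The Bézier control point sits level with the
NPC at a lateral offset solved by bisection so that the *sampled* minimum
NPC distance equals the participant's clearance. Solving against the
discrete grid (rather than the continuous curve) makes noise-free
simulations exactly linear in the trait, which the parameter-recovery
tests exploit: extracted IPD and minimum distance recover the configured
slopes to 1e-6. Speed, dwell medians and noise magnitudes are simulator
conventions; nothing in the analysis depends on their exact values.

NPC emotion and elevator side have *no* effect on simulated behavior, by
design: the analysis's design check should find nothing, and its null
calibration is tested. Age (discretized N(37.5, 9.9²), clipped to
[20, 65]) and gender (38% women / 61% men / 1% non-binary) are generated
independently of the trait; the non-binary rate exercises the analysis-side
exclusion path. Each participant's RNG stream is derived from
(cohort seed, participant index), so participant *i* is reproducible
regardless of cohort size.

**What the generator does not emulate.** Real steering dynamics and their
autocorrelation; trait effects on dwell times (time-in-room effects are
purely emergent from longer, wider paths); questionnaire response styles
(acquiescence, negligence); demographic correlations with the trait; any
emotion- or side-dependent behavior. Passing tests therefore show the
pipeline is correct and well-calibrated, not that the effect sizes would
transfer to human data.

## Questionnaire scoring

Totals are simple sums; published cutoffs of 30 (anxious) and 60 (high
risk of generalized social anxiety) are applied inclusively (total ≥
cutoff → higher band; the sources state thresholds but not boundary
inclusivity). The 11 social-interaction vs 13 public-performance items
follow the canonical instrument assignment. Cronbach's α uses unbiased
(n−1) variances and is undefined (NaN) for zero total-score variance. No
imputation: a missing or out-of-range rating is an error naming the item.

## Inference

**Design check.** For the 2 × 2 within-participant layout, each within
effect (emotion, side) reduces to one contrast score per participant and
marker. The contrast-score matrix is regressed on an intercept plus
mean-centered covariates (age, gender code), and the intercept is tested
with the four classical multivariate statistics computed from the
eigenvalues λ of E⁻¹H: Pillai Σλ/(1+λ), Wilks Π1/(1+λ), Hotelling Σλ,
Roy max λ, with the standard F approximations (Rao's F for Wilks; the
upper-bound F for Roy). Between-subject effects (intercept, age, gender)
are tested the same way on cell-averaged scores. For rank-1 hypotheses the
four statistics are deterministic functions of one another and all partial
η² definitions coincide with Pillai's trace; the property suite asserts
these identities to 1e-12 and cross-checks values, F and p against
statsmodels' MANOVA. A singular error SSCP (more markers than error df)
raises an explicit rank error rather than a numerical surprise.

**Hierarchical regressions.** One OLS per marker: block 1 is age plus
dummy-coded gender (−1 = man, +1 = woman; non-binary participants are
excluded from the inferential models only and retained in descriptives),
block 2 adds the participant-mean marker, outcome is the questionnaire
total. Reported per marker: unstandardized B, standardized
β = B·sd(marker)/sd(total) (covariates not standardized), the marker's
two-sided t-test p, R and R² of the full block-2 model, the block-2 model
F p-value (the "model p"; block-1 R²/p and the R² change are retained as
well), and n. No multiple-testing correction across the seven regressions
by default; a Holm-corrected column is available behind a flag.

## Numerical and design choices

- Timestamps are integers (ms); the 50 ms grid is exact by construction.
- The bypass bisection runs to a control-offset bracket of 1e-11 in
  noise-free runs (where exact trait-linearity matters) and 3e-5 otherwise.
- Detour side equals the target-elevator side: the shortest sensible route.
- Zero-duration trials, zero-variance distance sets, empty subscales,
  singular design matrices and n ≤ 4 regressions all raise or return
  missing values explicitly, never silently.
- Problem sizes in the test suite — 1,000 random trials for marker-oracle
  equivalence, 1,000 summary-level cohorts (n = 102) for the type-I-error
  calibration of each inferential stage, 24 full-pipeline replicate cohorts
  for effect-direction and effect-size checks — were chosen to keep each
  check's Monte-Carlo error well inside its assertion band.

## Known limitations

- Noise-free kurtosis is not strictly monotone in the trait at the extreme
  avoidant end (a dip of ~0.01 between z = −2 and −1.5 against a rise of
  ~0.15 across the grid); the suite asserts strict monotonicity for IPD,
  minimum distance and skew, and a positive fitted trend for kurtosis.
- The within-effect intercept test refers to covariate means (covariates
  are centered); packages that leave covariates uncentered test the effect
  at covariate zero instead.
- The simulated effect sizes are a calibration target, not an estimate of
  any population quantity.
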