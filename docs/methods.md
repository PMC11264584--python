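# Methods

This note documents the models and procedures implemented in
`socialoperant`, the assumptions behind the synthetic-data generator,
the numerical choices in the fitting and inference code, and the known
limitations of each.

## The social operant protocol

Sessions follow a three-phase fixed-ratio (FR) protocol. In every
session the subject sits in the chamber for a pre-period (600 s by
default) before the levers extend; completion of the FR requirement on
the active lever opens the social door for a fixed reward period, after
which an inter-trial interval (ITI) elapses before the next reward can
be earned.

| Phase | Schedule | Reward | ITI | Structure |
|---|---|---|---|---|
| 1a/1b | FR1 | 60 s | 20 s | 8 acquisition sessions (+1 after the time-of-day switch), 3600-s responding window |
| 2 | FR1→12 between sessions | 30 s | 5 s | 19 daily sessions: 3×FR1, 3×FR2, 4×FR4, 3×FR6, 3×FR9, 3×FR12 |
| 3 | FR1→12 within session | 30 s | 0 s | six 300-s bins (FR 1,2,4,6,9,12) separated by 15-s timeouts; 4 sessions with same-sex then 4 with opposite-sex stimuli |

Phase 3 implements the carry-over rule: a reward earned within 30 s of
a bin's end still receives its full 30-s open-door period, and the 15-s
timeout is delayed until the door closes. Rewards are attributed to
bins by onset time, so each reward belongs to exactly one bin.

## Exponential demand model

Consumption Q (social rewards) at price C (lever presses per reward) is

    log10 Q = log10 Q0 + k (exp(-alpha * Q0 * C) - 1)

- **Q0** (rewards/session, or rewards/bin for the within-session
  variant): demand at null cost, the model's extrapolated consumption
  at C = 0. `predict_consumption` satisfies Q(0) = Q0 to machine
  precision and is non-increasing in C (strictly decreasing for
  alpha > 0, saturating at Q0·10^(−k)).
- **alpha** (1/(reward·price)): demand elasticity; lower alpha means
  consumption survives price increases, i.e. higher motivation.
  Group analyses use log10 alpha; an exact-zero alpha has no log and
  such subjects are dropped from log-alpha analyses with a logged
  reason.
- **k** (dimensionless): the log10 range the curve can traverse. The
  default policy is a single shared cohort constant,
  k = log10(max mean consumption) − log10(min positive mean
  consumption) + 0.5, which keeps alpha comparable across subjects; a
  fixed user value or per-subject k are available via `k_policy`.

Consumption observations are built two ways, matching the two
economics procedures: between-session consumption at an FR level is the
mean over that level's sessions of active presses divided by the FR
("adjusted rewards", continuous-valued); within-session consumption at
price C is the mean reward count of the C-bin across the four sessions
of a stimulus-sex condition.

**Fitting.** Least squares on log10 Q with `scipy.optimize.least_squares`
over (log10 Q0, alpha), alpha bounded at zero, log10 Q0 bounded within
±3 of the observed maximum. Because the objective is multimodal in
alpha, the fit multi-starts from alpha = 0 and seven points spanning
alpha·Q0·Cmax from 0.01 to 10; tolerances are 1e-12. A fitted alpha
whose exponent alpha·Q0·Cmax is below 1e-8 is snapped to exactly zero
(perfect inelasticity). R² is computed on the log10 scale; flat
observations (zero variance) take R² = 1 when the residuals vanish.
Zero-consumption price points are dropped by default (log undefined);
a configurable floor substitution exists. Fewer than three positive
points yields an explicitly unfittable result. Subjects with R² < 0.6
(strict inequality, configurable threshold) are flagged excluded.

**Attainable precision of Q0.** Q0 is an extrapolation to C = 0 from
observations at C ≥ 1 with an unknown slope. With log10-scale Gaussian
noise of sd 0.1 at the six prices {1,2,4,6,9,12}, the Cramér–Rao bound
on se(log10 Q0) for the two-parameter fit is ≈ 0.073 even in the most
favourable (near-inelastic) regime and grows with elasticity, which
corresponds to a best-achievable median |Q̂0/Q0 − 1| of ≈ 13%. The
recovery tests measure ≈ 14% for Q0 (and ≈ 6–7% for alpha, whose
relative error is much better conditioned). Users should treat
per-subject Q0 estimates from six noisy price points as indicative,
and prefer group-level (population-curve) Q0 when precision matters.

**Correlations.** Pearson r over complete cases with df = n − 2 and a
two-sided p from the t transform (`scipy.stats.pearsonr`); two
independent correlations are compared with Fisher's
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) and a two-sided
normal p.

## Synthetic-data generator

The generator exists so that every analysis stage can be validated
against known truth; its defaults are the study conditions the analysis
assumes.

**Cohort structure.** A balanced Sex × Housing × ToD design (8
subjects/cell at full scale, N = 64), chambers assigned round-robin
within cells with sex kept consistent per chamber. Per-subject demand
parameters are log-normal around cell geometric means:
`param = mean · exp(N(0, σ))` with σ = 0.25, so the cell geometric mean
equals baseline × multiplier exactly in expectation. Baselines: Q0 = 20
rewards/session (inside the observed 18.5–24.5 range of mean rewards
per daily run at low price), alpha = 3e-3, k = 2 — an elastic but
non-collapsing demand curve spanning about one log10 unit over FR 1→12.
The default effect scenario encodes the headline finding the analysis
must be able to detect: isolated females get alpha × 0.5 and Q0 × 1.5;
Phase 3 opposite-sex stimuli multiply alpha by 0.6. Within-session Q0
is scaled to 0.35 of the session-level value to reflect the 5-min bin
ceiling (at most ten 30-s rewards fit in a bin).

**Press process.** Active presses are a renewal process with
exponential inter-press intervals (equivalently Poisson, thinned when
satiety is enabled). The rate is calibrated so expected consumption
follows the subject's demand curve: if Q(C) rewards each consume
reward + ITI seconds of a window W, the press rate is
λ = Q·C / (W − Q·(reward+ITI)), capped at the subject's physical
maximum (2 presses/s by default). This is the simplest generative
process matching the demand model in expectation; real rats do not
press by a memoryless clock, so the generator validates the estimators,
not the psychology. Inactive presses are homogeneous Poisson at a low
constant rate (0.005/s). Optional satiety multiplies the press rate by
2^(−t/half-life) within the session, producing the front-loading
pattern; it is off by default so demand-recovery tests see a
stationary process. The active lever is unavailable from reward onset
to ITI end, so the FR count between consecutive rewards is exact.

**Pose tracks.** 15 fps, 928 × 576 frame. The body centre performs a
clipped Gaussian random walk on the floor polygon and relocates to a
door-side anchor during "engaged" open-door periods; each open period
is engaged with a configurable probability (optionally decaying within
session, the consummatory-satiety knob). The nose rides ~18 px ahead
of the body and is placed strictly inside the door quadrilateral while
engaged — the engagement mask is the ground-truth nose-in-door
interval set. Cue-light likelihood exceeds 0.9 exactly while the door
is open and stays below 0.6 otherwise; lever likelihood exceeds 0.9
from lever extension (dropping during Phase 3 timeouts). Likelihood
dropouts (default 5% of frames) hit body parts only — they model the
chamber ceiling occluding the animal, which cannot occlude the static
cue/lever markers. Optional sub-second cue blips and a 10-frame lever
blip are injected below the 1-s annotation rule and recorded in the
ledger as non-events so inference precision/recall can be scored.
What the generator does **not** emulate: acquisition learning curves
across sessions, stimulus-rat behaviour, identity swaps or other
structured tracking failures, and camera distortion — passing tests
show the estimators are correct under the stated noise model, not that
they are robust to every real-world artefact.

## Kinematic inference rules

- Likelihood gate at 0.6: frames at or below threshold have x and y
  replaced by linear interpolation between valid neighbours; leading
  and trailing gaps take the nearest valid value (no extrapolation).
  Likelihoods are preserved and interpolated frames flagged, which
  makes cleaning idempotent. A part with no valid frames is marked
  unusable and downstream operations refuse it loudly.
- "1 s" spans are implemented as at least ⌈fps⌉ consecutive frames
  (15 at the default rate), non-strict at the boundary.
- Session start: first 1-s span with both lever likelihoods above 0.9.
  Absence raises an error — the video is unusable, matching how
  video-dependent outcomes attrit in practice.
- Door state: each ≥1-s span of cue likelihood above 0.9 marks a
  reward onset; the door is open for the phase's reward duration from
  that onset, and further onsets within that period are
  refractory-suppressed. Door-open duration comes from the phase
  configuration, not from the cue-light offset, because cue duration
  is not a reliable signal.
- Nose-in-door: point-in-polygon membership against the door
  quadrilateral (shapely), optionally dilated by a pixel margin
  (default 0). Geometry-based membership is scale-free and auditable;
  a distance threshold would need a calibration the data may not have.
- Locomotion: summed per-frame Euclidean displacement of the body
  centre, ignoring displacements below a 0.5 px jitter floor that
  would otherwise accumulate tracker noise into path length; optional
  cm conversion via floor-corner calibration.
- Alignment: the video clock is shifted so the detected session start
  equals the log's lever-extension time; after shifting, every
  inferred door onset must land within 1 s of a logged reward onset or
  an alignment error is raised. Per-FR-bin occupancy summaries are
  then computed inside each bin's interval.
- Occupancy proportions with a zero denominator (no open-door time in
  a zero-reward session) are reported as missing with a reason, never
  as zero.

## Cohort rules

- Top-responder selection: within each Sex × Housing × ToD × chamber
  cell, subjects ranked by mean acquisition rewards (descending, ties
  broken by ascending subject id for determinism); the top ⌈n/2⌉
  retained. On the full 64-subject design this retains exactly 32.
- Oestrous dichotomisation: proestrus/oestrus → P/O, metoestrus/
  dioestrus → M/D. Outcomes are averaged within category per subject;
  subjects lacking either category are excluded from paired tables
  with a logged reason. The generator assigns labels by stepping a
  4-phase cycle every other day from a random offset, which guarantees
  both categories occur across four sessions.
- Latency with no active press is censored at the operant duration and
  flagged, keeping non-responders in descriptive tables. Log
  transforms are base 10 throughout (any base is monotone-equivalent
  for the analyses used).

## Problem sizes used in the automated checks

The validation suites run at desk scale: parameter recovery uses 50
replicated 24-subject cohorts at six prices; effect-ordering uses 100
cohorts of 8 subjects per Sex × Housing cell; door-state/session-start
inference uses 100 simulated sessions with a 600-s responding window
and 60-s pre-period (the inference rules and thresholds are identical
at any session length); the zone-occupancy oracle uses 20 random
10,000-frame tracks. Full-scale cohorts (64 subjects, 3600-s sessions)
are available through the same configuration objects.

## Known limitations

- The press-generating process is a stand-in chosen for calibration
  transparency, not a behavioural model; inter-press-interval
  statistics of real rats (bouting, post-reinforcement pauses) are not
  reproduced.
- Per-subject Q0 from six noisy price points has limited precision
  (see the attainable-precision analysis above).
- Door inference cannot distinguish back-to-back rewards whose
  open-door periods abut within one frame (possible in the
  within-session phase at FR1 with near-zero press latency); the
  operant log is authoritative there, which is exactly why the
  alignment stage exists.
- ANOVA-style inferential statistics are deliberately out of scope;
  the pipeline emits tidy tables for standard statistics tooling.
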