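# Methods

This note documents the models and procedures implemented in `mstkit`,
the choices made where the design was genuinely open, and what the
synthetic cohorts can and cannot tell you about real data.

## Task structure and schedule generation

**Stimulus bank.** A pair is `(set_id, pair_id, lure_bin)`. Bin
polarity is fixed throughout the package: **bin 1 is the most similar
(hardest) lure** — the one with the highest normative false-alarm
rate — and bin 5 the least similar. The canonical pool is six sets of
192 pairs; the synthetic generator assigns bins i.i.d. (uniform by
default) because the real sets' per-bin composition is not published —
users with real metadata load it through the bank CSV. Matched-half
splitting shuffles within each bin and deals alternately to the two
halves, starting each bin on the currently smaller half; this is
provably balanced to ±1 per bin and ±1 in total, and recursive
application yields quarter-sets balanced pairwise to ±2.

**Study-test schedules.** The study phase presents exemplar `a` of
every later-tested repeat and lure pair (so `n_study = n_repeat +
n_lure`), in seeded random order; the test phase shuffles repeats
(exemplar `a`), lures (exemplar `b`) and never-studied foils. The test
phase order is an unconstrained shuffle: no spacing constraint between
test trials is imposed, as none is defined for the task.

**Continuous schedules.** Every slot in the block is either a first
presentation or a probe; with `n_first = n_repeat + n_lure` (the
standard designs) the block is completely dense, which makes
"place firsts, then insert probes" ordering infeasible in practice. The
builder instead constructs the block left-to-right: at each position it
either emits a probe already booked for that position, or starts a new
item and books its probe at a uniformly chosen free slot whose lag
falls inside the item's band (lags are differences of trial indices).
The whole layout restarts on a dead end, bounded at 10,000 attempts;
at the shipped densities the first attempt succeeds almost always
(tested over many seeds). Lag-band membership is exact, verified by the
independent checker.

The full continuous design assigns 32 repeats and 32 lures to each lag
band [4, 11] and [20, 99]. The reduced design's band split is not
specified anywhere, so each condition is divided as evenly as possible
across the same two bands (repeats 10/10, lures 22/22) — overridable
through `DesignSpec.repeat_lags` / `lure_lags`.

**Practice.** The study-test practice block is 4 study trials plus 6
test trials (3 guided, then 3 unguided) cycling repeat/lure/foil; the
continuous practice block is 9 trials (5 guided, 4 unguided) of firsts
with short-lag probes. Practice stimuli come from a reserved pool never
reused in the scored block (checked). Guided trials force the correct
response.

**Durations.** The per-trial floor is `min_trial_s` (default 2.5 s =
2.0 s stimulus + 0.5 s minimum ISI). Expected duration assumes a
response latency measured from stimulus onset, so a trial lasts
`max(min_trial_s, latency + min_isi_s)`; with the default 1.5 s latency
the expectation equals the minimum. Measured median component durations
of the deployed web task (instructions + phases per variant) are
shipped as data and sum to 12.24 min (baseline), 6.10 min (reduced
study-test) and 5.26 min (reduced continuous, 43% of baseline — a 57%
reduction); note the measured baseline study phase (~240 s for 128
trials) is faster than 128 × 2.5 s, so deployed effective minima differ
from the nominal ones, which is why duration estimates are
parameterized rather than hard-coded.

## Scoring

Rates are computed per condition over **emitted** responses by default;
omitted ("none") trials are tallied separately. The alternative
`count-as-new` policy is available because published analyses do not
state which convention they use — with the near-zero omission rates of
self-paced prompts the two agree closely. d′ uses the standard 1/(2N)
correction for rates of exactly 0 or 1. Validity thresholds are
inclusive: REC ≥ 0.5 (OSN), d′(TF) ≥ 1.5 (ON). OSN sessions
additionally report the d′ measures computed after collapsing
"similar" into "new", which makes OSN and ON sessions comparable; with
a shared "old" criterion and no lapses this collapse reproduces the ON
log exactly (a tested invariant). Sessions whose overall p("similar")
falls outside [0.05, 0.90] are flagged for review — never auto-dropped;
the interval operationalises "extreme over- or under-use" of the middle
response, for which no numeric rule exists.

Per-bin lure curves (p("old"|lure) and p("similar"|lure) by bin) are
computed but never enforced to be monotone: monotonicity is an
empirical property of participants, and the simulated cohorts do show
it (bin 1 attracts the most "old" false alarms).

## Generative participant model

Each trial evokes familiarity `x ~ N(μ, 1)` with

* μ = 0 for firsts/foils,
* μ = d_eff for repeats,
* μ = d_eff · s_b for a lure in bin b,

where `d_eff = d_rep · (1 + lag/8)^(−0.085)` decays as a power law in
lag (study-test probes use the study-list length as their effective
lag, continuous probes their actual lag). Responses: "old" if
`x > c_old`; "similar" if `c_sim < x ≤ c_old` (OSN only); otherwise
"new"; a lapse (default 2%) replaces the response uniformly.

Defaults (`young_adult_cohort()`): d_rep ~ N(5.1, 1.2²), c_old ~
N(3.25, 0.15²), c_sim ~ N(1.45, 0.40²), bin similarities
(0.41, 0.36, 0.31, 0.26, 0.21) scaled per participant by a log-normal
multiplier (σ = 0.45), clipped to keep the profile inside (0, 1) and
non-increasing. These values were calibrated jointly (closed-form
probabilities plus simulation) to a young-adult operating point:
baseline full-length LDI mean ≈ 0.28–0.30 with between-participant SD
≈ 0.15, REC validity pass rate ≈ 0.8, *higher* LDI under short-lag
continuous designs, and enough trait variance that the full-length
design can in principle attain test-retest reliability ≈ 0.8. The last
two constraints drove the key modelling choice: in a double-criterion
signal-detection model, p("similar"|lure) rises with memory strength
only while lure familiarity stays below the midpoint of the similar
window. Steep similarity profiles (e.g. 0.9 for bin 1) put lures past
that peak, where shorter lags *reduce* the LDI — the opposite of what
real cohorts show — so the default profile is deliberately shallow and
the criteria high.

**Cohort structure and stability.** Each participant has a latent
standard-normal vector (memory strength, both criteria, similarity
multiplier). The session-level realisation of *every* latent is
correlated across sessions at `retest_stability` (applying stability
only to memory strength would let perfectly stable criteria push
observed score reliability above the nominal stability, breaking the
attenuation bound). `practice_boost` (default +0.15 d-units) is added
from session 2 onward, emulating the small first-session disadvantage
seen in repeat testing. An `older_adult_cohort()` preset with lower
memory strength is provided for demonstrations; it is illustrative, not
normative.

**Semi-analytic reliability oracle.** `predicted_reliability` computes,
for sampled correlated session latents, each session's *true* expected
LDI in closed form given the schedule's lure-bin/lag composition, plus
the binomial variance of the LDI estimator, and returns
`cov(T₁, T₂) / √((var T₁ + E V₁)(var T₂ + E V₂))` — a Spearman–Brown
style attenuation. It is the oracle for parameter-recovery tests
(simulated cohorts reproduce it closely; e.g. predicted 0.545 vs.
observed 0.545 averaged over replications) and the target function that
`tune_retest_stability` bisects. It does **not** model the validity
filter; in full pipeline replays the filter's range restriction lowers
observed correlations by roughly 0.03.

## Psychometric analysis

**Outlier-robust correlation.** The robust fit follows the published
outline of the ROUT procedure: an iteratively-reweighted line with
Lorentzian weights `1/(1 + (res/RSDR)²)`, a robust residual scale
(RSDR = 68.27th percentile of |residuals| × n/(n−2)), two-tailed t
probabilities per point, and a Benjamini–Hochberg step-up at rate Q
(default 1%) flagging the largest residuals; the reported correlation
is the ordinary Pearson r over retained points. The commercial
implementation is not fully published, so agreement is behavioural, not
bit-exact: on clean bivariate-normal data the mean flag count stays
well below one per fit and r moves by < 0.02 on average, while a gross
planted outlier is flagged exactly (both tested).

**Fisher comparisons** use `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) +
1/(n₂−3))`. The one-tailed default tests the directional question
"is the variant's correlation *below* the reference?", so the variant
correlation is passed first; post-outlier n, not enrolled n, enters the
test. **Sample size** for detecting a correlation uses the Fisher-z
normal approximation `n = ⌈((z₁₋α/₂ + z_power)/atanh r)² + 3⌉ (r =
0.48 at α = 0.05, power 0.8 gives n = 32), verified against a
simulation oracle. **Cohen's d** offers pooled-SD (independent groups)
and change-score (paired) variants. The **extra-sum-of-squares F-test**
compares one common regression line against separate per-group lines
with df (2, n₁+n₂−4) and is type-I calibrated under the null (tested).
**Score conversion** applies `oMST = 0.33 + 0.65 · baseline` (the
pooled two-cohort fit) or its algebraic inverse; the coefficients live
in configuration, not in code.

## What the synthetic cohorts do and do not show

The simulator reproduces the *structure* of the empirical phenomena:
bias-corrected difference scores near the published young-adult range,
realistic engagement-failure rates, monotone lure-bin curves, higher
scores at shorter lags, attenuated test-retest correlations that grow
with lure-trial counts, and a small first-session practice effect. It
is still an equal-variance, unidimensional familiarity model with
independent trials: it has no response times, no fatigue or strategy
shifts, no unequal-variance extension, no genuine pattern-separation
process, and its parameters are calibrated, not fitted to human logs
(no fitting machinery is shipped). Passing tests therefore validate
the *pipeline* — generators, scoring, filters, statistics — on data
whose ground truth is known; they are not evidence about any human
population. Reported human-scale quantities (trial counts, durations,
conversion coefficients, thresholds) come from the task definitions and
shipped constants, not from simulation.

## Monte-Carlo problem sizes and numerical choices

Stochastic suites use fixed seeds and these scaled sizes: outlier
calibration 300 fits of n = 50; simulator/closed-form agreement 30–40
sessions per check; attenuation 60 cohorts of n = 50; lure-count
monotonicity one cohort of n = 1000 per trial count (11/44/64);
parameter recovery 15 cohorts of n = 200 against a 20,000-draw
semi-analytic prediction; the end-to-end replay 200 replications of a
47-participant two-session pipeline with stability tuned so the oracle
predicts r = 0.73. Schedules are generated once per suite and shared
across simulated participants (the simulator depends only on bins and
lags, so sharing removes only schedule-level jitter). Degenerate
inputs fail loudly: zero-variance predictors, empty conditions,
extreme rates without trial counts, infeasible lag constraints (the
failing constraint is named), and malformed files (the offending line
is named).
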