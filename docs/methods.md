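# Methods

## Task engines

Three self-paced operant tasks are simulated at trial resolution. Timing
elements of the physical tasks (intertrial intervals, time-outs, cue
lights) are not modelled: every trial receives exactly one response, and a
session is a fixed-length sequence of (choice, outcome) records. All
within-session randomness comes from one `numpy` PCG64 generator seeded per
session, so a (seed, policy) pair reproduces a session bit-for-bit.

**Serial reversal learning.** Two response options; the active one always
pays one pellet. A run of `criterion_run` consecutive correct responses
(default 5; the photometry task variant uses 8) completes a reversal: the
flag is set on the completing trial, the active side swaps, and the run
counter resets. An incorrect response resets the counter to zero — the task
description only constrains *consecutive* correct responses, and a full
reset is the natural reading. Sessions are 150 trials; the initially active
side is drawn from the session generator, mirroring counterbalancing across
animals.

**Probabilistic discounting.** Four blocks of 6 forced risky trials
followed by 10 free-choice trials (64 trials, 24 forced). The safe lever
always pays 1 pellet; the risky lever pays 3 with block probability 1, 1/3,
1/6, 1/12 in the decreasing variant. The probabilities are kept as exact
fractions rather than the rounded percentages (33%, 16.67%, 8.33%) because
the odds are defined as "1 in n" events; block 2 is therefore exactly
value-neutral (3 × 1/3 = 1). The increasing variant presents the same odds
in reversed order — the literature does not pin the order down further, so
the exact mirror is used.

**Punished responding.** A step schedule of foot-shock probabilities over
blocks of 10 trials (0, 1/3, 2/3, then 1 from trial 31 on). The physical
session ends after five minutes without an active response; since no trial
count maps onto that rule, sessions are a fixed 40 trials by default and
the policy may return `None` to stop responding early.

## Learning model

The dual-learning-rate Rescorla–Wagner model attaches values to spatial
responses (left/right), not to task roles — the metrics translate sides to
roles. Both values start at 0. Only the chosen option is updated (no decay
or forgetting of the unchosen option). Outcomes are coded binary
(reward present/absent); pellet magnitude never enters the update, since
the model is defined for the reversal task where every reward is one
pellet. With outcomes in {0, 1} and learning rates in [0, 1], values are
confined to [0, 1] for any trajectory; the softmax is still computed with
the max-subtraction trick because β itself is unbounded in principle.

A structural consequence worth knowing: an unrewarded response at value 0
produces a zero prediction error, so before the first reversal the loss
learning rate cannot influence behavior at all. This is what confines
treatment effects on α_lose to post-reversal measures, and it also makes
the point (α_win, α_lose, β) with α = 0 *or* β = 0 an exactly flat ridge of
the likelihood (all choice probabilities 0.5 regardless of the other
parameters).

## Fitting

The per-session negative log likelihood replays the observed
choice/outcome sequence through the recursion (values updated with observed
outcomes, each trial contributing −log p of the observed choice). Fits use
L-BFGS-B with box bounds α ∈ [0, 1], β ∈ [0, 20] and `ftol` 1e-10. The β
cap is a fitting decision, not a model constraint: with values in [0, 1], a
value gap of 0.5 at β = 20 already gives p ≈ 0.99995, so larger β is
unidentifiable and only invites boundary runaway on near-deterministic
sessions.

Starting points are chosen by screening: a seeded pool of 3 × `n_starts`
(at least 30) uniform candidates is ranked by NLL and the best `n_starts`
(default 10) seed the local runs; the lowest NLL wins, ties broken by order
found. Screening exists because of the flat chance ridge described above —
the first projected-gradient step from a poor random start can land exactly
on the α = β = 0 corner, where the gradient is identically zero and the
optimizer terminates at the chance likelihood even when far better optima
exist. Starts that already beat most candidates do not exhibit this.

Model-versus-chance comparison is a likelihood-ratio test:
statistic 2·(chance NLL − fitted NLL), chance NLL = T·ln 2, referred to a
chi-square distribution. The degrees of freedom default to 3, the full
parameter-count difference; because both learning rates are unidentifiable
at β = 0, the effective df is arguably smaller and df = 3 is therefore
conservative (the measured null rejection rate at the liberal p < 0.1
threshold runs well below 0.1). The df is an argument, not a constant.
Sessions that fail the comparison are flagged but retained in cohort
tables, avoiding a selection bias against noisy subjects.

## Behavioral metrics

Win-stay is the percentage of rewarded active-option trials followed by the
same response; lose-stay the percentage of unrewarded inactive-option
trials followed by the same response. Three boundary conventions are made
explicit because the field's verbal definitions do not pin them down:

* the final trial of a session has no successor and never enters a
  denominator;
* the pre/post split assigns the trial completing the first reversal to
  "pre", and each transition is scored in the phase of its earlier trial;
* a metric with an empty denominator (e.g. no pre-reversal losses, common
  in good performers) is reported as NaN, never 0 — downstream tables
  preserve the missing value.

Note that the rewarded trial completing a reversal still counts in the
win-stay denominator even though the optimal next response is a switch;
win-stay for a perfect subject is therefore 80% at criterion 5, not 100%.

Perseveration counts the consecutive responses on the formerly active
option immediately after each reversal (inactive–inactive–active scores
2); a reversal followed immediately by the new active option contributes 0
to the mean. Discounting percentages and stay metrics use free-choice
trials only; stay metrics are scored over pairs of *consecutive* free
trials, so the last free trial of a block (whose successor is forced) is
excluded. Percent optimal scores risky choices where the risky expected
value exceeds the safe pellet and safe choices where it falls short,
leaving the value-neutral block unscored — for the default schedule this is
exactly "risky in block 1, safe in blocks 3 and 4". The discounting rate is
((p₃ + p₄)/2 − p₁)/3 in % per block.

## Photometry

dF/F normalisation: for each sample, the baseline F₀ is the interquartile
mean (middle 50% of values by rank, a quarter trimmed from each end) of the
30 s of samples *following* that sample, and dF/F = (F − F₀)/F₀. Tie
handling at the quartile cut is by rank, and the trim count is ⌊n/4⌋ per
side. In the final 30 s the window truncates to the available samples; for
the last sample (empty window) F₀ falls back to the sample itself, giving
dF/F = 0 rather than an undefined value. The output is exactly invariant to
positive rescaling of the input and exactly zero for constant input.

The forward-looking window has a known bias on a bleaching trace: the
baseline aggregates only *future* (decayed) values, sitting roughly
mid-window below the current sample, so dF/F carries a positive offset of
about exp(w/2τ) − 1 for window w and bleach time constant τ. At the default
synthetic τ = 3000 s (about 2% signal loss per minute, the slow-bleaching
regime of a well-powered GCaMP preparation) the offset is ~0.5% and small
transients remain readable against it; analyses of much faster-bleaching
data should read AUC contrasts (win vs loss, pre vs post) rather than
absolute levels, which is how the measures are used here.

PSTHs snap each event to the nearest sample at or before its timestamp and
drop (but count) events whose window would cross a trace edge. AUC is the
trapezoidal integral of dF/F over 0–5 s post-event, computed per event and
then averaged; per-event and mean-trace AUC coincide for the mean but the
per-event values carry the dispersion used by across-event statistics.

The synthetic trace generator produces
F(t) = baseline·exp(−t/τ)·(1 + Σ transients) + Gaussian noise, with
event-locked double-exponential transients (rise 0.2 s, decay 1.5–2 s,
positive for wins, dips for losses and shocks, roughly calcium-indicator
kinetics). It emulates bleaching, event-locked responses and sensor noise;
it does not emulate movement artefacts, hemodynamic contamination,
isosbestic-channel correction or rig-specific filtering, so photometry
tests validate the *analysis*, not robustness to those artefacts.

## Synthetic cohorts and the treatment contrast

`generate_cohort` draws per-subject parameters uniformly from configurable
ranges (defaults α ∈ [0.1, 0.9], β ∈ [1, 5] — spanning slow-to-fast
learners and weakly-to-strongly value-driven choosers) and derives every
(subject, condition, session) seed from the master seed via
`SeedSequence.spawn`. The treatment condition multiplies α_lose by a factor
(default 0.3), leaving the other parameters untouched; an additive variant
is available behind a flag.

`replicate_simulation_result` is the in-silico treatment experiment: n = 25
subjects, each run under control and treated parameters. The two conditions
of a subject share one session seed (common random numbers) — the analogue
of a within-subject crossover design, and because the generator consumes
exactly one draw per trial the control and treated streams stay aligned.
Combined with the zero-RPE property above, this makes the pre-reversal
measures (trials to criterion, pre-reversal win-stay) pairwise *identical*
by construction, so their null contrasts are exact rather than merely
insignificant, while post-reversal measures carry the treatment effect.
Contrasts are summarised by paired Wilcoxon signed-rank p-values and paired
Cohen's d. Control parameters default to (α_win 0.6, α_lose 0.6, β 3.0) —
a plausible trained-rat regime, configurable, and not estimated from any
particular dataset.

Parameter recovery (`run_recovery`) fits each subject's sessions jointly
(values restart at 0 at session boundaries) and reports per-parameter bias,
RMSE and Spearman rank correlation against the generating values. At 10 ×
150 trials per subject, both learning rates recover with rank correlation
above 0.9 and median absolute error under 0.05; a single 150-trial session
recovers α_lose and β usefully but α_win only loosely, because pre-reversal
wins saturate the chosen value within a few trials.

## Problem sizes and tolerances

Exact claims (chance likelihood, worked perseveration example, dF/F
algebraic identities) are tested to 1e-10 or machine precision against
independent oracles. Simulation-based claims use: 500 replicates for the
null calibration of the chance comparison (three-sigma binomial slack on
the nominal 0.1 rate); 25 subjects × 10 sessions for recovery; 20 replicate
cohorts of n = 25 for the directional treatment contrast (requiring the
four-way pattern in at least 16 of 20); and 8-event synthetic traces at
150 s, 100 Hz for the photometry AUC signs. These sizes give stable
outcomes across seeds while keeping the full suite fast enough to run
routinely.

## Known limitations

* Omissions, response latencies and within-session satiety are not
  modelled; every trial receives a response.
* The model is fitted only to reversal-learning sessions (as in the source
  analyses); fitting discounting or punishment sessions is out of scope.
* The LRT's chi-square reference is asymptotic and its df choice
  conservative; calibration beyond the simulated null is not attempted.
* The photometry pipeline assumes a single uniformly sampled channel;
  multi-channel (isosbestic) regression correction is not implemented.
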