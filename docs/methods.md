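# Methods note

This note records the statistical model behind `gazehab`, the parameter
conventions baked into its defaults, what the synthetic-session generator
does and does not cover, and the numerical choices that matter for
reproducing its outputs.

## Habituation criterion

Looking time is accumulated per stimulus token (default 1 s tokens). The
criterion operates on **non-overlapping** windows of `window_tokens = 3`
tokens and is checked each time a window completes, starting at token
`first_check_token = 6` and ending at `max_tokens = 33`:

- the just-completed window's total looking is compared against the peak
  total over all **preceding** completed windows (the window under test is
  excluded from its own reference peak — otherwise a session whose first
  window is also its largest could never habituate against it);
- habituation is declared when `current ≤ criterion_ratio · peak`, with
  `criterion_ratio = 0.60`; the comparison uses a 1e-12 absolute slack so
  exact-ratio boundary cases are decided as "habituated" regardless of
  floating-point representation;
- a session reaching token 33 without meeting the criterion terminates
  non-habituated.

The online engine (`HabituationState` / `update`) and the offline replay
(`recompute_habituation`) are the same decision rule by construction: the
replay feeds a completed per-token sequence through the identical state
machine. Sessions are included in analysis only if the habituation trial
falls in `[min_habituation_trial, max_tokens] = [9, 33]`; a session
habituating at the first check (trial 6) is excluded as outside the
window, not treated as an error.

A `sliding_peak` variant (peak over every contiguous 3-token window
rather than the non-overlapping grid) is implemented but off by default.

## Looking-time coding

Both channels reduce to a boolean LOOK series on a uniform time grid:

- **Eye tracker**: one sample per `1/rate_hz` s (default 120 Hz); a sample
  is LOOK iff it is valid *and* inside the area of interest (default: the
  full normalized screen). Track loss is NO-LOOK; no fixation filtering or
  interpolation is applied. Valid-flagged samples with missing coordinates
  are coerced to invalid at read time (logged).
- **Frames**: 40 ms frames labelled LOOK/NO-LOOK; time not covered by an
  annotation is NO-LOOK. Annotation boundaries must lie on the frame grid;
  off-grid or overlapping intervals are data errors, never silently
  snapped.

Windowed looking time is the exact measure-theoretic overlap between the
query window and the LOOK units (partial units count fractionally), which
makes it additive over adjacent windows and monotone in window size. The
two channels can disagree by up to one frame per look run purely from
quantization; they agree exactly only when the sample period divides the
frame duration and look runs are frame-aligned.

## Test phase and novelty preference

Each test phase (same, switch) is 8 tokens of 1 s. The novelty preference
score is `(LT_switch − LT_same) / (LT_switch + LT_same)`, undefined (NaN)
when both looking times are zero. A participant is classified a
discriminator iff the score is strictly positive; a zero score is not
discrimination, and an undefined score yields no classification.

## Exclusion pipeline

Three rules, applied in fixed precedence so each excluded participant
carries exactly one reason:

1. `incomplete_task` — the session ended before both test phases ran;
2. `habituation_window` — no habituation within trials 9–33;
3. `low_test_looking` — less than 1 s total looking to either test phase.

The ledger records all three flags per participant plus the first failing
rule; summary counts are reported per reason and per group.

## Effect sizes and power

From a reported interaction F statistic:

- `eta_p^2 = F · df_effect / (F · df_effect + df_error)`
- `f = sqrt(eta_p^2 / (1 − eta_p^2))`

Power for the 2 (between) × m (within) interaction uses the noncentral F
distribution with `df1 = (g−1)(m−1)`, `df2 = (N−g)(m−1)` and
noncentrality `λ = f² · N · m / (1 − ρ)`, where N is the **total** sample
size and ρ the repeated-measures correlation. ρ defaults to 0 (the
neutral choice when it is not reported); it is a free parameter. At λ = 0
the central F is used directly, as scipy's noncentral implementation is
inexact there.

The Monte-Carlo estimate draws replicates from the Gaussian cell-means
model with compound-symmetric repeated measures. For m = 2 the
interaction test reduces algebraically to a pooled two-sample t-test on
within-subject difference scores (F = t² with df (1, N−2)), which is what
each replicate evaluates; the subject random effect cancels in the
difference, so only the within-subject residual (variance 1 − ρ) is
drawn. Odd totals place the extra participant in group 1; for N = 37 this
shifts λ by < 0.1 % relative to the balanced formula. The estimate
reports the rejection proportion, its binomial standard error
`sqrt(p(1−p)/n_sims)`, and the closed-form value for cross-checking.
Recruitment targets are `ceil(n_required / (1 − attrition_rate))`.

## Language metrics

Exposure percentages normalize reported weekly hours per language. Degree
of bilingualism is `min(pct) / max(pct)` over the two main languages
(1.0 at a 50/50 split; undefined for monolinguals). The mixing score sums
six 0–6 frequency ratings (range 0–36; fractional ratings allowed).
Eligibility requires both main languages in [20 %, 80 %] inclusive, any
additional language at most 5 % (strictly more excludes), and no exposure
to a language on the caller-supplied retroflex-consonant list; an empty
list skips that check with a warning.

## Synthetic generator: scope

The generator exists to validate the pipeline, not to model infants
faithfully. It covers: geometric attention decay with Gaussian per-token
noise; additive novelty effects on switch trials; per-sample track loss;
integer-frame coder jitter; and four designed failure modes (early
termination, near-flat decay, low test looking, mid-session tracker
starvation with intact frame coding). The online habituation decision is
made on the *measured* gaze signal — the same sample grid and track-loss
draws later emitted in the stream — so offline replay of the written
session reproduces the live decision exactly, including at criterion
boundary cases.

It does **not** model: saccade dynamics or fixation structure, spatial
gaze error, attention-getter contingency, anticipatory looks, drift in
coder bias, or correlations between a participant's habituation speed and
test-phase looking. Default parameters are fixed study conditions, not
fitted quantities.

## Numerical choices

- Habituation comparison slack 1e-12 (absolute), decides exact-ratio
  boundaries as habituated.
- Sample-to-window assignment uses half-open intervals `[onset, offset)`
  with a 1e-9 ms guard against floating-point boundary samples.
- Cohort generation and power simulation are driven by
  `numpy.random.default_rng` seeded explicitly; fixed seeds give
  bit-identical cohorts and output files (checksummed in the run
  manifest).
- Correlation of paired channels is undefined (NaN, flagged as such) when
  either channel is constant to within a 1e-12 relative tolerance.

## Limitations

Quantities computed here describe the implemented model and its synthetic
data only. The test suite verifies internal consistency (oracle replays,
closed-form cross-checks, parameter recovery on generated cohorts); it
makes no empirical claims about infant behaviour, and group-level
findings from real studies cannot be reproduced from this package because
no raw participant data is distributed with it.
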