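# Methods

## The paradigm

The 1-back Stroop (BS) task crosses two binary judgments in every trial: a
spatial 1-back judgment (does the stimulus occupy the same cell of a 3×3
grid as on the previous trial?) and a color–word Stroop judgment (does the
word's meaning match its ink color, over a four-color palette?). The cross
yields four conditions — both consistent (1), both inconsistent (2), 1-back
consistent only (3), Stroop congruent only (4) — answered with two keys:
conditions 1–2 share one key and 3–4 the other, so the required key is the
XNOR of the two judgments. Key assignment is counterbalanced (variant A:
F/J; variant B: J/F). Combining working memory, inhibitory control, and
cognitive flexibility under a per-condition response deadline makes the task
a high-mental-workload paradigm; running it continuously for 30 minutes
adds a time-on-task manipulation that induces mental fatigue.

This package implements the paradigm as a headless engine: the stimulus
combinatorics and constrained sequencing, the deadline calibration, a
virtual-clock session executor for the three protocols (workload comparison
against a 2-back task, 30-minute fatigue induction, psychomotor vigilance),
stochastic simulated participants, and the repeated-measures analysis
pipeline. Rendering (grid, Chinese character glyphs, progress bar) is a
front-end concern; the engine stores color identities and exposes the
character mapping as a constant table.

## Time-pressure calibration

Time pressure is controlled through the ratio of required time (RT, the mean
reaction time measured with no response deadline) to available time (AT, the
deadline). A ratio of RT/AT = 0.8 produces a felt sense of time pressure, so
AT = 1.25 × mean RT per condition, rounded to the nearest 100 ms (half-up).
The nearest-100 rule is the unique simple quantization consistent with all
four published (mean RT, AT) pairs — 2269.5→2300, 2992.7→3000, 2638.1→2600,
2814.3→2800 — where ceiling or floor rules each fail at least one pair. Both
the factor and the quantum are configurable.

Calibration input is preprocessed in one three-stage sweep, with sample SDs
(n−1) at both levels and no iteration to convergence (each rule is applied
once, using pre-removal statistics):

1. incorrect trials removed per participant;
2. trials outside mean ± 3 SD within each (participant, condition) cell
   removed; singleton cells are retained with a warning (SD undefined);
3. participants with any condition mean outside the group mean ± 3 SD for
   that condition excluded entirely (exclusion is participant-wise because
   quality problems of this kind are participant-level).

The trial-level mean/SD are computed within participant and condition; a
pooled-per-condition reading of the rule is possible but sits poorly with
removal being described per participant.

## Sequencing

Scored condition sequences are exact multisets (e.g. 30 per condition for
the full 121-trial task, 2 per condition for 8-trial blocks) with no run of
identical conditions longer than `max_run_length` (default 4). "Pseudo-
random" is not further specified by the protocol, so the bounded-run
constraint is this package's reading of balanced pseudo-randomness; it is
configurable and can be disabled by setting the bound to the sequence
length. Generation is rejection sampling — permute, check runs, retry —
with a 10,000-attempt cap whose exhaustion (or an arithmetic infeasibility
pre-check) raises an explicit error. Every generator is a pure function of
its seed.

Each sequence (and each block in the fatigue protocol) is preceded by one
unscored lead-in trial with an unconstrained random stimulus, because a
1-back judgment is undefined without a predecessor. Back-inconsistent
trials draw uniformly from the 8 other cells; incongruent trials draw the
word uniformly from the 3 non-ink colors.

## The virtual clock

Sessions run on a simulated clock, so a 30-minute protocol executes in
milliseconds. Per scored BS trial the clock advances by min(RT, AT) plus
500 ms of ISI feedback ("√" correct / "×" incorrect / "–" no response
before the deadline; responses after the deadline are recorded as no
response). The lead-in trial consumes a fixed exposure (default 1000 ms;
the protocol does not state one, since no key press is required). The
fatigue protocol fills each 5-minute block with shuffled four-condition
mini-batches, checking the clock only at batch boundaries so realized
condition counts stay exactly 1:1:1:1 within a block; block trial counts
therefore vary with responder speed (~150 scored trials per block under the
default preset). VAS administration is instantaneous on the task clock.

PVT bouts draw uniform foreperiods in [2, 10] s; each trial consumes
foreperiod + RT + 1 s of feedback display, and the bout ends when the next
stimulus would fall outside the 3-minute duration. RT ≥ 100 ms is a valid
response, RT ≥ 500 ms an attention lapse. The 2-back comparison task runs
at fixed pacing (0.5 s letter + 2 s blank, responses accepted in the 2.5 s
window, no feedback).

## Simulated participants

The simulated responder is artifact plumbing — a generative stand-in that
makes protocols testable, not a cognitive-process model:

- **BS RTs**: per-condition lognormal kernels, moment-matched to target
  mean/SD. Lognormal is the standard positive, right-skewed RT family.
- **Fatigue drift**: RT scale multiplied by (1 + d_rt·b) and accuracy
  reduced by d_acc·b for 0-based block b — linear in block, the simplest
  drift that produces the qualitative block-wise decline.
- **PVT**: a mixture — with lapse probability p (inflated by a multiplier
  after the task), 500 ms plus an exponential excess; otherwise the base
  kernel truncated at the 100 ms validity floor, with a post-task RT
  multiplier.
- **VAS**: mean trajectory baseline + asymptote·(1 − e^(−rate·b)) plus
  Gaussian noise, rounded and clamped to [0, 100] integers. The saturating
  form encodes the diminishing block-over-block increments characteristic
  of subjective fatigue ratings.

The `tot_preset` defaults put simulated cohorts on the scale of published
group descriptives: deadline-pressured RT means of 1300–1700 ms (yielding
~140–150 scored trials per 5-minute block), accuracy ~95% declining ~3
points over six blocks (d_rt = 0.02, d_acc = 0.006 per block), PVT mean
~276 ms with lapse probability 0.006 pre (×3.5 and ×1.05 on RT post), and
VAS curves rising from single digits toward 20–60 with diminishing
increments. Between-participant heterogeneity (RT ±8%, accuracy ±0.02, VAS
asymptote ±25%, PVT ±7%, random key variant) is a free choice — the
published tables carry no individual-level variance decomposition. These
presets emulate the published behavioral ranges for testing; they are not a
reproduction of any human dataset, and passing tests show that the
machinery detects planted effects of realistic size, not that it reproduces
human cohort statistics.

## Statistics

- **Paired comparisons** route on a normality test of the pairwise
  differences (Shapiro–Wilk by default; Lilliefors-corrected KS exposed for
  the protocols described with "Kolmogorov–Smirnov", since distribution
  parameters are estimated): normal → matched t-test with Cohen's d for
  paired data (mean difference / SD of differences); non-normal → Wilcoxon
  signed-rank with the matched-pairs rank-biserial correlation
  r = (W⁺ − W⁻)/(W⁺ + W⁻), zeros dropped, midranks for ties.
- **RM-ANOVA** uses the classical one-way within-subject sums-of-squares
  decomposition; partial η² = SS_cond/(SS_cond + SS_err). Mauchly's W comes
  from the eigenvalues of the orthonormally contrasted covariance, with the
  ezANOVA-style second-order corrected chi-square p-value; when sphericity
  is rejected (α = 0.05, or forced) both dfs are multiplied by the
  Greenhouse–Geisser ε̂, bounded in [1/(k−1), 1]. With k = 2, ε = 1 and the
  test reduces exactly to the paired t (F = t²). The implementation is
  cross-checked in tests against pingouin and against a from-scratch SS
  oracle.
- **Friedman** tests use scipy's tie-corrected chi-square on
  within-participant midranks; Kendall's W = χ²/(n(k−1)), an identity the
  tests verify against the rank-sum formula to machine precision.
  Bonferroni-corrected pairwise signed-rank post hocs are available. The
  timepoint set (with or without baseline) is the caller's explicit choice,
  since different indicators legitimately include different timepoints.
- **Spearman** matrices use tie-corrected ranks; constant columns are
  reported by name with NaN entries rather than a silent zero.
- p-values format as three decimals with a "<0.001" floor.

## Numerical and degenerate-input choices

Half-up rounding for AT quantization (floor(x/q + 0.5)·q, no banker's
rounding); rejection-sampling cap 10,000; singleton RT cells retained with a
warning; all-zero difference vectors and all-constant matrices return
flagged degenerate results with zero effect size rather than raising;
rank-deficient covariance raises. Cohen's d = 4.321 printed for the
reaction-time comparison in the source tables cannot be reproduced without
raw data; the formula choice (difference-score d) is documented, not
calibrated to that value.

## Problem sizes in the test suite

Sequence-structure checks run over 100 seeds; Monte-Carlo checks of the
responder use 10³–10⁴ draws; the power/type-I characterization simulates
100 drifted and 200 drift-free cohorts of 72 participants through the full
30-minute protocol (≈19 million simulated trials, a few minutes on one
core). The drifted preset is detected by Friedman on block accuracy at
p < 0.001 in ≥95% of cohorts; the drift-free preset rejects at the nominal
5% level (within ±2 points) on the integer correct-count indicator. On the
block-accuracy indicator the Friedman test is *conservative* under the
null (~2% empirical level): accuracy is a small-denominator ratio, so a
majority of simulated participants carry at least one exact tie across
their six blocks, and rank tests on discrete data reject less often than
nominal — never more often. On continuous matrices of the same shape the
implementation's level is 0.0465. These sizes are the package's chosen
desk-scale study conditions.

## Known limitations

- The engine models no anticipation/false-start behavior in the PVT (RTs
  below 100 ms only arise from a responder that produces them).
- The simulated participant has no trial-level sequential dependencies
  (post-error slowing, condition switch costs) and no motivation dynamics.
- The practice-gate loop regenerates balanced 16-trial blocks but does not
  model learning across attempts; a responder's accuracy is stationary
  unless its parameters say otherwise.
- Inferential statistics of the original human cohorts are not reproducible
  from printed summaries; only deterministic functions of printed values
  (deadlines, scale totals, declines, effect-size identities) are exactly
  recoverable, and the rest of the validation is property-based.
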