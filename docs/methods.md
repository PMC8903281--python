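# Methods

## Stimulus model

A musical excerpt is represented only by its beat annotation: a strictly
increasing list of beat onsets (seconds, relative to excerpt start) and a
duration. The normalizer used everywhere is the **mean inter-beat interval
(IBI)**, the mean of consecutive onset differences; irregular (annotated)
grids are accepted anywhere a grid is, but the bundled defaults are
isochronous stand-ins with tempos spread over 80–140 bpm and durations drawn
from the 10–16 s range typical of BAT excerpts.

Click tracks come in three alignment conditions:

* **on-beat** — beeps are the subset of beats at/after the beep start
  (default 5 s into the excerpt), bit-identical to the annotation;
* **phase shift** — every beep is displaced by `direction × magnitude ×
  mean IBI` (magnitudes 0.10 and 0.175 in the standard battery). The shift
  is constant along the train;
* **period shift** — the first beep is anchored on the first beat at/after
  the beep start and successive beeps are spaced `mean IBI × (1 ± magnitude)`
  (magnitude 0.02), so beep-to-beat misalignment grows linearly. Anchoring
  at the first post-start beat makes the perturbation a pure period error
  (phase-aligned at onset, drifting thereafter); the beep train is truncated
  at the excerpt duration.

Both shift directions (early/late, fast/slow) are supported and both appear
in the default 17-trial plan. The original battery's exact per-condition
counts are not public, so the shipped plan — 8 on-beat, 5 phase-shifted
covering both magnitudes and directions, 4 period-shifted covering both
directions — is a documented, configurable default rather than a canonical
reconstruction. Trial order is randomized by a seeded generator; practice
trials (default 3, one per condition kind) precede the test block in fixed
order.

## Observer and tapper models

The study populations are emulated by two parametric models chosen as the
minimal generative processes whose parameters map one-to-one onto the
outcome measures.

**Perceiver.** The probability of answering "off the beat" is a
lapse-contaminated logistic in normalized misalignment *d*:

    P("off") = λ/2 + (1 − λ) · logistic(s·(d − c) − b)

with sensitivity *s* (slope, ≥ 0), lapse rate λ ∈ [0, 0.5], response bias
*b* ∈ [−1, 1] toward "on", and decision criterion *c* = 0.05 — half the
smallest phase magnitude, so an ideal (s → ∞) observer is correct on both
on-beat (d = 0) and all standard off-beat trials, while s = 0 yields chance
performance. Phase trials have *d* = magnitude. Period trials use
*d* = magnitude × 5.0: a 2% tempo error is perceptually a drift, not a fixed
offset, and 5.0 is the mean beep-to-beat drift (in IBI fractions per unit
magnitude) accumulated over an 11-beep train (mean of k/2 for k = 0…10).
Confidence ratings (1–7) increase with distance of P("off") from ½ plus
small Gaussian response noise; they are stored as metadata and never
analyzed, matching field practice.

**Tapper.** Intended tap *k* lies at

    beat₀ + latency + (beat_k − beat₀)·period_scale + phase_offset·IBI

plus Gaussian jitter with SD `motor_noise × IBI`; intended taps are dropped
with probability `miss_prob` and spurious taps inserted at uniform positions
with expected count `extra_prob × n_beats`. Consequences used as test
oracles: with zero noise, scored asynchrony equals |phase_offset| and CDEV
equals |period_scale − 1| exactly; with zero offset and noise σ, per-tap
absolute error is folded-normal with mean σ·√(2/π); CoV is invariant to the
phase offset and increases with σ.

**Cohorts.** A design is a list of cells over group (young / older /
Parkinson's) × music bin × dance bin, each with its own n, mean parameters
and between-participant SDs (sampled normally, clipped to valid domains).
Ages are drawn per group from the published demographics (20.41 ± 3.01,
64.63 ± 9.27, 68.28 ± 7.73 years); training years are drawn uniformly inside
the assigned bin (0–2 or 3–15). All randomness descends from one cohort seed
via `numpy` `SeedSequence` substreams, one per participant, so extending a
design never perturbs existing participants. The `default_design` plants the
study's headline structure: a 0.10-IBI mean phase offset in the Parkinson's /
minimal-music-training cell versus 0.02 elsewhere, higher perceptual
sensitivity in the trained bins, and slightly higher motor noise in the two
older groups.

## Scoring

* **Percent correct** = 100 × (judgment = truth) / n over test trials.
* **Asynchrony** = mean |tap − nearest beat| / mean IBI. Nearest-beat
  matching allows beat reuse and breaks exact half-IBI ties toward the
  earlier beat (deterministic and verified against exhaustive search).
  Taps outside the grid span match the terminal beats; no truncation window.
* **CDEV**: the printed formula in the source literature is ambiguous
  between a per-interval and an aggregate reading. The default is the
  per-interval mean |IRIᵢ − mean IBI| / mean IBI, which penalizes unstable
  as well as mis-set tempo and coincides with |period_scale − 1| for steady
  tapping; the aggregate form |mean IRI − mean IBI| / mean IBI is available
  via `variant="aggregate"`.
* **CoV** = sample (n−1) SD of IRIs over mean IRI — the sample convention
  because per-trial IRI counts are small.

Trials with fewer than `min_taps` taps (default 4; boundary inclusive) or no
tap after the listening window are invalid and propagate as missing values,
never zeros. Participant scores average the two consecutive repetitions per
excerpt first (a lone valid repetition stands for its excerpt), then across
excerpts, keeping excerpts equally weighted; participants with no valid
production trial or no responses are excluded, mirroring the exclusion of
incomplete batteries. All three production scores are invariant under joint
uniform time rescaling of taps and beats.

A vectorized frame scorer (`score_taps_frame`) performs the identical
computation on long-format tap logs, matching the per-trial path to 1e-9
relative tolerance in tests; it exists because replicated power studies
score millions of taps.

## Frequentist analyses

Factorial ANOVAs use Type III sums of squares with sum-to-zero contrasts
(the design cells are highly unbalanced; this matches the common JASP/SPSS
default), computed by `statsmodels` OLS + `anova_lm`. Effect size is partial
η² = SS_effect / (SS_effect + SS_error). Missing observations are deleted
listwise. Covariates (e.g. age) enter additively with no factor
interactions — the simplest ANCOVA reading. Empty cells raise an explicit
inestimable-effect error naming the missing cell. Simple main effects are
one-way ANOVAs within each level of the other factor, each on its own error
term. Pairwise follow-ups are pooled-variance t tests with Bonferroni
adjustment `p_adj = min(1, m·p)`. Welch's t uses the Satterthwaite df and
also accepts summary statistics (mean, SD, n) — reconstructing the published
older-vs-Parkinson's age contrast from printed summaries gives t ≈ −2.53,
within 0.1 of the raw-data value. Training-history binning cuts at 3 years
("0-2" / "3+") with the stricter 6-year dance cut ("0-5" / "6+") available.

## Bayesian model comparison

The bookkeeping — `P(M|data) = P(M)·BF₁₀ / Σ P(M′)·BF₁₀′`, `BF_M` as
posterior over prior odds, and the evidence bands with breakpoints 0.1,
1/3, 3, 10 (boundary values assigned to the weaker-evidence band, since the
source literature uses strict inequalities and leaves boundaries
undefined) — is exact arithmetic and accepts externally supplied BF₁₀
columns. The eight published tables bundled in `batkit.published` reproduce
their printed posterior columns at 2 dp except in a handful of rows whose
printed BF_M is internally inconsistent with its own BF₁₀ column; all rows
agree within the half-ulp slack implied by the 2-dp rounding of the printed
BF₁₀ inputs.

Computing BF₁₀ *from data* uses the BIC approximation
`BF₁₀ ≈ exp((BIC₀ − BIC₁)/2)` over the standard five-model candidate set
(null, each main effect, additive, full). This corresponds to a
unit-information prior: it will not numerically match Bayes factors computed
under other default priors (e.g. JASP's multivariate Cauchy), but preserves
evidence ordering and order of magnitude, and separates reproducible
arithmetic from prior-dependent fitting.

## Problem sizes and calibration checks

The acceptance suite runs: the published-table arithmetic (exact); 1000
randomized small trials against brute-force scoring oracles; noiseless
parameter recovery plus a 1000-replicate folded-normal check (3 SE); Type I
calibration of the factorial ANOVA and Welch's t over 1000 null simulations
at n = 20/cell (3 binomial SE around α = 0.05) and the F = t² identity to
1e-8; and an end-to-end power study of 200 replicate cohorts at n = 50/cell
with the group × training phase-offset interaction (motor noise 0.01 IBI),
requiring a significant scored-asynchrony interaction in > 90% of
replicates. The power replicates use a 5-excerpt × 2-repetition production
battery: at noise 0.01 the participant-level asynchrony estimate is
essentially exact, so excerpt count does not affect power, only runtime.

## Known limitations

* Synthetic cohorts have no serial dependence between taps (no phase
  correction / error feedback), no tempo drift within trial beyond the
  constant period scale, and no excerpt-difficulty or familiarity effects;
  passing tests demonstrate correctness of the scoring and statistics, not
  realism of human tapping dynamics.
* The perceiver treats period misalignment through a single drift-salience
  constant rather than a process model of tempo discrimination.
* BIC Bayes factors approximate, not reproduce, default-prior ANOVA Bayes
  factors.
* Audio is out of scope: excerpts exist only as beat annotations.
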