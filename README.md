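# batkit

Analysis toolkit for the **Beat Alignment Test (BAT)** — the two-part
sensorimotor-synchronization battery in which listeners (1) judge whether
metronome beeps superimposed on short musical excerpts are *on the beat* and
(2) tap along with the beat of the same excerpts. The BAT is widely used to
study auditory–motor timing across the lifespan and in clinical populations
such as Parkinson's disease, where beat-based timing is thought to depend on
basal-ganglia circuits.

`batkit` provides, as composable library modules plus a thin CLI:

* **stimuli** — beat grids and perturbed click tracks: on-beat beeps, *phase
  shifts* (beeps displaced by 10% or 17.5% of the inter-beat interval, early
  or late) and *period shifts* (beep tempo 2% faster or slower, so
  misalignment accumulates), with beeps starting 5 s into each excerpt, and
  randomized 3-practice / 17-test trial batteries;
* **scoring** — the standard BAT outcome measures (below);
* **cohort** — synthetic perceivers (lapse-contaminated logistic observers)
  and tappers (linear-phase model with phase offset, period scaling and
  Gaussian motor noise) whose parameters map one-to-one onto the scores,
  organized into study-shaped cohorts with known ground truth;
* **freq** — training-history binning (0–2 vs 3+ years), Type III factorial
  ANOVA with partial η², simple main effects, Bonferroni pairwise
  comparisons, Welch's *t*, and age–score regressions;
* **bayes** — Bayesian ANOVA model-comparison bookkeeping: BF₁₀, posterior
  model probabilities, BF_M and qualitative evidence bands, plus a
  BIC-approximate Bayesian ANOVA.

## The measures

For taps *r₁ … r_n* scored against annotated beats with mean inter-beat
interval IBI (inter-response intervals IRIᵢ = rᵢ₊₁ − rᵢ):

* **percent correct** — share of correct on/off-the-beat judgments over the
  17 test trials;
* **asynchrony** (phase matching) = mean |rᵢ − nearest beat| / mean IBI;
* **CDEV** (tempo matching) = mean |IRIᵢ − mean IBI| / mean IBI;
* **CoV** (tapping variability) = SD(IRI) / mean(IRI).

Trial scores are averaged over the two consecutive presentations of each
excerpt and then across excerpts. For the Bayesian tables, each candidate
model *M* carries a prior *P(M)* (uniform 0.20 over the five standard
candidates), a Bayes factor BF₁₀ against the null, a posterior
*P(M|data) = P(M)·BF₁₀ / Σ P(M′)·BF₁₀′*, and
*BF_M = posterior odds / prior odds*.

## Worked example

```python
import batkit as bk
from batkit.scoring import score_taps_frame, participant_table
from batkit.freq import add_training_bins

cohort = bk.simulate_cohort(bk.default_design(seed=7, n_per_cell=25))
scored = score_taps_frame(cohort.taps, cohort.grids)
scores = participant_table(scored, cohort.responses)
table  = add_training_bins(scores.merge(cohort.demographics, on="participant_id"))

print(table.groupby(["group", "music_bin"])[["pct_correct", "asynchrony"]].mean().round(3))
for e in bk.factorial_anova(table, "asynchrony", ["group", "music_bin"]):
    print(f"{e.name}: F({e.df_num}, {e.df_den}) = {e.F:.2f}, p = {e.p:.3g}, eta_p2 = {e.eta_p2:.3f}")
```

prints

```
                      pct_correct  asynchrony
group      music_bin
older      0-2             65.412       0.035
           3+              79.059       0.037
parkinsons 0-2             67.529       0.102
           3+              75.765       0.033
young      0-2             69.412       0.028
           3+              77.882       0.030
group: F(2, 144) = 542.76, p = 8.74e-68, eta_p2 = 0.883
music_bin: F(1, 144) = 441.46, p = 1.06e-45, eta_p2 = 0.754
group:music_bin: F(2, 144) = 542.66, p = 8.84e-68, eta_p2 = 0.883
```

The default design plants a larger tapping phase offset (0.10 IBI vs 0.02)
only in the Parkinson's / minimal-music-training cell — visible in the
asynchrony cell means — and the factorial ANOVA recovers it as a large
group × music-training interaction. Musically trained perceivers are more
sensitive, hence the higher percent-correct in the 3+ bins.

The same pipeline is available from the shell:

```sh
batkit simulate --seed 7 --n-per-cell 25 --out raw/
batkit score --taps raw/taps.csv --responses raw/responses.csv --beats raw/beats.csv --out scores.csv
batkit analyze --scores scores.csv --demographics raw/demographics.csv --out analysis/
batkit bayes --bf-table bf.csv --out bayes.csv     # bookkeeping on external BF_10 values
batkit report --results analysis/ --out report.txt
```

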