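# Methods

This note documents the models implemented in `cadkit`, the default
parameters and the reasoning behind the numerical and design choices. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The titration engine

One discounting session consists of the three pairings of the strategies
distraction, distancing and expressive suppression, presented in randomized
order with randomized left/right placement. Each pairing has two phases:

1. **Equal-value round.** Three presentations of "1 € for A vs 1 € for B".
   The strategy chosen at least twice becomes the *flexible* strategy; the
   other is *fixed* at 2 €. Three binary votes cannot tie.
2. **Titration.** Six presentations. The flexible offer starts at 1.00 €;
   after each of the first five choices it moves down (flexible chosen) or
   up (fixed chosen) by an adjustment that starts at 0.50 € and halves each
   step. The sixth choice is only recorded; its ±0.02 € effect is applied at
   the valuation stage.

**Rounding locus.** The adjustments are kept exact (multiples of 2⁻⁵ €,
which binary floating point represents without error) and only the displayed
value is rounded, half away from zero, to two decimals. This is the unique
two-decimal rule under which the all-fixed path displays
1.00 → 1.50 → 1.75 → 1.88 → 1.94 → **1.97** and the all-flexible path ends
at **0.03**; accumulating *rounded* adjustments instead would end at 1.96 or
1.99. Money is therefore never stored as integer cents: internal values are
exact binary fractions, displays are two-decimal floats.

**Degenerate inputs and tie-breaks.** A deterministic agent facing an exact
utility tie chooses the flexible strategy during titration and the
canonically (alphabetically) first strategy in the equal round. Comparisons
use a ±10⁻⁹ € tolerance: displayed values and indifference points sit on the
0.01 € grid, so genuine differences are never that small but float round-off
can be, and an unguarded comparison would occasionally flip the documented
tie-break.

## Subjective values

Per pairing, `SV_flexible = 1` and
`SV_fixed = (last display − 0.02)/2` if the last choice was flexible,
`(last display + 0.02)/2` if it was fixed. The arithmetic deliberately uses
the *rounded displayed* value: (0.03 − 0.02)/2 = 0.005 reproduces the
observable minimum, whereas the exact internal endpoint would give 0.005625.
Aggregated SVs are the mean of each strategy's two per-pairing SVs; ranking
ties (identical aggregated SVs) are broken canonically so the −1/0/1
recoding is always well defined. The ordered-SV least-squares line over
codes (−1, 0, 1) has the closed form intercept = mean(SV) and
slope = (lowest − highest)/2 ≤ 0.

**Recovery bound.** A deterministic chooser with indifference point `m*`
walks the staircase into a bracket of width 0.03125 € around `m*`; with the
±0.02 € final adjustment the per-pairing SV deviates from `m*/2` by at most
0.03. The suite verifies this exhaustively on the 0.01 € grid against a
brute-force bracket walker implemented independently of the session engine
(`valuation._threshold_walk`), and verifies that the analytic oracle
`expected_sv` reproduces the engine exactly for random transitive agents.

## Simulated agents

An agent values an on-screen option at displayed money plus its strategy
utility (€). Choices are argmax at infinite inverse temperature, otherwise
logistic in the utility difference with slope `inverse_temperature` (1/€);
with probability `lapse_rate` the response is replaced by a uniform coin —
the standard psychometric lapse convention, applied as an independent
mixture after the logistic draw. `CyclicAgent` implements an intransitive
pairwise preference to exercise the inconsistent response pattern in which
every strategy loses one equal round and no aggregated SV reaches 1.0.

## The synthetic study generator

The generator emulates the study structure the analysis assumes: n = 120
participants, five blocks (neutral viewing, negative viewing, three
regulation strategies) of 20 trials, block-level slider ratings, per-trial
EMG activity summaries, one discounting session per participant, a final
strategy choice and questionnaire scores.

- **Ratings** (arousal, effort; utility for regulation blocks only) are
  drawn per condition from normal distributions with the condition means and
  SDs of the study's descriptive table (e.g. suppression effort
  158.3 ± 99.5), split into a subject-level random effect and a residual by
  `rating_icc` (default 0.3), and resampled — not clipped — into the slider
  range. The original slider's numeric range is not documented; since
  condition means reach ≈ 229, the generator uses a continuous 0–300 scale
  (configurable). Resampling keeps draws interpretable but raises the
  realized mean of strongly left-truncated conditions (neutral-viewing
  arousal/effort); the generator tests therefore check cohort means against
  the closed-form truncated-normal expectation, not the raw input mean.
- **EMG summaries** are drawn per trial such that the per-participant
  condition means reproduce the descriptive table's means and SDs (share
  `emg_icc` between subjects).
- **Agent utilities** are built as
  `u_s = 2·(w_eff·effort̃_s + w_util·utilitỹ_s + w_corr·corrugator̃_s) + scale·ε_s`,
  where tildes denote within-participant centring across the three
  strategies, the default weights (−6.85·10⁻⁴ /slider-unit,
  +1.42·10⁻³ /slider-unit, +7.45·10⁻³ /mV) are the association magnitudes
  the paradigm is designed to detect, ε is N(0, `utility_sd`) and
  `scale = exp(N(0, dispersion_log_sd))`. The factor 2 makes a unit utility
  change move a per-pairing SV by ≈ the weight itself (SV differences are
  utility differences over the 2 € anchor). SVs then come from running these
  agents through the titration engine — there is no shortcut path, which the
  suite verifies by recomputing SVs from the emitted session logs.
- **Between-subject SV variance.** A purely additive per-subject utility
  shift cancels exactly in pairwise comparisons, so a "random intercept"
  cannot be injected directly. Subject-level heterogeneity enters instead
  through the dispersion scale: participants differ in how strongly they
  differentiate between strategies, which moves their mean SV. The defaults
  `utility_sd = 0.30`, `dispersion_log_sd = 0.45` were calibrated once by
  simulation so the null-model ICC of the generated SVs is ≈ 0.19, the
  between-subject share observed in the study this emulates.
- **Decision noise.** Defaults `inverse_temperature = 10 /€`,
  `lapse_rate = 0.02` describe highly consistent deciders: about 96% of
  generated participants show exactly one SV of 1.0, matching the observed
  119 of 120.
- **Choice and questionnaires.** The last-block choice equals the
  highest-SV strategy with probability `choice_agreement = 0.75` (uniform
  over the other two otherwise), which yields a strongly diagonal 3×3
  predicted-vs-actual table. FlexER scores default to pure noise
  (50 ± 10) with configurable loadings on the ordered-SV intercept and
  slope — the study found no association, and recovery tests switch the
  loadings on explicitly. Self-control and NFC are standard-normal level-2
  covariates with no built-in effect.

**What the generator does not emulate:** habituation across trials,
session/time-of-day effects, EMG artifacts, rating anchors and response
styles, and any trait structure of SVs. Passing recovery tests therefore
show that the pipeline recovers what the generator puts in — not that real
data satisfy the generative assumptions.

**Stimulus partitioning.** The evolutionary partitioner splits 100 rated
items into five sets of 20 by genetic search over permutations (tournament
selection of size 3, cross-set swap mutation, two elites, population 60,
250 generations), minimizing the summed variance of set means over the
valence and arousal dimensions. Elitism makes the best objective
non-increasing; with the defaults, set means typically agree within 0.1
rating units on both dimensions.

## EMG preprocessing

Order of operations: 20 Hz high-pass and 300 Hz low-pass Butterworth filters
(order 8 each) and a 50 Hz notch (second-order IIR, Q = 30), all applied
forward–backward (zero phase); full-wave rectification; integration as a
100 ms moving average; downsampling to 100 Hz; per-trial mean over the 6 s
picture window minus the mean of the 2 s pre-onset baseline. The recording
protocol fixes the cutoffs and orders but not the filter family, phase
handling or integration window; Butterworth/zero-phase/100 ms are common
choices and all are configurable. Baseline subtraction after trial averaging
makes each trial's corrected pre-onset mean exactly zero. Raw recordings and
the filtered product are distinct types, so the chain cannot be applied
twice. Trials whose windows exceed the record are dropped with a warning.

The synthetic generator band-limits Gaussian noise to 20–300 Hz with a steep
zero-phase filter and scales it by `noise_floor + burst_amplitude[condition]`
during stimulus windows (fixation gaps uniform 3–5 s). Because the carrier
is Gaussian, the rectified mean at amplitude *a* is √(2/π)·a times the
cascade's RMS gain, which the tests compute in closed form from the filter
frequency responses together with the moving-average edge terms; recovered
activities match within 1%.

## Statistical pipeline

- **Unit of observation.** The default analysis table is trial-level
  (participant × strategy × trial, block ratings broadcast), matching the
  degrees of freedom the original analysis implies; a condition-level mode
  (3 rows/participant) exists for simulations. Note the caveat: with
  block-level predictors duplicated across trials, residual-df t-tests are
  anticonservative. Null-calibration simulations in the suite therefore run
  at condition granularity; sign-recovery and ICC checks are unaffected.
- **Multilevel model.** Random-intercept linear mixed model fitted by REML
  (statsmodels `MixedLM`), level-1 predictors centred within cluster.
  statsmodels provides no Satterthwaite approximation, so t-tests use
  residual df and the result records `df_method = "residual"`. The
  null-model ICC is σ²_subject/(σ²_subject + σ²_resid); R² marginal and
  conditional follow the fixed/random/residual variance decomposition;
  Cohen's f² per predictor is (R²_full − R²_reduced)/(1 − R²_full) on the
  *marginal* R² (ΔR² is reported alongside). Boundary (singular)
  random-effect estimates are flagged, not dropped. The optimizer order is
  bfgs → cg → powell; lbfgs stalls on the variance boundary for these data
  shapes.
- **rmANOVA.** One-factor repeated-measures ANOVA via pingouin, with
  Greenhouse–Geisser epsilon applied to both dfs, generalized and partial
  eta squared, and pairwise paired-t post-hocs adjusted by Tukey (default;
  studentized-range on the contrast's own df) or Bonferroni. Zero-variance
  input returns F = 0 with ε = 1 by convention.
- **Choice prediction.** Pearson χ² on the full 3×3 predicted-vs-actual
  grid; strategy levels absent from both margins remain structural zeros
  (cells with zero expectation contribute nothing) and df stays 4. The
  choice regression defaults to a proportional-odds logit over the canonical
  strategy order; because a 3-way strategy choice is nominal rather than
  ordinal, a multinomial mode is provided and used for sign checks.
  Separation and constant predictors are flagged with a warning rather than
  raised.
- **Flexibility regression.** OLS of the FlexER score on the ordered-SV
  intercept and slope, with coefficient CIs, R², F and p.
- Bayes factors are not computed; every result bundle carries a note.

## Problem sizes used by the test suite

Simulation-based tests use sizes chosen to make the checked property
decisive: 199 grid points for exhaustive indifference recovery; 500 agents
for uniqueness and noise-ladder RMSE; 100 replicates of n = 120 cohorts for
multilevel sign/ICC recovery; 60 replicates (n = 60, condition granularity)
for type-I calibration; 5–6 replicates per point for the f² ladder.

## Known limitations

- Residual-df p-values in the mixed model are approximate (see above); for
  confirmatory use, refit with a Kenward–Roger/Satterthwaite implementation.
- The generator's rating–SV link is linear in within-participant centred
  ratings; saturation at SV = 1 for the top strategy attenuates recovered
  coefficients relative to the generating weights (signs and ordering are
  preserved, which is what the tests assert).
- The proportional-odds model inherits the arbitrary canonical ordering of a
  nominal outcome; interpret its coefficients with care or use the
  multinomial mode.
- The interactive terminal runner presents the same offers as the
  experiment but makes no attempt at timing accuracy or response-time
  capture.
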