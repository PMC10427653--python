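# cadkit

**Cognitive and Affective Discounting (CAD) for emotion-regulation strategies.**

People regulate emotions with strategies such as *distraction* (thinking of
something else), *distancing* (adopting an uninvolved observer's view) and
*expressive suppression* (keeping a neutral face). Classic effort-discounting
paradigms assign a subjective value (SV) to task levels by titrating money
against a harder option — but they assume everyone agrees on which option is
harder. Emotion-regulation strategies have no objective difficulty order. The
CAD paradigm solves this with an *equal-value round*: each strategy pair is
offered three times at 1 € vs 1 €, and the majority winner becomes the
*flexible* option whose reward is then titrated against the loser anchored at
a *fixed* 2 €.

`cadkit` is a tested implementation of that paradigm and its analysis
pipeline for researchers in decision science and affective psychophysiology:

- **titration** — the adaptive staircase: starting at 1.00 €, the flexible
  offer is lowered (flexible chosen) or raised (fixed chosen) by adjustments
  of 0.50, 0.25, 0.125, 0.0625, 0.03125 € across six presentations; the
  internal value stays exact and only the on-screen value is rounded to two
  decimals (half away from zero), so the extreme paths end at the displayed
  1.97 € and 0.03 €.
- **valuation** — SVs from titration outcomes. Per pairing,
  `SV_fixed = (last display ± 0.02 €) / 2 €` (− if the last choice was
  flexible, + if fixed) and `SV_flexible = 1`; per strategy, the mean over
  its two pairings. Attainable values span 0.005–1.00. Also the −1/0/1 rank
  recoding and each participant's ordered-SV intercept (overall strategy
  worth) and slope (preference strength).
- **agents** — parametric simulated deciders (strategy utilities in €,
  softmax inverse temperature, lapse rate). A deterministic agent reduces to
  a threshold rule with indifference point `m* = 2 + u_fixed − u_flexible`,
  giving exhaustive ground truth for recovery tests: over the whole 0.01 €
  grid of `m*`, recovered per-pairing SVs stay within 0.03 of `m*/2`.
- **synthetic_study** — a full synthetic cohort (default n = 120, five
  blocks × 20 trials) with slider ratings (arousal, effort, utility on
  0–300), per-trial facial-EMG summaries, questionnaire scores, and SVs
  produced by running agents through the titration engine. Includes the
  evolutionary partitioner that splits 100 rated pictures into five sets
  with matched valence/arousal means.
- **emg** — facial-EMG preprocessing (corrugator supercilii, levator labii):
  20–300 Hz order-8 Butterworth band-pass, 50 Hz notch, full-wave
  rectification, 100 ms moving-average integration, downsampling to 100 Hz,
  per-trial means over the 6 s picture window baseline-corrected by the 2 s
  pre-onset window — plus a synthetic generator with known burst amplitudes.
- **analysis** — the statistical pipeline: repeated-measures ANOVAs with
  Greenhouse–Geisser correction and Tukey/Bonferroni post-hocs; the
  random-intercept multilevel model
  `SV ~ effort + arousal + utility + corrugator + levator + (1 | subject)`
  fitted by REML with within-cluster-centred level-1 predictors, null-model
  ICC, marginal/conditional R² and Cohen's f² per predictor; the predicted-
  vs-actual choice χ² (3×3, df = 4); ordinal/multinomial choice regression
  on SVs; and the FlexER regression on ordered-SV intercepts and slopes.

## Worked example

```python
from cadkit import Agent, run_session, profile_from_session

agent = Agent(utilities={"distraction": 0.8, "distancing": 0.2, "suppression": -0.4})
session = run_session("demo", agent, 7)          # 27 choices, replayable from the seed
profile = profile_from_session(session)
for s, v in sorted(profile.sv.items(), key=lambda kv: -kv[1]):
    print(f"SV {s.value:<12} {v:.3f}   rank code {profile.rank_code[s]:+d}")
print(f"ordered intercept {profile.ordered_intercept:.3f}, slope {profile.ordered_slope:.3f}")
print("predicted choice:", profile.predicted_choice.value)
```

prints

```
SV distraction  1.000   rank code -1
SV distancing   0.847   rank code +0
SV suppression  0.547   rank code +1
ordered intercept 0.798, slope -0.226
predicted choice: distraction
```

Distraction has the highest utility, wins both of its equal rounds and
therefore carries SV 1.0. Distancing's utility is 0.6 € below distraction's,
so its titration against distraction converges near the indifference point
2 − 0.6 = 1.4 € (SV ≈ 0.7), while it beats suppression (SV 1 in that
pairing); the mean of the two per-pairing SVs is 0.847. The ordered-SV line
over codes (−1, 0, 1) summarises the profile: the intercept is the mean SV
and the slope −0.226 quantifies how peaked the preference is.

The same flows are available from a shell:

```bash
cadkit simulate --n 20 --seed 1 --out out/cohort        # sessions + SV profiles + truth
cadkit titrate --interactive --out mylog.csv            # run a session on the terminal
cadkit sv --log out/cohort/sessions.csv --out prof.csv  # SVs from any session log
cadkit generate-study --n 120 --seed 1 --out out/study  # full synthetic study
cadkit analyze --table out/study/study_table.csv \
    --blocks out/study/blocks.csv --profiles out/study/profiles.csv \
    --out out/results                                   # JSON bundle + text report
cadkit emg-preprocess --synthesize --seed 1 --out trials.csv
```

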