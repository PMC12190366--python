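# bstask

A headless, testable engine for the **1-back Stroop (BS) task** — a
high-mental-workload paradigm that induces mental fatigue by combining task
complexity with time pressure — together with its calibration procedure,
session protocols, simulated participants, and analysis pipeline.

It is aimed at researchers who study mental workload and mental fatigue and
want the paradigm's machinery (trial combinatorics, deadline calibration,
protocol timing, repeated-measures statistics) as a reusable, seedable
library rather than buried inside presentation software. A display
front-end (e.g. PsychoPy) can drive the engine through a small responder
interface; everything here runs on a virtual clock with no graphics.

## The paradigm

Each trial shows a color word (rendered as a Chinese character by a
front-end) in one cell of a 3×3 grid, in one of four ink colors. The
participant makes two judgments at once:

- **1-back**: does the stimulus occupy the same grid cell as on the
  previous trial?
- **Stroop**: does the word's meaning match its ink color?

The 2×2 cross defines four conditions — (1) both consistent, (2) both
inconsistent, (3) 1-back consistent only, (4) Stroop congruent only — and
the response key depends only on XNOR(back-consistent, congruent):
conditions 1–2 share one key, 3–4 the other (counterbalanced F/J).

Time pressure is set per condition through the required-time/available-time
ratio: with mean unconstrained reaction time RT̄_c for condition c, the
response deadline is

    AT_c = round₁₀₀(1.25 × RT̄_c)        (so RT̄/AT = 0.8)

which, applied to unlimited-time condition means of 1815.63 / 2394.17 /
2110.47 / 2251.46 ms, gives the deadlines 2300 / 3000 / 2600 / 2800 ms used
by the protocols. Fatigue induction runs the task continuously for 30
minutes (6 blocks, 1:1:1:1 condition ratio), with a 0–100 VAS
(mental fatigue / effort / stress / boredom) after every block and a
3-minute psychomotor vigilance test (PVT; valid ≥ 100 ms, lapse ≥ 500 ms)
before and after. Workload validation compares the BS task against a
2-back letter task over 8 short blocks, scored with the unweighted NASA-TLX.

See `docs/methods.md` for the full model, parameter, and statistics notes.

## Worked example

Simulate a small fatigue-induction cohort and analyze it:

```sh
bstask simulate --n 8 --seed 11 --out-dir demo/logs
bstask analyze --logs demo/logs --protocol tot --out-dir demo/results
cat demo/results/block_effects.csv
```

```
indicator,chi2,df,p,kendalls_w
mental_fatigue,38.88590604026845,6,<0.001,0.8101230425055927
mental_effort,15.053956834532357,5,0.010,0.37634892086330896
mental_stress,16.22743682310468,5,0.006,0.405685920577617
boredom,14.233576642335754,5,0.014,0.35583941605839386
correct_count,24.67272727272725,5,<0.001,0.6168181818181813
accuracy,8.093525179856107,5,0.151,0.20233812949640267
```

Each row is a Friedman test across the session's timepoints (mental fatigue
includes the pre-task baseline, hence 6 df instead of 5) on one subjective
or behavioral indicator, with Kendall's W = χ²/(n(k−1)) as the concordance
effect size. With only 8 simulated participants the subjective fatigue
trend is already decisive (χ²₍₆₎ = 38.9, p < 0.001, W = 0.81) while block
accuracy is not yet significant — at the protocol's actual cohort sizes the
planted performance decline is detected at p < 0.001 in essentially every
replicate (see the test suite). `demo/results/pvt_pre_post.csv` holds each
participant's pre/post PVT mean RT and lapse counts for the paired
comparison.

The same machinery is importable directly:

```python
from bstask import compute_available_time, tot_config, generate_cohort
from bstask.analysis import cohort_block_table, friedman_kendall

compute_available_time(1815.63)          # -> 2300 (ms)
logs = generate_cohort(72, protocol_config=tot_config(), seed=1)
res = friedman_kendall(cohort_block_table(logs, "accuracy"))
print(res.statistic, res.p_formatted, res.effect_size)
```

Other entry points: `bstask generate` (constrained pseudo-random trial
sequences as CSV), `bstask calibrate` (deadline derivation from
unlimited-time RT logs, with the two-level 3 SD preprocessing), `bstask run`
(single sessions: `hmw`, `tot`, or `pvt`), `bstask fixtures` (canned
table-like cohorts). Shipped YAML presets: `hmw_step2`, `tot_step3`,
`calibration_step1`.

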