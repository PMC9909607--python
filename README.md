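# mstkit

Design, score and simulate the **Mnemonic Similarity Task (MST)** — the
widely used recognition-memory test that probes hippocampal pattern
separation with *similar lures* alongside the usual repeats and novel
foils — and analyse how well shortened task variants capture the
full-length task's score.

`mstkit` is for researchers who run (or plan to run) an MST variant and
need to: generate trial schedules with controlled condition counts and
lag structure, score response logs into the standard outcome measures,
estimate how reliable a candidate short form will be *before* collecting
data, and run the variant-vs-baseline psychometric comparison once data
are in. No stimulus images are required anywhere: a stimulus pair is
just `(set_id, pair_id, lure_bin)`.

## Outcome measures

With the three-choice old/similar/new (OSN) prompt:

```
LDI = p("similar" | lure)  − p("similar" | foil)     lure discrimination index
REC = p("old" | repeat)    − p("old" | foil)         corrected recognition
```

With the two-choice old/new (ON) prompt, equal-variance signal
detection applies: `d′(TL) = z(hit) − z("old"|lure)` for target–lure
discrimination and `d′(TF) = z(hit) − z("old"|foil)` for target–foil
discrimination (extreme rates corrected by 1/(2N)). Engagement
filtering accepts a session when REC ≥ 0.5 (OSN) or d′(TF) ≥ 1.5 (ON).
In the continuous task format the first presentations double as the
novel foils.

Task variants shipped as presets:

| variant        | format     | structure                              | trials |
|----------------|------------|----------------------------------------|--------|
| `full-st`      | study-test | 128 study + 64/64/64 test              | 320    |
| `full-cont`    | continuous | 128 firsts + 64 repeats + 64 lures     | 256    |
| `reduced-st`   | study-test | 64 study + 20/44/20 test               | 148    |
| `reduced-cont` | continuous | 64 firsts + 20 repeats + 44 lures      | 128    |

Continuous probes honour per-condition lag bands (gaps of 4–11 and
20–99 trials, 32+32 per condition in the full design), where the lag is
the difference of trial indices between a probe and its first
presentation. `reduced-cont` with the guided practice block is the
"optimized MST" (oMST) configuration, and LDI scores convert between
the baseline and oMST scales via the shipped regression
`oMST = 0.33 + 0.65 · baseline`.

## Worked example

```python
import mstkit as m

bank = m.make_synthetic_bank(seed=7)                      # 6 sets x 192 pairs
spec = m.design_variant("reduced-cont", seed=7)           # the oMST design
schedule = m.build_schedule(spec, bank.pairs_for_set(1))
lo, hi = m.estimate_duration(schedule)

participant = m.ParticipantParams(d_rep=4.8)              # a strong memory
log = m.simulate_session(schedule, participant, seed=7)
report = m.score_session(log)
print(f"LDI = {report.ldi:.3f}  REC = {report.rec:.3f}  valid = {report.valid}")
print(f"equivalent baseline-MST LDI: "
      f"{m.convert_scores(report.ldi, 'omst_to_baseline'):.3f}")
```

prints

```
LDI = 0.386  REC = 0.750  valid = True
equivalent baseline-MST LDI: 0.087
```

128 scored trials (plus a 9-trial practice block), 5.3 minutes at the
2.5 s per-trial minimum. The simulated participant discriminates lures
well above chance (LDI 0.386), recognises repeats comfortably above the
0.5 validity bar (REC 0.750), and the conversion line maps the
(short-lag, hence easier) oMST score back to the harder baseline scale.

A whole variant-comparison experiment can be replayed on a synthetic
cohort in one call — simulate every participant doing the baseline and
the alternate task, score, filter validity, robustly correlate:

```python
>>> m.experiment_replay("5b", seed=3, n_participants=49)
{'n_enrolled': 49, 'n_valid': 38, 'baseline_mean': 0.311,
 'variant_mean': 0.346, 'r_clean': 0.633, 'n_removed': 0,
 'fisher_one_tailed_p': 0.213, ...}
```

Here 38 of 49 simulated participants pass the engagement filter, the
short continuous variant scores higher than the baseline (0.346
vs. 0.311, the expected short-lag benefit), and the baseline–variant
correlation (0.633, no outliers flagged) is statistically compatible
with the baseline's own test-retest reliability (one-tailed Fisher
p = 0.213).

The same operations are available from a shell:

```
mstkit --seed 3 generate --variant reduced-cont --out sched.csv
mstkit --seed 3 simulate --design sched.json --n 50 --out logs/
mstkit score --log logs/log_p0001_s1.csv --out report.json
mstkit reliability --scores paired.csv --out result.json
mstkit power --r 0.48          # -> 32
```

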