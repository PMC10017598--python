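# metresrtt

Design generation, simulation and analysis for a **metre-augmented serial
reaction time task (SRTT)** — a visuomotor sequence-learning experiment in
which a task-irrelevant auditory metre (a 3- or 4-beat grouping with one
accented beat per cycle) runs alongside the repeating visual cue sequence.

The package is aimed at researchers who want to analyse such experiments —
or stress-test the analysis before collecting data. It provides:

* **Design generation** — 12-unit cue sequences with equal location
  frequencies and equal transition probabilities (exactly the Eulerian
  circuits of the complete directed graph on the four cue locations),
  counterbalanced key mappings, accent schedules, the 12-block plan with
  phase-shifted-metre / new-metre / new-visual-sequence test blocks, and
  same/different rhythm-discrimination stimuli.
* **A synthetic-data simulator** — seeded trial-level reaction times with
  per-participant learning curves, a bimodal signed accent effect, test-block
  disruptions tied to rhythmic sensitivity, realistic accuracy (~93%
  correct) and anticipatory responses (~2% of correct presses under 50 ms).
* **Preprocessing** — the trial-filtering and participant-exclusion rules,
  mean-centring and median splits.
* **The accent permutation test** — the core statistic and its restricted
  permutation null, with Benjamini–Hochberg FDR correction.
* **Descriptive contrasts** — test-block vs late-learning comparisons,
  block-boundary windows, standardised disruption scores, correlations and
  variability-by-accent profiles.

## The statistic at the core

For each participant, learning-phase reaction times are summarised by the
**accent relative difference**

```
ARD = |x̄_accented − x̄_unaccented| / ((x̄_accented + x̄_unaccented) / 2)
```

a dimensionless measure of how far responses to accented and unaccented
cues diverge, irrespective of direction. Its null distribution is built by
shuffling the participant's reaction times against the accent labels
**within each response key × block stratum** (a restricted permutation:
key- and block-level RT structure is preserved, only the accent pairing is
broken). A participant is *flagged* when the observed ARD exceeds the 95th
percentile of the null; p-values use the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_iter)` and are corrected across
participants with the Benjamini–Hochberg step-up procedure.

## Worked example

```python
from metresrtt import GenParams, simulate_cohort, filter_valid, AccentPermutation
from metresrtt.contrasts import block_contrast

profiles, designs, trials = simulate_cohort(GenParams(), seed=1)
clean = filter_valid(trials)                    # exclusions + trial filter
kept = profiles[~profiles["participant"].isin(clean.excluded)]

res = AccentPermutation.from_clean(clean).fit(n_iter=2000, seed=1)
print(res.summary(kept))
```

```
Accent permutation test (restricted shuffle within key x block)
  participants: 41   iterations: 2000   learning blocks: 1-8
  flagged (> 95th null percentile): 13 / 41
  flagged faster-accented: 11   slower-accented: 2
  median observed ARD: 0.0146   median q: 0.343
  metre 3/4-style grouping: 3 of 18 flagged
  metre 4/4-style grouping: 10 of 23 flagged
```

Five of the 46 simulated participants were excluded as heavy anticipators,
leaving 41. Flagged participants concentrate in the 4-beat metre — the
simulator's mixture puts most non-zero accent effects there — and most
flagged participants responded faster to accented cues. The phase-shift
contrast shows the slowing in the test block, strongest for participants
with high rhythm-discrimination scores:

```python
print(block_contrast(clean, 8, 9, profiles=kept).summary_text())
```

```
block 9 - block 8 (ms)
  overall            n= 41  mean=  +15.38  95% CI [9.33, 21.44]  sd=19.18
  metre_condition=3  n= 18  mean=  +12.59  95% CI [2.38, 22.81]  sd=20.54
  metre_condition=4  n= 23  mean=  +17.56  95% CI [9.69, 25.44]  sd=18.21
  rhythm_group=high  n= 21  mean=  +25.83  95% CI [17.19, 34.47]  sd=18.98
  rhythm_group=low   n= 20  mean=   +4.41  95% CI [-1.28, 10.10]  sd=12.16
```

The same pipeline is available from the shell:

```bash
metresrtt run --seed 1 --out runs/demo       # end-to-end, writes report.json
metresrtt design --metre 4 --seed 1 --out designs/
metresrtt calibrate --effects 0,10,25,50 --out calibration.csv
```

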