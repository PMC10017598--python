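# Methods

This note documents the models and procedures implemented in `metresrtt`:
what the experimental design encodes, what the synthetic-data generator
does and does not emulate, how the permutation test is constructed, and the
numerical and design decisions taken where more than one choice was
defensible.

## Experimental design

**Cue sequences.** The visual sequence is a 12-element series over four cue
locations with each location appearing three times and — reading the
sequence cyclically, wrap-around transition included — every ordered pair
of distinct locations appearing exactly once as a transition. Such
sequences are precisely the Eulerian circuits of the complete directed
graph on four nodes (12 arcs, each used once), read as node sequences.
`generate_basic_sequence` performs a seeded backtracking circuit search;
`enumerate_basic_sequences` enumerates the full pool by depth-first search.
The pool has 3 072 members (rotations counted as distinct lists), which
matches the BEST-theorem count of 256 circuits × 12 rotations and is frozen
as a regression value in the tests. The wrap-around reading is used because
blocks repeat the sequence cyclically and the canonical published example
satisfies it.

**Counterbalancing.** Six distinct sequence structures × two fixed key
bijections (`Z X N M` and `N M Z X` over locations 1–4) give 12 task
variants. Whether the original six structures were related by rotation or
drawn independently is not documented; we draw six independent structures
from the pool per seed.

**Metre schedules.** Both metres run at 60 beats/min (1000 ms inter-onset
interval) with one accented beat per cycle at position 1. The background
subdivision divides each beat into `grouping` equal parts; the 3-grouping
subdivision is stored as the printed integer 333 ms (nearest-ms rounding of
1000/3), which leaves a deliberate 1 ms rounding slack in the
`subdivisions × IOI = beat` invariant.

**Block plan.** Twelve blocks of 120 cues (10 cycles of the 12-cue
sequence): eight learning blocks, a phase-shifted-metre test (accent
pattern delayed by one cue step; both the sequence and the metre are
individually unchanged), one more learning block, a new-metre test (the
other grouping), and a new-visual-sequence check against the familiar
metre. Start offsets are sampled without replacement from 1–12 per seed, so
each block starts at a different point of the joint cue/metre cycle while
the cue↔accent pairing during learning stays fixed. The phase-shift
direction (delay) is a convention; only "one step" is specified. The novel
sequence for the final check is drawn from the pool subject to differing
from the learned sequence in at least 6 of 12 positions.

**Rhythm-discrimination stimuli.** Each pattern is a permutation of the
inter-onset-interval multiset {5×200, 2×400, 1×600, 1×800} ms (3.2 s
total; 1 512 distinct patterns exist). Difficulty of "different" trials is
operationalised by the shared IOI prefix: easier pairs diverge within the
first three intervals, harder pairs agree on at least the first four. A
session holds 40 trials — 20 same, 10 easier-different, 10
harder-different — with 8 of 10 easier-different trials placed in the first
half (and symmetrically for harder), emulating the easier-first ordering.

## Generative model

Per participant *i*, block *b* and trial, reaction time in ms is

```
rt = baseline_i − slope_i (b − 1)
     + accent · effect_i · exp(−λ (b − 1))
     + disruption_i(role)
     + ε,     ε ~ N(0, sd_i²)
```

floored at 120 ms; injected anticipatory responses override this with a
uniform draw on [−400, 50) ms and are marked correct (negative values stand
for pre-cue presses). Correctness is Bernoulli(1 − error_rate_i). A
lognormal multiplicative-noise option exists but is off by default, since
the analyses model linear block effects.

Key defaults and their rationale (all set from the study's reported
descriptive values):

| parameter | default | reasoning |
|---|---|---|
| baseline | lognormal, median 460 ms, σ=0.21 | task-average retained RT ≈ 430 ms after the learning decline |
| slope | N(8.28, 3²) ms/block | the reported linear block effect |
| accent-effect mixture | 4/4: (0.30, 0.35, 0.35); 3/4: (0.85, 0.075, 0.075) over (zero, −25 ms, +25 ms), sd 8 | bimodal signed effects, concentrated in the 4-beat metre; reproduces roughly 17/24 vs 3/17 flagged |
| accent decay λ | 0.15 /block | early ~17 ms accented advantage shrinking to ~4 ms by late learning |
| phase-shift disruption | 20 ms × (1 + 0.9 z_rhythm) | strong slowing for rhythm-sensitive participants (~+30 ms at the boundary for the high group) and near-zero for the low group; deliberately loose — only boundary summaries are reported for the original data |
| new-metre disruption | 15 ms × z_rhythm (3→4 direction); −8 ms (4→3) | heterogeneous sign by sensitivity in one direction, mild speeding in the other, mirroring the mixed observed pattern |
| new-visual cost | 63 ms latent | the observed contrast versus pooled blocks 8/10 is the latent cost minus ~3 blocks of continued learning, ≈ 38 ms as reported |
| trial noise | 60 ms, lognormal across participants (σ=0.2) | typical within-participant SD |
| accented-variability ratio | 0.85 (4-beat metre only) | accented responses less variable (reported SDs ≈ 58 vs 65 ms) |
| error rate | Beta, mean 0.07 | correct share = antic + (1−antic)(1−err) ≈ 93% |
| anticipatory rate | Beta, mean 2.24%, SD 1.84%; plus an 11% "anticipator" fraction at 18% | matches the reported anticipatory share and yields ~5 exclusions per 46 |
| rhythm accuracy | Beta, mean 0.82, SD 0.12 → score = % correct of 40 | median score ≈ 85 on the 2.5-point grid |
| rank correlations | score↔RT −0.44, score↔experience 0.65 | Gaussian copula on the latent normals; latent correlations are inflated by 1/0.87 to offset the binomial measurement noise of the 40-trial score, so the *observed* correlations hit the targets |

What the generator does **not** emulate: chunking dynamics, key-press force
or duration, fatigue/boredom drifts, within-block recovery after a test
block begins (disruption is constant across a block), and any plateau in
the learning curve (the slope is linear through block 12). Passing tests
therefore demonstrate that the analysis machinery recovers effects under
this stylised model, not that the model captures every feature of real
SRTT data.

## Permutation test

The observed statistic is the accent relative difference of raw (not
mean-centred) retained learning-phase RTs; the statistic's normalisation by
the participant's mean already removes participant-level scale, and
mean-centred input would put the denominator near zero (rejected by the
positivity precondition). Strata are response key × block: cue location is
a bijection of key within a mapping, so a separate location stratum would
be redundant. Within each stratum the RTs are permuted against the accent
labels (equivalently, a size-k subset is sampled without replacement as
the accented draw); strata containing a single accent class cannot be
reshuffled, contribute a constant, and are logged as degenerate.

Numerical conventions:

* p-value: add-one estimator `(1 + #{null ≥ obs}) / (1 + n_iter)`; the
  percentile is the share of null values strictly below the observed.
* Ties count against rejection, with a 1e-9 absolute tolerance on the
  dimensionless statistic. This matters in a genuinely degenerate corner:
  a counterbalance draw can place one location exactly on the accented cue
  positions, making *every* stratum single-class; the null is then constant
  and equal to the observed value up to floating-point summation order, and
  without the tolerance such participants would be flagged spuriously.
  With it they get p = 1, as they should.
* Under an exchangeable null the flag probability is 100/(n_iter+1) ≈ 5%;
  the type-I calibration in the acceptance tests (500 simulated null
  participants, 2 000 iterations) checks 5% ± 1.5%. Note that a *true*
  null requires both a zero accent-effect mixture and an
  accented-variability ratio of 1 — unequal class variances with unequal
  class sizes violate exchangeability and measurably inflate the rate.
* BH-FDR adjustment is delegated to `statsmodels`
  (`multipletests(method="fdr_bh")`) behind `bh_fdr`, and cross-checked in
  the tests against a literal step-up implementation.

## Contrasts

Block contrasts are per-participant mean differences (test minus
preceding learning block) with t-based 95% CIs; the boundary analysis uses
the final/first `n_cycles` × 12 *scheduled* trials of each block,
intersected with retained trials, so exclusions shrink a window rather
than shifting it. The standardised disruption score divides the mean
difference by the participant's grand-mean RT; the default sign convention
is positive = slowing (the literal learning-minus-test subtraction is
available via `sign="raw"`). Correlation CIs use the Fisher z
transformation. The accent-variability contrast compares mean log-SD of
accented vs unaccented cells with a paired t-test per metre condition — a
descriptive stand-in for the mixed model used confirmatorily in the
original analysis, which is out of scope here (as are Satterthwaite
degrees of freedom, Tukey HSD and semi-partial R²; the pipeline exports
tidy tables suitable for such fits).

Because the generator's learning slope continues through the test blocks,
the model-implied expectation of the block-9-minus-8 contrast is
`disruption − slope` (≈ 11.7 ms at defaults); the parameter-recovery
harness checks CI coverage of that quantity, and slope recovery regresses
per-block means over learning blocks only.

## Problem sizes and reproducibility

All randomness flows from a single seed through named
`numpy.random.SeedSequence` substreams; identical configuration and seed
give byte-identical CSV outputs, each stamped with the configuration hash.
The test suite and the acceptance script run the Monte-Carlo checks at the
sizes stated above (type-I: 500 participants × 2 000 iterations; power: 40
participants × 720 trials; recovery: 100 runs × 100 participants), which
we consider large enough for the binomial error bars they are judged
against while keeping a full run in the minutes range on one CPU.

## Known limitations

* The permutation test has no power for designs where accent is fully
  confounded with one response key (p = 1 by construction); cohort-level
  flagged shares are correspondingly diluted when such variants are drawn.
* The generator's disruption magnitudes for the test blocks are loosely
  calibrated — only group-level boundary summaries were reported for the
  original data — and should be treated as illustrative.
* `exclude_anticipators` interprets "more than 10% in multiple blocks" as
  ≥ 2 blocks (smallest plural); the threshold and block count are
  configurable.
* Whether incorrect presses under 50 ms should be discarded before or with
  the correctness filter is ambiguous in the source description; they are
  counted as ordinary errors here (the anticipatory rule names the correct
  key only).
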