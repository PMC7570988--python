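# sleepkit

Objective sleep-quality analysis from a single EEG channel and wrist
actigraphy: unsupervised hidden-Markov-model sleep staging, hypnogram-derived
quality indices, Sadeh sleep/wake scoring, per-stage evaluation metrics and
the paired nonparametric statistics of a small crossover sleep study.

## Who this is for

Sleep researchers who record overnight single-channel EEG (no full
polysomnography) and per-minute actigraphy counts, and want objective
per-night summaries — stage durations, REM-to-non-REM ratio, stage-shift
index, sleep efficiency — plus a statistics layer to compare sleeping
conditions within subjects.

## The model

A night is scored in 30-s epochs. Each epoch is summarized by its relative
power in four stage-associated frequency bands (complex Morlet wavelet
filtering, per-epoch powers normalized to sum to 1):

| stage | band |
|---|---|
| Wake | 35–50 Hz |
| REM | 20–30 Hz |
| Light (N1+N2 / S1+S2) | 10.15–15.75 Hz |
| Deep (SWS, N3 / S3+S4) | 1–3 Hz |

The epoch feature sequence **x**₁…**x**_T is modeled by a 4-state HMM with
diagonal-Gaussian emissions. Initialization encodes sleep physiology: the
initial distribution π₀ = (1, 0, 0, 0) (the night starts awake), a prior
transition matrix Q₀ with no direct Wake→Deep or REM→Deep jumps, emission
means μ₀ with 0.7 in each stage's own band and 0.1 elsewhere, and unit
emission standard deviations. All of (π, Q, μ, σ) are then re-estimated per
recording by Baum–Welch EM (log-space forward–backward, variance floor
1e-4, tol 1e-6 on the log-likelihood, ≤100 iterations), and the hypnogram is
the Viterbi path. Stage identity is anchored only by the diagonal structure
of μ₀.

From a hypnogram (or any binary sleep/wake sequence) the package computes

* **RNR** = 100 × REM minutes / (Light + Deep minutes),
* **SSI** = stage shifts per hour of total sleep time,
* **SE, TST, SOL, WASO** — sleep efficiency, total sleep time, sleep-onset
  latency, wake after sleep onset,

per-stage one-vs-rest accuracy/precision/recall/F1 against a reference
hypnogram, the Sadeh regression for actigraphy sleep/wake scoring, exact
paired Wilcoxon signed-rank condition comparisons, a PSQI > 5 poor/good
sleeper split and Spearman rank correlations. A synthetic-data module
generates hypnograms (stage Markov chains), band-structured EEG, Poisson
actigraphy counts and whole crossover cohorts with exactly known injected
effects, so the entire pipeline is testable end to end without any
recordings.

## Worked example

```python
import numpy as np
from sleepkit import (GeneratorSpec, sample_hypnogram, synthesize_eeg,
                      score_sleep, hypnogram_indices, evaluation_report)

spec = GeneratorSpec(seed=7, n_epochs=840)          # one 7-h synthetic night
truth = sample_hypnogram(spec)                      # ground-truth hypnogram
eeg = synthesize_eeg(truth, spec)                   # 100 Hz single-channel EEG

decoded = score_sleep(eeg, sampling_rate_hz=100.0)  # unsupervised staging
idx = hypnogram_indices(decoded)

print(f"accuracy vs truth: {np.mean(decoded.stages == truth.stages):.3f}")
print(f"TST {idx.tst_min:.1f} min  SE {100*idx.se:.1f} %  RNR {idx.rnr:.2f} %  SSI {idx.ssi:.2f}/h")
print(evaluation_report(decoded, truth).round(2))
```

prints

```
accuracy vs truth: 0.998
TST 338.5 min  SE 80.6 %  RNR 83.97 %  SSI 33.68/h
            Wake     Rem   Light    Deep
accuracy   100.0   99.88   99.76   99.88
precision  100.0   99.68  100.00   99.43
recall     100.0  100.00   98.97  100.00
f1         100.0   99.84   99.48   99.71
```

The decoded hypnogram recovers 99.8% of the ground-truth epochs; TST/SE
describe how much of the night was spent asleep, RNR the share of REM
relative to non-REM sleep, and SSI how fragmented the night was. The table
is the per-stage one-vs-rest evaluation against the known truth.

A command-line interface wraps the same pipeline for files on disk:

```bash
sleepkit score night.edf --channel "EEG Fpz-Cz" --hypnogram-out hyp.csv --indices-out idx.csv
sleepkit --seed 1 simulate study_dir --subjects 10
sleepkit study study_dir/records.csv
```

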