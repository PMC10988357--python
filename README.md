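# vocalmod

Peri-vocalization spike-train analysis for rodent electrophysiology:
characterizing how motor-cortex neurons modulate their firing around
ultrasonic vocalizations (USVs), and identifying projection neurons by
optogenetic tagging.

Rats emit 50 kHz-band USVs in bouts of short syllables. Given sorted spike
trains and either USV audio or pre-detected syllable tables, `vocalmod`

- **segments syllables** from audio with a spectrogram threshold (band
  20–120 kHz, minimum duration 5 ms, minimum gap 20 ms), splits them into
  *first calls* (bout onsets, >1 s after the previous syllable) vs
  *subsequent calls*, and types them *flat* vs *frequency-modulated* (FM)
  at a 15 kHz frequency-extent boundary;
- **tests responsiveness** per unit with four two-sided Wilcoxon rank-sum
  tests comparing pre-call baseline firing (−1.0 to −0.5 s before
  first-call onsets) against peri-call windows (±0.5/±0.25 s), Bonferroni-
  corrected (×4, responsive iff any adjusted *p* < 0.05);
- **normalizes responses with auROC**: for each 50 ms bin in ±1 s around
  onsets, the area under the ROC curve comparing the across-trial rate
  distribution to the baseline distribution — 0.5 = no modulation, >0.5
  excitation, <0.5 inhibition — and builds a 25-dimensional response
  vector (15 first-call bins over −0.5..+0.25 s ⧺ 10 subsequent-call bins
  over −0.25..+0.25 s);
- **classifies response types** without supervision: PCA (3 PCs) +
  log₁₀ baseline rate, z-scored, embedded with t-SNE, and segmented by a
  watershed transform of the Gaussian-smoothed 2-D unit density; basins are
  named E (excitatory), I (inhibitory) or O (other);
- **tags projection neurons** with the stimulus-associated spike-latency
  test (SALT): first-spike latency histograms in the 10 ms post-pulse
  window vs 10 ms baseline epochs (−150..0 ms), compared by √Jensen–Shannon
  distance; light-responsive iff rate increase ∧ SALT *p* < 0.01 ∧
  evoked/spontaneous waveform correlation *r* > 0.9;
- **compares groups**: anterior/posterior split at AP +1.5 mm, Fisher's
  exact tests with Woolf (log-normal) odds-ratio CIs on response-type
  count tables, and permutation tests of median differences with bootstrap
  percentile CIs.

A synthetic-data module plants known ground truth for every stage —
bout-structured call streams (within-bout inter-onset intervals
366 ± 64 ms, inter-bout gaps >1 s), audio, inhomogeneous-Poisson spike
trains with multiplicative peri-call gain kernels (7 responsive types plus
nonresponders), and tagging sessions (10 trains × 10 pulses, 10 ms at
5 Hz) — so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from vocalmod import synth, responses

stream = synth.gen_usv_stream(duration=1200.0, seed=11)   # ~120 first calls
profile = synth.default_profiles(baseline_rate=5.0)["E1"]  # sustained excitation
spikes = synth.gen_spike_train(profile, stream, stream.duration, seed=2)

prof = responses.analyze_unit("demo", spikes,
                              stream.first_onsets, stream.subsequent_onsets)
print(prof.responsive)                      # True
print(round(min(prof.window_pvalues), 4))   # 0.0  (Bonferroni-adjusted)
print(round(prof.vector25[10:15].mean(), 2))  # 0.84
```

The unit is flagged responsive (smallest adjusted *p* ≈ 0 against the
baseline), and the post-onset entries of its response vector average an
auROC of 0.84 — the across-trial firing in the 0.25 s after first-call
onsets almost always exceeds baseline firing, as planted (gain 3.0 for
0.5 s after onset).

The `examples/` scripts walk one capability each (segmentation round-trip,
response typing, optotagging, group statistics) and print annotated
numbers; `vocalmod --help` lists the equivalent command-line entry points,
and `vocalmod run --config cfg.yaml` drives the full pipeline from a YAML
config.

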