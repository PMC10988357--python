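# Methods

This note documents the models and procedures implemented in `vocalmod`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducing results.

## The analysis in one paragraph

Sorted motor-cortex units are screened for quality (≥100 spikes, clean
1 ms refractory period), their firing is aligned to ultrasonic-vocalization
(USV) syllable onsets — separately for *first calls* (bout onsets, >1 s
after the previous syllable) and *subsequent calls* — and each unit is
tested for peri-call modulation against its pre-call baseline. Modulation
is normalized with auROC so that units with very different firing rates
become comparable, responsive units are clustered into response types
without supervision, and projection neurons are identified in separate
sessions by short-latency light-evoked spiking. Group-level questions
(does the responsive fraction differ between anterior and posterior motor
cortex?) are answered with contingency statistics on response-type count
tables and permutation tests on continuous response measures.

## Syllable segmentation

The segmenter computes a short-time magnitude spectrogram (Hann window,
512 samples with 75% overlap at the 250 kHz default rate → ~2 ms windows,
~0.5 ms steps), restricts to the 20–120 kHz band, and thresholds the
per-frame in-band **peak log₁₀-magnitude** at

    median + 5 × 1.4826 × MAD

computed over all frames (noise-floor statistics; the MAD-based robust SD
ignores the vocal minority). Above-threshold runs separated by less than
20 ms are merged, then runs shorter than 5 ms are discarded — in that
order, so a syllable briefly interrupted by a formant gap stays one
syllable. fmin/fmax are the extent of the per-frame peak-frequency track.

Two choices deserve explanation:

- **Log magnitude.** The per-frame peak of a few hundred noise bins has a
  heavy right tail on a linear scale, so "k robust SDs above the median"
  sits at a much lower quantile than the Gaussian intuition suggests. On
  the log scale the noise statistic is near-Gaussian and the threshold
  behaves as expected.
- **5 robust SDs, not 3.** Because merging precedes the duration filter, a
  single spurious noise frame within 20 ms of a real syllable extends or
  chains detections; the per-frame false rate must therefore be far below
  1/(merge gap ≈ 39 frames). At 5 robust SDs the measured noise exceedance
  is zero in minutes of synthetic audio while tonal syllables at the
  default SNR sit ~40 robust SDs above the floor, so the operating point is
  insensitive to the exact value. Real USVSEG-style detectors achieve the
  same end with multitaper spectral flattening; this package uses the
  simpler statistic and documents it.

First/subsequent splitting is the strict rule: the first onset of a record
is "first", and any onset more than 1.0 s after its predecessor is "first";
an inter-onset interval of exactly 1.0 s is "subsequent". Call typing is
flat iff (fmax − fmin) < 15 kHz; an extent of exactly 15 kHz is FM.

There is no interactive curation step; the detection threshold stands in
for it. Exact detection counts on real recordings are not claimed.

## Unit quality control and cell typing

A unit passes QC with ≥100 spikes and at most 0.5% of inter-spike
intervals below 1.0 ms (the tolerated violation fraction is a package
default; an absolute zero-violation rule would be hostage to single
artifacts). Spike width is the trough-to-peak duration of the mean
waveform on the channel with the largest peak-to-trough amplitude; if the
dominant deflection is positive the waveform is inverted first, so
polarity conventions do not flip the measurement. Widths are clustered
with k-means (k=2, 10 restarts, fixed seed); the narrow-mean cluster is
labeled putative interneuron, the wide putative pyramidal.

## Responsiveness battery

Per unit, four two-sided Wilcoxon rank-sum tests compare baseline firing
with peri-call firing:

| window | event kind |
|---|---|
| [−0.5, 0) s | first calls |
| [0, +0.25) s | first calls |
| [−0.25, 0) s | subsequent calls |
| [0, +0.25) s | subsequent calls |

Raw p-values are multiplied by 4 (capped at 1); the unit is responsive iff
any adjusted p < 0.05. The baseline period is always [−1.0, −0.5) s before
**first-call** onsets (subsequent calls have no quiet pre-window of their
own).

**Baseline sample construction.** A rank-sum test is only calibrated when
the two samples share a distribution under the null. Per-trial *rates*
over a 0.5 s window and over a 0.25 s window do not: for Poisson counts
they live on different lattices with different variances even at equal
means (the theoretical null auROC between them is 0.474 at 5 spikes/s, and
the measured per-window false-positive rate rises to ~5% at the 1.25%
Bonferroni level). The battery therefore draws its baseline sample from
sub-windows of the baseline period **matched in length to the test
window**: the single 0.5 s window for the 0.5 s test, and the two 0.25 s
halves per trial for the 0.25 s tests. This uses only the stated baseline
period and makes the null exact; the type-I calibration test verifies a
family-wise false-positive rate within the Bonferroni guarantee on 1,000
null units.

**Rank-sum implementation.** Exact enumeration of all group splits (with
midranks, so ties are handled exactly) when both samples have ≤8
observations; otherwise the tie-corrected normal approximation with
continuity correction. The exact path is verified against an independent
enumeration oracle in the tests.

## auROC normalization and the response vector

Spikes are binned at 50 ms in ±1 s around onsets (40 bins), per-trial
rates are smoothed with a centered 5-bin moving average (shrinking,
renormalized window at the edges), and each bin's across-trial rate
distribution is compared with the per-trial 0.5 s baseline rates by

    auROC = P(bin rate > baseline rate) + ½ P(equal)

over all trial pairs (the Mann–Whitney identity, computed with midranks).
0.5 means no modulation; excitation pushes above, inhibition below. The
response-pattern vector concatenates the 15 first-call bins covering
[−0.5, +0.25) s with the 10 subsequent-call bins covering [−0.25, +0.25) s
— 25 dimensions.

**Smoothing order.** Whether the 5-bin average is applied to per-trial
rates before the ROC or to the auROC time course afterwards is genuinely
ambiguous; the default smooths per-trial rates first (keeping a
distribution per bin), and `auroc_timecourse(..., use_smoothed=False)`
selects the other order.

Note that smoothing makes neighboring auROC bins correlated, and the
baseline-window-length mismatch discussed above biases null auROC values
slightly below 0.5 (≈0.47–0.48 at 5 spikes/s). This bias is common to all
units and far below the ±0.05 naming threshold, so it does not affect
classification; it is *not* corrected, matching the stated auROC
definition.

Call-type discrimination is a single rank-sum test (p < 0.05) on per-trial
rates in ±0.25 s around flat-first vs FM-first call onsets — equal window
lengths, so no baseline-matching issue arises.

## Unsupervised response typing

Features are PC1–3 of the 25-dim vectors of all responsive units plus
log₁₀ baseline rate (floored at 0.01 spikes/s), z-scored. t-SNE
(perplexity 30, 1,000 iterations, PCA initialization, fixed seed) embeds
the features in 2-D; a 100×100 histogram over the 5%-padded bounding box
is smoothed with a Gaussian (σ = 2 bins) and segmented by a watershed of
the negated density.

**Watershed markers.** Raw regional maxima of a sparse smoothed histogram
over-segment badly (sampling noise seeds basins). Markers are therefore
the regional maxima of a *coarser* smoothing (2× σ) with prominence at
least 10% of its peak (h-maxima); basin boundaries still follow the finer
density. On planted populations this yields one basin per recoverable
type, stable (±0) across t-SNE seeds 0–4, while remaining faithful to the
histogram → smooth → watershed recipe.

Basins are named from their mean response vector: E if the mean post-onset
auROC exceeds 0.5 + δ, I if below 0.5 − δ (δ = 0.05), else O; E/I
subtypes are numbered by decreasing response duration (count of post-onset
bins deviating by more than δ), so sustained types come first. The naming
is a labeling convenience — no claim is made that the discovered basins
match any particular published type boundaries.

## Optogenetic tagging (SALT)

For each pulse, first-spike latencies are collected in 1 ms bins within
the 10 ms test window after light onset and within each of the 15 ten-ms
baseline epochs tiling [−150, 0) ms (plus a no-spike bin, so each histogram
sums to the pulse count). Histograms are compared with the square root of
the Jensen–Shannon divergence (a metric; 0·ln 0 = 0 convention, and the
½-mixture keeps every term finite). The null set is the 105 pairwise
distances among the baseline epochs; the test statistic m* is the median
distance from the test histogram to the baseline histograms;

    salt_p = (#{null ≥ m*} + 1) / 106,    salt_info = m* − median(null).

The smallest attainable p is 1/106 ≈ 0.0094, which is what a reliably
locked unit reaches, and the rank-based construction is conservative under
the null (verified on 500 simulated untagged units). A unit is
light-responsive iff its post-pulse/pre-pulse rate ratio exceeds 1, salt_p
< 0.01, and the Pearson correlation between evoked and spontaneous mean
waveforms (samples concatenated across the 4 tetrode channels) exceeds
0.9. Pulses from all 10 trains are pooled (100 reference events).

## Group statistics

Recording sites are split anterior/posterior at AP = +1.5 mm (the boundary
itself is posterior; configurable). Count tables (region-part × response
type) collapse to 2×2 tables — responsive vs nonresponsive among recorded
units, or one response class vs the other responsive units — tested with
Fisher's exact test. Effect sizes are sample odds ratios ad/bc with Woolf
log-normal CIs, exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); tables with a zero cell
get the Haldane +0.5 correction on every cell. CIs are emitted uncorrected
even where the accompanying p-values carry a Bonferroni factor.

The permutation test for a median difference enumerates all label splits
exhaustively when there are ≤20,000 of them (exact p = fraction of splits
at least as extreme) and otherwise samples 5,000 splits with the add-one
correction; the CI is a 5,000-resample bootstrap percentile interval of
the median difference. All resampling is seeded.

## The synthetic-data generator

The generator emulates the study conditions, not vocal acoustics:

- **Call streams.** Bout starts arrive with exponential spacing scaled to
  the bout rate (default 6 bouts/min); each bout holds a geometric number
  of syllables (mean 4, minimum 1); within-bout inter-onset intervals are
  Gamma with mean 366 ms and SD 64 ms (moment-matched; a Normal would go
  negative), clipped below the 1 s bout gap; inter-bout silent gaps always
  exceed 1 s, so the first/subsequent splitter recovers the planted bout
  starts exactly. Syllable durations are Gamma (mean 50 ms, SD 15 ms) —
  a placeholder, as duration and bout-length distributions are not
  constrained by data. Flat syllables get a 3–10 kHz extent, FM 20–40 kHz,
  centers 45–75 kHz.
- **Audio.** Flat syllables are pure tones, FM syllables linear chirps,
  amplitude 0.5 over white noise (σ = 0.02 → ~25 dB SNR), with 2 ms cosine
  edge tapers, rendered at 250 kHz (desk-scale; configurable). No harmonic
  stacks, no amplitude modulation, no broadband noise calls.
- **Spike trains.** Inhomogeneous Poisson by thinning; the rate is
  baseline × the product of active rectangular gain kernels (E1: gain 3 on
  (0, 0.5] s; E2: 3 on (0, 0.1]; I1: 0.2 on (0, 0.5]; I2: 0.2 on
  (0, 0.15]; I3: 0.2 on (−0.25, +0.25]; I4: 0.2 on (−0.5, 0]; O: 1.2 on
  (0, 0.05]; NR: flat), applied to both first and subsequent calls.
  Overlapping kernels multiply; the thinning bound accounts for the
  maximum kernel overlap actually present in the event stream. Type O is
  deliberately weak: such units are rarely flagged responsive and mostly
  drop out before clustering, which is why classification recovery is
  scored over the units that reach the classifier.
- **Tagging sessions.** 10 trains × 10 pulses at 5 Hz, 10 s intertrain
  intervals. Tagged units add one evoked spike per pulse with probability
  0.8 at latency ~ Normal(3, 1) ms; untagged units are background only.
  Mean waveforms are a fixed biphasic 4-channel template plus estimation
  noise shrinking as 1/√n_spikes — so evoked and spontaneous waveforms of
  the *same* unit always correlate highly, and the waveform criterion
  models sorting contamination rather than discriminating tagged from
  untagged here.

Because the generator is Poisson with stationary baselines, passing tests
demonstrate calibration and recovery under ideal statistical conditions;
they do not speak to bursting, rate drift, movement covariates, or
correlated noise in real recordings.

## Problem sizes and determinism

The validation suite uses: 1,000 null units (on a stream with ≥100 first
and ≥300 subsequent calls, i.e. 20 min of simulated session) for type-I
calibration; 500 untagged + 200 tagged sessions for the tagging criteria;
490 units (7 responsive types × 70) for classification recovery; and three
40 s audio clips for segmentation recall. These sizes give binomial
standard errors well under the margins being asserted while the whole
suite completes in well under a minute of compute. Every random stage
takes an explicit integer seed (numpy `default_rng`); reruns are
bit-identical, and the pipeline's CSV outputs are byte-identical across
reruns of the same config.

## Known limitations

- The segmenter is a threshold detector: no spectral flattening, no
  harmonic handling, no overlap resolution; its false-positive behaviour
  on real colony noise is untested.
- The responsiveness battery inherits the baseline-window design: units
  with strong *pre-first-call* modulation slower than 0.5 s would
  contaminate their own baseline.
- t-SNE/watershed hyperparameters are package defaults; cluster counts on
  real data depend on them and no particular count is claimed.
- The SALT information measure is reported as the median-distance excess
  over the null median, a monotone surrogate for the cited method's
  information difference, adequate for ranking but not for comparing
  absolute values across studies.
- Per-animal (hierarchical) structure is ignored throughout; all
  contingency and permutation tests treat units as exchangeable.
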