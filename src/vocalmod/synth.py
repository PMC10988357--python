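"""Synthetic data generation with planted ground truth.

Emulates the study conditions of a rat ultrasonic-vocalization (USV)
recording session: 50 kHz-band call bouts, baseline-Poisson cortical units
whose firing is multiplicatively modulated around call onsets, and
optogenetic-tagging sessions with short-latency light-evoked spikes.

Every generator takes an explicit integer seed and is bit-reproducible for
a fixed seed (determinism contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UsvGroundTruth",
    "GainSegment",
    "ResponseProfileSpec",
    "TaggingSpec",
    "default_profiles",
    "RESPONSE_TYPES",
    "gen_usv_stream",
    "gen_audio",
    "gen_spike_train",
    "gen_tagging_session",
    "waveform_template",
]

#: labels of the planted response types (seven responsive + nonresponder)
RESPONSE_TYPES = ("E1", "E2", "I1", "I2", "I3", "I4", "O", "NR")

SYLLABLE_COLUMNS = ["onset_s", "offset_s", "fmin_khz", "fmax_khz", "bout_id"]


@dataclass
class UsvGroundTruth:
    """Planted USV syllable stream.

    ``syllables`` is a DataFrame with columns onset_s, offset_s, fmin_khz,
    fmax_khz, bout_id; onsets strictly increasing. ``bout_gap`` is the
    minimum silent gap (s) separating bouts; the first syllable of each bout
    is, by construction, the first call under the >bout_gap splitting rule.
    """

    syllables: pd.DataFrame
    duration: float
    bout_gap: float = 1.0
    isi_mean: float = 0.366
    isi_sd: float = 0.064

    @property
    def onsets(self) -> np.ndarray:
        return self.syllables["onset_s"].to_numpy()

    @property
    def is_first(self) -> np.ndarray:
        """True for the first syllable of each bout (planted labels)."""
        bout = self.syllables["bout_id"].to_numpy()
        flag = np.ones(len(bout), dtype=bool)
        flag[1:] = bout[1:] != bout[:-1]
        return flag

    @property
    def first_onsets(self) -> np.ndarray:
        return self.onsets[self.is_first]

    @property
    def subsequent_onsets(self) -> np.ndarray:
        return self.onsets[~self.is_first]

    @property
    def is_flat(self) -> np.ndarray:
        rng = self.syllables["fmax_khz"] - self.syllables["fmin_khz"]
        return (rng < 15.0).to_numpy()

    def to_csv(self, path) -> None:
        self.syllables.to_csv(path, index=False)


@dataclass(frozen=True)
class GainSegment:
    """Multiplicative rate gain ``gain`` active for t - onset in (start, stop]."""

    start: float
    stop: float
    gain: float


@dataclass(frozen=True)
class ResponseProfileSpec:
    """Planted peri-call modulation of one unit.

    The instantaneous rate is ``baseline_rate`` times the product of the
    gains of all active segments (first-call and subsequent-call kernels
    multiply when they overlap; the product is always >= 0).
    """

    type_label: str
    baseline_rate: float = 5.0
    first_kernel: tuple[GainSegment, ...] = ()
    subsequent_kernel: tuple[GainSegment, ...] = ()

    def __post_init__(self):
        for seg in self.first_kernel + self.subsequent_kernel:
            if seg.gain < 0:
                raise ValueError("gain kernels must be non-negative")
            if seg.stop <= seg.start:
                raise ValueError("gain segment must have stop > start")


# Rectangular kernels emulating the empirical shapes of the seven response
# types: E1 sustained / E2 transient excitation after onset; I1-I4 troughs
# of differing onset and duration; O a weak single-bin bump; NR flat.
_KERNELS: dict[str, tuple[GainSegment, ...]] = {
    "E1": (GainSegment(0.0, 0.5, 3.0),),
    "E2": (GainSegment(0.0, 0.1, 3.0),),
    "I1": (GainSegment(0.0, 0.5, 0.2),),
    "I2": (GainSegment(0.0, 0.15, 0.2),),
    "I3": (GainSegment(-0.25, 0.25, 0.2),),
    "I4": (GainSegment(-0.5, 0.0, 0.2),),
    "O": (GainSegment(0.0, 0.05, 1.2),),
    "NR": (),
}


def default_profiles(baseline_rate: float = 5.0) -> dict[str, ResponseProfileSpec]:
    """The eight planted profile specs (same kernel on first and subsequent calls)."""
    return {
        label: ResponseProfileSpec(
            type_label=label,
            baseline_rate=baseline_rate,
            first_kernel=_KERNELS[label],
            subsequent_kernel=_KERNELS[label],
        )
        for label in RESPONSE_TYPES
    }


@dataclass(frozen=True)
class TaggingSpec:
    """Optogenetic tagging protocol: trains of brief light pulses.

    Defaults mirror the recording protocol: 10 trains of 10 pulses,
    10 ms pulse duration at 5 Hz, 10 s intertrain interval.
    """

    latency_mean: float = 3.0  # ms
    latency_jitter_sd: float = 1.0  # ms
    reliability: float = 0.8  # evoked-spike probability per pulse
    n_trains: int = 10
    pulses_per_train: int = 10
    pulse_duration: float = 10.0  # ms
    pulse_rate: float = 5.0  # Hz
    intertrain_interval: float = 10.0  # s

    def __post_init__(self):
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must be in [0, 1]")
        if self.n_trains < 1 or self.pulses_per_train < 1:
            raise ValueError("need at least one train and one pulse")

    def pulse_times(self, t0: float = 1.0) -> np.ndarray:
        period = 1.0 / self.pulse_rate
        within = np.arange(self.pulses_per_train) * period
        starts = t0 + np.arange(self.n_trains) * (
            self.intertrain_interval + (self.pulses_per_train - 1) * period
        )
        return (starts[:, None] + within[None, :]).ravel()


def gen_usv_stream(
    duration: float,
    bout_rate: float = 6.0,
    syllables_per_bout_mean: float = 4.0,
    isi_mean: float = 0.366,
    isi_sd: float = 0.064,
    flat_fraction: float = 0.5,
    seed: int = 0,
    bout_gap: float = 1.0,
    syllable_dur_mean: float = 0.05,
    syllable_dur_sd: float = 0.015,
    t_start: float = 1.5,
) -> UsvGroundTruth:
    """Generate a bout-structured syllable stream.

    Bouts hold a geometric number of syllables (mean ``syllables_per_bout_mean``,
    minimum 1); within-bout inter-onset intervals are Gamma-distributed with
    the given mean and SD (positively supported, matched moments) and clipped
    below ``bout_gap``; silent gaps between bouts always exceed ``bout_gap``.
    Flat syllables get a frequency extent < 15 kHz, frequency-modulated
    syllables > 15 kHz.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if bout_rate < 0:
        raise ValueError("bout_rate must be non-negative")
    if not isi_mean > isi_sd >= 0:
        raise ValueError("need isi_mean > isi_sd >= 0")
    if not 0.0 <= flat_fraction <= 1.0:
        raise ValueError("flat_fraction must be in [0, 1]")

    rows: list[tuple[float, float, float, float, int]] = []
    if bout_rate == 0:
        return UsvGroundTruth(
            pd.DataFrame(rows, columns=SYLLABLE_COLUMNS),
            duration=duration, bout_gap=bout_gap,
            isi_mean=isi_mean, isi_sd=isi_sd,
        )

    rng = np.random.default_rng(seed)
    # spacing of bout starts: silent gap is bout_gap plus an exponential tail
    # sized so bouts arrive at roughly bout_rate per minute
    cycle = 60.0 / bout_rate
    mean_span = (syllables_per_bout_mean - 1.0) * isi_mean
    gap_scale = max(0.25, cycle - mean_span - bout_gap)

    shape_isi = (isi_mean / isi_sd) ** 2 if isi_sd > 0 else None
    scale_isi = isi_sd**2 / isi_mean if isi_sd > 0 else None
    shape_dur = (syllable_dur_mean / syllable_dur_sd) ** 2
    scale_dur = syllable_dur_sd**2 / syllable_dur_mean

    t = t_start + rng.exponential(gap_scale)
    bout_id = 0
    while True:
        n_syl = rng.geometric(1.0 / syllables_per_bout_mean)
        onsets = [t]
        for _ in range(n_syl - 1):
            if shape_isi is None:
                isi = isi_mean
            else:
                isi = float(rng.gamma(shape_isi, scale_isi))
            isi = float(np.clip(isi, 0.05, bout_gap * 0.98))
            onsets.append(onsets[-1] + isi)
        durs = np.clip(rng.gamma(shape_dur, scale_dur, size=n_syl), 0.006, None)
        # keep syllables disjoint: duration below the gap to the next onset
        for i in range(n_syl - 1):
            durs[i] = min(durs[i], 0.8 * (onsets[i + 1] - onsets[i]))
        durs[-1] = min(durs[-1], 0.3)
        if onsets[-1] + durs[-1] > duration:
            break
        for onset, dur in zip(onsets, durs):
            if rng.random() < flat_fraction:
                extent = rng.uniform(3.0, 10.0)
            else:
                extent = rng.uniform(20.0, 40.0)
            center = rng.uniform(45.0, 75.0)
            fmin = max(20.0, center - extent / 2.0)
            fmax = min(120.0, fmin + extent)
            rows.append((onset, onset + dur, fmin, fmax, bout_id))
        t = onsets[-1] + durs[-1] + bout_gap + 1e-3 + rng.exponential(gap_scale)
        bout_id += 1

    table = pd.DataFrame(rows, columns=SYLLABLE_COLUMNS)
    table["bout_id"] = table["bout_id"].astype(int)
    return UsvGroundTruth(
        table, duration=duration, bout_gap=bout_gap,
        isi_mean=isi_mean, isi_sd=isi_sd,
    )


def gen_audio(
    ground_truth: UsvGroundTruth,
    sample_rate: float = 250_000.0,
    noise_sd: float = 0.02,
    amplitude: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize an audio waveform from a syllable stream.

    Flat syllables are rendered as pure tones at the syllable's center
    frequency, FM syllables as linear chirps fmin -> fmax, both over white
    Gaussian noise. Syllable edges carry a short cosine taper to avoid
    spectral splatter.
    """
    fs = float(sample_rate)
    syl = ground_truth.syllables
    if len(syl) and fs < 2.0 * syl["fmax_khz"].max() * 1e3:
        raise ValueError("sample_rate violates Nyquist for the highest syllable frequency")
    rng = np.random.default_rng(seed)
    n = int(round(ground_truth.duration * fs))
    wave = rng.normal(0.0, noise_sd, size=n)
    flat = ground_truth.is_flat
    for i, row in enumerate(syl.itertuples(index=False)):
        i0 = int(round(row.onset_s * fs))
        i1 = min(n, int(round(row.offset_s * fs)))
        if i1 <= i0:
            continue
        t = np.arange(i1 - i0) / fs
        if flat[i]:
            f0 = 0.5 * (row.fmin_khz + row.fmax_khz) * 1e3
            phase = 2.0 * np.pi * f0 * t
        else:
            f_lo = row.fmin_khz * 1e3
            f_hi = row.fmax_khz * 1e3
            sweep = (f_hi - f_lo) / t[-1] if t[-1] > 0 else 0.0
            phase = 2.0 * np.pi * (f_lo * t + 0.5 * sweep * t**2)
        tone = amplitude * np.sin(phase)
        taper = min(len(t) // 4, int(0.002 * fs))
        if taper > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(taper) / taper))
            tone[:taper] *= ramp
            tone[-taper:] *= ramp[::-1]
        wave[i0:i1] += tone
    return wave


def _max_overlap(onsets: np.ndarray, span: float) -> int:
    """Largest number of onsets falling inside any window of length span."""
    if len(onsets) == 0:
        return 0
    k = 1
    while k < len(onsets) and np.any(onsets[k:] - onsets[:-k] < span):
        k += 1
    return k


def _gain_at(times: np.ndarray, spec: ResponseProfileSpec,
             first_onsets: np.ndarray, sub_onsets: np.ndarray) -> np.ndarray:
    g = np.ones_like(times)
    for onsets, kernel in ((first_onsets, spec.first_kernel),
                           (sub_onsets, spec.subsequent_kernel)):
        if len(onsets) == 0:
            continue
        for seg in kernel:
            lo = np.searchsorted(onsets, times - seg.stop)
            hi = np.searchsorted(onsets, times - seg.start)
            k = hi - lo
            if seg.gain == 0.0:
                g[k > 0] = 0.0
            else:
                g *= seg.gain ** k
    return g


def gen_spike_train(
    spec: ResponseProfileSpec,
    events: UsvGroundTruth,
    duration: float,
    seed: int = 0,
) -> np.ndarray:
    """Sample an inhomogeneous-Poisson spike train (thinning algorithm).

    The rate is ``baseline_rate`` multiplied by the product of the gains of
    every active kernel segment; overlapping kernels multiply and the rate
    never goes negative.
    """
    if spec.baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    rng = np.random.default_rng(seed)
    first = events.first_onsets
    sub = events.subsequent_onsets

    gmax = 1.0
    for onsets, kernel in ((first, spec.first_kernel), (sub, spec.subsequent_kernel)):
        for seg in kernel:
            if seg.gain > 1.0:
                k = _max_overlap(onsets, seg.stop - seg.start)
                gmax *= seg.gain ** k
    rate_max = spec.baseline_rate * gmax

    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    accept_p = spec.baseline_rate * _gain_at(cand, spec, first, sub) / rate_max
    keep = rng.random(n_cand) < accept_p
    return cand[keep]


def waveform_template(n_samples: int = 32, fs_wf: float = 30_000.0) -> np.ndarray:
    """Canonical biphasic extracellular waveform on 4 tetrode channels (uV).

    Trough at ~1/3 of the window followed by a slower positive peak, scaled
    across channels as on a tetrode where the unit is closest to channel 1.
    """
    t = np.arange(n_samples) / fs_wf * 1e3  # ms
    trough_t, peak_t = 0.35, 0.75
    shape = -np.exp(-0.5 * ((t - trough_t) / 0.08) ** 2) \
        + 0.45 * np.exp(-0.5 * ((t - peak_t) / 0.18) ** 2)
    chan_scale = np.array([1.0, 0.8, 0.5, 0.3])
    return 100.0 * chan_scale[:, None] * shape[None, :]


def gen_tagging_session(
    spec: TaggingSpec,
    background_rate: float = 5.0,
    tagged: bool = True,
    seed: int = 0,
    waveform_noise_sd: float = 4.0,
):
    """Simulate one optogenetic-tagging session for a single unit.

    Returns ``(pulse_times, spike_times, waveforms)`` where waveforms is a
    dict with mean 'evoked' and 'spontaneous' 4-channel waveforms. A tagged
    unit fires one evoked spike per pulse with probability ``reliability``
    at latency ~ Normal(latency_mean, latency_jitter_sd) ms; an untagged
    unit carries only its background Poisson spikes. Mean waveforms carry
    estimation noise shrinking with the number of contributing spikes.
    """
    if background_rate < 0:
        raise ValueError("background_rate must be non-negative")
    rng = np.random.default_rng(seed)
    pulses = spec.pulse_times()
    duration = float(pulses[-1]) + 2.0

    n_bg = rng.poisson(background_rate * duration)
    spikes = rng.uniform(0.0, duration, size=n_bg)
    if tagged:
        fire = rng.random(len(pulses)) < spec.reliability
        lat = rng.normal(spec.latency_mean, spec.latency_jitter_sd, size=len(pulses))
        lat = np.clip(lat, 0.5, spec.pulse_duration - 0.1) * 1e-3
        spikes = np.concatenate([spikes, pulses[fire] + lat[fire]])
    spikes = np.sort(spikes)

    # mean-waveform estimates: template + noise ~ 1/sqrt(n_spikes)
    template = waveform_template()
    win = spec.pulse_duration * 1e-3
    in_test = np.zeros(len(spikes), dtype=bool)
    for p in pulses:
        i0, i1 = np.searchsorted(spikes, [p, p + win])
        in_test[i0:i1] = True
    n_evoked = max(1, int(in_test.sum()))
    n_spont = max(1, int((~in_test).sum()))
    wf_evoked = template + rng.normal(0, waveform_noise_sd / np.sqrt(n_evoked), template.shape)
    wf_spont = template + rng.normal(0, waveform_noise_sd / np.sqrt(n_spont), template.shape)
    return pulses, spikes, {"evoked": wf_evoked, "spontaneous": wf_spont}
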