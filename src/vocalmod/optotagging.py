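"""Optogenetic tagging via the stimulus-associated spike-latency test (SALT).

A unit is light-responsive (putatively a projection neuron expressing the
opsin) when three criteria hold together: a light-induced firing-rate
increase, a SALT p-value below 0.01, and a Pearson correlation above 0.9
between its light-evoked and spontaneous mean waveforms.

SALT asks whether the distribution of first-spike latencies in the 10 ms
window after light onset differs from those in 10 ms epochs tiling the
baseline period (-150 to 0 ms before the pulse). Latency histograms are
compared with the square-root Jensen-Shannon divergence (a metric); the
null distribution is the set of all pairwise distances among the baseline
epochs, and the p-value is the rank of the test statistic (the median
distance from the test epoch to the baseline epochs) within that null set.
With 15 baseline epochs the null has 105 pairwise distances, so the
smallest attainable p is 1/106 with the add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "LatencyHistogramSet", "TagResult",
    "latency_histograms", "js_distance", "salt",
    "waveform_similarity", "rate_ratio", "classify_tag",
]


@dataclass
class LatencyHistogramSet:
    """First-spike-latency counts per epoch.

    ``baseline`` is (n_epochs, n_bins + 1) and ``test`` is (n_bins + 1,);
    the final column is the no-spike bin, so each row sums to the number
    of pulses.
    """

    baseline: np.ndarray
    test: np.ndarray
    bin_ms: float
    epoch_ms: float
    n_pulses: int


def latency_histograms(
    spikes,
    pulse_onsets,
    epoch_ms: float = 10.0,
    baseline_span_ms: float = 150.0,
    bin_ms: float = 1.0,
) -> LatencyHistogramSet:
    """Accumulate first-spike latencies per epoch over all pulses.

    Baseline epochs tile [-baseline_span, 0) ms before each pulse in
    ``epoch_ms`` steps; the test epoch is [0, epoch_ms) after the pulse.
    For each (pulse, epoch) the latency of the first spike inside the epoch
    goes into a ``bin_ms`` bin, or into the trailing no-spike bin.
    """
    spikes = np.asarray(spikes, dtype=float)
    pulses = np.asarray(pulse_onsets, dtype=float)
    if len(pulses) < 10:
        raise ValueError("need at least 10 pulses")
    if len(pulses) > 1 and np.min(np.diff(np.sort(pulses))) < (baseline_span_ms + epoch_ms) / 1e3:
        raise ValueError("pulses closer than baseline span + test window overlap")
    n_base = int(round(baseline_span_ms / epoch_ms))
    n_bins = int(round(epoch_ms / bin_ms))
    starts_ms = np.concatenate([-baseline_span_ms + epoch_ms * np.arange(n_base), [0.0]])

    hists = np.zeros((n_base + 1, n_bins + 1), dtype=float)
    if len(spikes) == 0:
        hists[:, n_bins] = len(pulses)
        return LatencyHistogramSet(
            baseline=hists[:-1], test=hists[-1],
            bin_ms=bin_ms, epoch_ms=epoch_ms, n_pulses=len(pulses),
        )
    for e, start in enumerate(starts_ms):
        t0 = pulses + start / 1e3
        i0 = np.searchsorted(spikes, t0)
        i1 = np.searchsorted(spikes, t0 + epoch_ms / 1e3)
        has = i1 > i0
        lat_ms = np.where(has, spikes[np.minimum(i0, len(spikes) - 1)] - t0, 0.0) * 1e3
        bins = np.clip((lat_ms / bin_ms).astype(int), 0, n_bins - 1)
        for h, b in zip(has, bins):
            hists[e, b if h else n_bins] += 1
    return LatencyHistogramSet(
        baseline=hists[:-1], test=hists[-1],
        bin_ms=bin_ms, epoch_ms=epoch_ms, n_pulses=len(pulses),
    )


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def js_distance(p, q) -> float:
    """sqrt of the Jensen-Shannon divergence (nats); a metric in [0, sqrt(ln 2)].

    JSD(p, q) = 0.5 KL(p || m) + 0.5 KL(q || m) with m = (p + q)/2; zero
    bins follow the 0 * log(0/x) = 0 convention and the mixture keeps every
    term finite.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if abs(p.sum() - 1.0) > 1e-8 or abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("inputs must be normalized probability vectors")
    m = 0.5 * (p + q)
    return float(np.sqrt(max(0.0, 0.5 * _kl(p, m) + 0.5 * _kl(q, m))))


@dataclass
class SaltResult:
    salt_p: float
    salt_info: float  # test-statistic excess over the null median, distance units


def salt(hists: LatencyHistogramSet) -> SaltResult:
    """SALT p-value and information distance from a latency-histogram set.

    Null set: all pairwise sqrt-JS distances among the baseline epochs.
    Test statistic m*: median distance from the test histogram to the
    baseline histograms. salt_p = (#{null >= m*} + 1) / (#null + 1);
    salt_info = m* - median(null). All-identical histograms give p = 1.
    """
    base = np.asarray(hists.baseline, dtype=float)
    totals = base.sum(axis=1)
    if np.count_nonzero(totals) < 2:
        raise ValueError("need at least two baseline epochs with events")
    p_base = base / totals[:, None]
    p_test = np.asarray(hists.test, dtype=float) / hists.test.sum()

    n = len(p_base)
    null = [
        js_distance(p_base[i], p_base[j]) for i in range(n) for j in range(i + 1, n)
    ]
    null = np.asarray(null)
    m_star = float(np.median([js_distance(p_test, p_base[i]) for i in range(n)]))
    p_val = (np.sum(null >= m_star) + 1.0) / (len(null) + 1.0)
    return SaltResult(salt_p=float(p_val), salt_info=m_star - float(np.median(null)))


def waveform_similarity(evoked_mean_wf, spontaneous_mean_wf) -> float:
    """Pearson r between mean waveforms, samples concatenated across the 4
    tetrode channels."""
    a = np.asarray(evoked_mean_wf, dtype=float).ravel()
    b = np.asarray(spontaneous_mean_wf, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("waveforms must have the same shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance waveform")
    return float(scipy.stats.pearsonr(a, b).statistic)


def rate_ratio(spikes, pulse_onsets, epoch_ms: float = 10.0,
               baseline_span_ms: float = 150.0) -> float:
    """Firing rate in the post-pulse test windows over the rate in the
    pre-pulse baseline spans."""
    spikes = np.asarray(spikes, dtype=float)
    pulses = np.asarray(pulse_onsets, dtype=float)
    test = np.sum(
        np.searchsorted(spikes, pulses + epoch_ms / 1e3) - np.searchsorted(spikes, pulses)
    )
    base = np.sum(
        np.searchsorted(spikes, pulses) - np.searchsorted(spikes, pulses - baseline_span_ms / 1e3)
    )
    test_rate = test / (len(pulses) * epoch_ms / 1e3)
    base_rate = base / (len(pulses) * baseline_span_ms / 1e3)
    if base_rate == 0:
        return np.inf if test_rate > 0 else 1.0
    return float(test_rate / base_rate)


@dataclass
class TagResult:
    salt_p: float
    salt_info: float
    waveform_r: float | None
    rate_ratio: float
    light_responsive: bool
    indeterminate: bool = False


def classify_tag(spikes, pulse_onsets, evoked_wf=None, spontaneous_wf=None,
                 alpha: float = 0.01, r_min: float = 0.9) -> TagResult:
    """Conjunction of the three light-responsiveness criteria:
    rate_ratio > 1 AND salt_p < alpha AND waveform r > r_min.

    Missing waveforms yield an indeterminate result (flag False).
    """
    hists = latency_histograms(spikes, pulse_onsets)
    s = salt(hists)
    rr = rate_ratio(spikes, pulse_onsets)
    if evoked_wf is None or spontaneous_wf is None:
        return TagResult(s.salt_p, s.salt_info, None, rr, False, indeterminate=True)
    r = waveform_similarity(evoked_wf, spontaneous_wf)
    flag = (rr > 1.0) and (s.salt_p < alpha) and (r > r_min)
    return TagResult(s.salt_p, s.salt_info, r, rr, bool(flag))
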