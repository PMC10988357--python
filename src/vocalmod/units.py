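"""Unit quality control and waveform-based cell typing.

Sorted units enter the analysis only if they have at least 100 spikes and a
clean absolute refractory period (1.0 ms). Units are typed narrow-spiking
(putative interneuron) vs wide-spiking (putative pyramidal) by k-means on
the trough-to-peak width of the mean waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["UnitRecord", "QcResult", "qc_unit", "spike_width", "classify_cell_type"]


@dataclass
class UnitRecord:
    unit_id: str
    spike_times: np.ndarray  # s, sorted
    mean_waveform: np.ndarray | None = None  # (4, n_samples), uV
    waveform_fs: float = 30_000.0
    ap: float | None = None  # mm from bregma
    ml: float | None = None
    region: str | None = None  # M1 or M2

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class QcResult:
    passed: bool
    reasons: list = field(default_factory=list)
    n_spikes: int = 0
    violation_fraction: float = 0.0


def qc_unit(
    unit: UnitRecord,
    min_spikes: int = 100,
    refractory: float = 0.001,
    max_violation_fraction: float = 0.005,
) -> QcResult:
    """Inclusion test: spike count and refractory-period violations.

    Fails when the unit has fewer than ``min_spikes`` spikes, or when the
    fraction of inter-spike intervals shorter than ``refractory`` exceeds
    ``max_violation_fraction`` (a contaminated, likely multi-unit cluster).
    """
    reasons = []
    n = unit.n_spikes
    if n < min_spikes:
        reasons.append(f"fewer than {min_spikes} spikes (n={n})")
    isi = np.diff(unit.spike_times)
    frac = float(np.mean(isi < refractory)) if len(isi) else 0.0
    if frac > max_violation_fraction:
        reasons.append(
            f"refractory violations {frac:.3%} exceed {max_violation_fraction:.3%}"
        )
    return QcResult(passed=not reasons, reasons=reasons, n_spikes=n,
                    violation_fraction=frac)


def spike_width(mean_waveform: np.ndarray, fs: float = 30_000.0) -> float:
    """Trough-to-peak duration (ms) of the mean waveform.

    Measured on the channel with the largest peak-to-trough amplitude. If
    the dominant deflection is positive the waveform is inverted first
    (polarity normalization), so the width is always trough -> next peak.
    """
    wf = np.atleast_2d(np.asarray(mean_waveform, dtype=float))
    ch = int(np.argmax(wf.max(axis=1) - wf.min(axis=1)))
    w = wf[ch]
    if np.all(np.diff(w) >= 0) or np.all(np.diff(w) <= 0):
        raise ValueError("monotone waveform has no trough")
    if abs(w.max()) > abs(w.min()):
        w = -w
    trough = int(np.argmin(w))
    after = w[trough:]
    if len(after) < 2:
        raise ValueError("trough at the last sample; no subsequent peak")
    peak = trough + int(np.argmax(after))
    return (peak - trough) / fs * 1e3


def classify_cell_type(widths, seed: int = 0) -> np.ndarray:
    """k-means (k=2) on spike widths; the narrow cluster is the putative
    interneuron class, the wide cluster putative pyramidal.

    Returns an array of 'narrow' / 'wide' labels aligned with the input.
    """
    widths = np.asarray(widths, dtype=float).reshape(-1, 1)
    if len(widths) < 2:
        raise ValueError("need at least two units")
    if np.ptp(widths) == 0:
        raise ValueError("all widths identical; two clusters undefined")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(widths)
    means = [widths[km.labels_ == k].mean() for k in (0, 1)]
    narrow = int(np.argmin(means))
    return np.where(km.labels_ == narrow, "narrow", "wide")
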