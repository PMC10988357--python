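"""Study-scale simulation benchmarks with planted ground truth.

These functions run the full analysis chain on synthetic populations at the
sizes used for validation: a null population for family-wise error
calibration, tagged/untagged populations for the light-responsiveness
criteria, a seven-type population for classification recovery, and audio
round-trips for the segmenter. They are the common substrate of the
acceptance checks and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import classification, optotagging, responses, segmentation, synth

__all__ = [
    "null_calibration",
    "salt_calibration",
    "type_recovery",
    "segmentation_benchmark",
]


def _null_stream(seed: int):
    """A call stream with >= 100 first and >= 300 subsequent calls."""
    return synth.gen_usv_stream(duration=1200.0, seed=seed)


def null_calibration(n_units: int = 1000, baseline_rate: float = 5.0,
                     seed: int = 0) -> dict:
    """Type-I calibration on null (homogeneous Poisson) units.

    Every unit fires at ``baseline_rate`` with no call modulation; the
    responsiveness battery and the flat-vs-FM discrimination test are run
    against a shared call stream. Returns the fraction of units flagged
    responsive (family-wise false-positive rate; Bonferroni should keep it
    near the nominal 5%) and the fraction flagged call-discriminating
    (nominal 5% single test).
    """
    stream = _null_stream(seed)
    firsts = stream.first_onsets
    subs = stream.subsequent_onsets
    flat_first = firsts[stream.is_flat[stream.is_first]]
    fm_first = firsts[~stream.is_flat[stream.is_first]]
    rng = np.random.default_rng(seed + 1)

    n_resp = n_disc = 0
    duration = stream.duration
    for _ in range(n_units):
        n = rng.poisson(baseline_rate * duration)
        spikes = np.sort(rng.uniform(0.0, duration, n))
        res = responses.responsiveness_test(spikes, firsts, subs)
        n_resp += res.responsive
        _, disc = responses.call_discrimination_test(spikes, flat_first, fm_first)
        n_disc += disc
    return {
        "n_units": n_units,
        "n_first_calls": len(firsts),
        "n_subsequent_calls": len(subs),
        "responsive_fraction": n_resp / n_units,
        "discriminating_fraction": n_disc / n_units,
    }


def salt_calibration(n_untagged: int = 500, n_tagged: int = 200,
                     seed: int = 0) -> dict:
    """Tagging sensitivity and specificity on simulated sessions.

    Untagged units are pure background; tagged units add an evoked spike
    per pulse (80% reliability, 3 +/- 1 ms latency by default). Reports the
    fraction of tagged units passing all three light-responsiveness
    criteria, the untagged false-flag rate, and the null salt_p sample for
    uniformity checks.
    """
    spec = synth.TaggingSpec()
    null_p = np.empty(n_untagged)
    false_flags = 0
    for i in range(n_untagged):
        pulses, spikes, wfs = synth.gen_tagging_session(
            spec, background_rate=5.0, tagged=False, seed=seed + i)
        res = optotagging.classify_tag(spikes, pulses, wfs["evoked"], wfs["spontaneous"])
        null_p[i] = res.salt_p
        false_flags += res.light_responsive

    hits = 0
    for i in range(n_tagged):
        pulses, spikes, wfs = synth.gen_tagging_session(
            spec, background_rate=5.0, tagged=True, seed=seed + 10_000 + i)
        res = optotagging.classify_tag(spikes, pulses, wfs["evoked"], wfs["spontaneous"])
        hits += res.light_responsive
    return {
        "n_untagged": n_untagged,
        "n_tagged": n_tagged,
        "null_salt_p": null_p,
        "sensitivity": hits / n_tagged,
        "false_positive_rate": false_flags / n_untagged,
    }


def type_recovery(n_per_type: int = 70, baseline_rate: float = 5.0,
                  seed: int = 0, tsne_seed: int = 0) -> dict:
    """Classification recovery of the seven planted responsive types.

    Builds a population with ``n_per_type`` units of each responsive type,
    runs the responsiveness battery, classifies the responsive units, and
    scores the watershed labels against the planted labels (adjusted Rand
    index over classified units). Also checks that every basin dominated by
    planted excitatory units is named E and every inhibition-dominated
    basin is named I.
    """
    stream = _null_stream(seed)
    profiles = synth.default_profiles(baseline_rate)
    type_order = [t for t in synth.RESPONSE_TYPES if t != "NR"]
    vecs, rates, resp, planted = [], [], [], []
    uid = 0
    for label in type_order:
        for _ in range(n_per_type):
            spikes = synth.gen_spike_train(
                profiles[label], stream, stream.duration, seed=seed + 100 + uid)
            prof = responses.analyze_unit(
                str(uid), spikes, stream.first_onsets, stream.subsequent_onsets)
            vecs.append(prof.vector25)
            rates.append(prof.baseline_rate)
            resp.append(prof.responsive)
            planted.append(label)
            uid += 1
    vecs = np.asarray(vecs)
    rates = np.asarray(rates)
    resp = np.asarray(resp)
    planted = np.asarray(planted)

    tm = classification.classify_population(
        vecs[resp], rates[resp], seed=tsne_seed)
    ari = adjusted_rand_score(planted[resp], tm.labels)

    naming_ok = True
    for lab in np.unique(tm.labels):
        members = planted[resp][tm.labels == lab]
        vals, counts = np.unique(members, return_counts=True)
        majority = vals[np.argmax(counts)]
        name = tm.type_names[lab]
        if majority.startswith("E") and not name.startswith("E"):
            naming_ok = False
        if majority.startswith("I") and not name.startswith("I"):
            naming_ok = False
    return {
        "n_units": len(planted),
        "n_classified": int(resp.sum()),
        "ari": float(ari),
        "n_basins": len(np.unique(tm.labels)),
        "naming_consistent": naming_ok,
        "planted": planted,
        "responsive": resp,
        "type_map": tm,
    }


def segmentation_benchmark(duration: float = 40.0, n_repeats: int = 3,
                           seed: int = 0, sample_rate: float = 250_000.0) -> dict:
    """Audio round-trip: synthesize known syllables, re-detect them, and
    measure recall at a 5 ms onset tolerance."""
    recovered = total = 0
    errors = []
    for r in range(n_repeats):
        gt = synth.gen_usv_stream(duration=duration, bout_rate=8.0, seed=seed + r)
        wave = synth.gen_audio(gt, sample_rate, noise_sd=0.02, seed=seed + 50 + r)
        det = segmentation.detect_syllables(
            segmentation.spectrogram(wave, sample_rate))
        onsets = np.array([d.onset for d in det])
        for o in gt.onsets:
            total += 1
            if len(onsets):
                err = float(np.min(np.abs(onsets - o)))
                errors.append(err)
                recovered += err <= 0.005
    return {
        "n_planted": total,
        "recall": recovered / total if total else float("nan"),
        "median_onset_error_ms": float(np.median(errors) * 1e3) if errors else float("nan"),
    }
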