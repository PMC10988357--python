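"""Generator contracts: bout structure, audio rendering, planted spike gains."""

import numpy as np
import pandas as pd
import pytest

from vocalmod import responses, segmentation, synth


class TestUsvStream:
    def test_within_bout_interval_statistics(self):
        gt = synth.gen_usv_stream(duration=600.0, bout_rate=20.0, seed=1)
        bout = gt.syllables["bout_id"].to_numpy()
        d = np.diff(gt.onsets)
        within = d[bout[1:] == bout[:-1]]
        assert len(within) >= 500
        assert abs(within.mean() - 0.366) <= 0.02

    def test_bout_structure_invariants(self, usv_stream):
        gt = usv_stream
        onsets = gt.onsets
        assert np.all(np.diff(onsets) > 0)
        assert np.all(gt.syllables["offset_s"] > gt.syllables["onset_s"])
        bout = gt.syllables["bout_id"].to_numpy()
        d = np.diff(onsets)
        same = bout[1:] == bout[:-1]
        assert np.all(d[same] < gt.bout_gap)
        # between-bout silent gaps (previous offset to next onset) >= bout_gap
        offs = gt.syllables["offset_s"].to_numpy()
        assert np.all(onsets[1:][~same] - offs[:-1][~same] >= gt.bout_gap)

    def test_first_call_split_recovers_planted_bout_starts(self, usv_stream):
        flags = segmentation.split_calls(usv_stream.onsets)
        assert np.array_equal(flags, usv_stream.is_first)

    def test_zero_bout_rate_gives_empty_table(self):
        gt = synth.gen_usv_stream(duration=100.0, bout_rate=0.0, seed=0)
        assert len(gt.syllables) == 0

    def test_deterministic_for_fixed_seed(self):
        a = synth.gen_usv_stream(duration=200.0, seed=42)
        b = synth.gen_usv_stream(duration=200.0, seed=42)
        pd.testing.assert_frame_equal(a.syllables, b.syllables)

    @pytest.mark.parametrize("kwargs", [
        {"duration": -1.0}, {"duration": 0.0},
        {"duration": 10.0, "bout_rate": -1.0},
        {"duration": 10.0, "isi_mean": 0.05, "isi_sd": 0.06},
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            synth.gen_usv_stream(seed=0, **kwargs)

    def test_flat_fm_frequency_extents(self, usv_stream):
        extent = (usv_stream.syllables["fmax_khz"] - usv_stream.syllables["fmin_khz"])
        flat = usv_stream.is_flat
        assert np.all(extent[flat] < 15.0)
        assert np.all(extent[~flat] > 15.0)


def _single_syllable_truth(onset, offset, fmin, fmax, duration):
    table = pd.DataFrame(
        [[onset, offset, fmin, fmax, 0]],
        columns=["onset_s", "offset_s", "fmin_khz", "fmax_khz", "bout_id"],
    )
    return synth.UsvGroundTruth(table, duration=duration)


class TestAudio:
    def test_empty_truth_gives_pure_noise(self):
        gt = synth.gen_usv_stream(duration=0.5, bout_rate=0.0, seed=0)
        wave = synth.gen_audio(gt, sample_rate=250_000, noise_sd=0.02, seed=0)
        assert len(wave) == 125_000
        assert abs(np.std(wave) - 0.02) < 0.002

    def test_flat_tone_energy_at_stated_frequency_and_time(self):
        gt = _single_syllable_truth(1.0, 1.05, 58.0, 62.0, 2.0)
        wave = synth.gen_audio(gt, sample_rate=250_000, seed=0)
        spec = segmentation.spectrogram(wave, 250_000)
        inside = (spec.times >= 1.005) & (spec.times <= 1.045)
        peaks = spec.freqs[np.argmax(spec.magnitude[:, inside], axis=0)]
        assert np.all(np.abs(peaks - 60.0) < 2.0)
        outside = spec.times < 0.9
        assert spec.magnitude[:, inside].max() > 10 * spec.magnitude[:, outside].max()

    def test_fm_chirp_sweeps_stated_extent(self):
        gt = _single_syllable_truth(0.5, 0.6, 40.0, 80.0, 1.5)
        wave = synth.gen_audio(gt, sample_rate=250_000, seed=0)
        spec = segmentation.spectrogram(wave, 250_000)
        inside = (spec.times >= 0.51) & (spec.times <= 0.59)
        peaks = spec.freqs[np.argmax(spec.magnitude[:, inside], axis=0)]
        assert peaks.max() - peaks.min() >= 15.0

    def test_nyquist_violation_raises(self):
        gt = _single_syllable_truth(0.1, 0.2, 60.0, 110.0, 1.0)
        with pytest.raises(ValueError):
            synth.gen_audio(gt, sample_rate=100_000, seed=0)


class TestSpikeTrain:
    def test_nonresponder_is_homogeneous_poisson(self, profiles):
        gt = synth.gen_usv_stream(duration=100.0, bout_rate=0.0, seed=0)
        spikes = synth.gen_spike_train(profiles["NR"], gt, 100.0, seed=7)
        assert 390 <= len(spikes) <= 610  # 500 +/- 4 SD

    def test_excitatory_gain_recovered_in_psth(self, profiles, long_usv_stream):
        spec = synth.ResponseProfileSpec(
            "E1", baseline_rate=5.0,
            first_kernel=(synth.GainSegment(0.0, 0.25, 3.0),),
            subsequent_kernel=(),
        )
        # pool trials over several independent units to reach ~200+ first calls
        ratios = []
        for s in range(3):
            spikes = synth.gen_spike_train(spec, long_usv_stream, 1000.0, seed=50 + s)
            resp = responses.window_rates(
                spikes, long_usv_stream.first_onsets, 0.0, 0.25)
            base = responses.baseline_rates(spikes, long_usv_stream.first_onsets)
            ratios.append(resp.mean() / base.mean())
        assert abs(np.mean(ratios) - 3.0) <= 0.3

    def test_inhibitory_gain_pushes_auroc_below_half(self, profiles, long_usv_stream):
        spikes = synth.gen_spike_train(profiles["I1"], long_usv_stream, 1000.0, seed=3)
        prof = responses.analyze_unit(
            "i1", spikes, long_usv_stream.first_onsets,
            long_usv_stream.subsequent_onsets)
        post = prof.auroc_first[20:25]  # bins covering (0, 0.25] s
        assert np.all(post < 0.5)

    def test_zero_baseline_rate_rejected(self, profiles, usv_stream):
        bad = synth.ResponseProfileSpec("NR", baseline_rate=0.0)
        with pytest.raises(ValueError):
            synth.gen_spike_train(bad, usv_stream, 10.0, seed=0)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            synth.ResponseProfileSpec(
                "X", 5.0, first_kernel=(synth.GainSegment(0, 0.1, -1.0),))


class TestTaggingSession:
    def test_default_protocol_has_100_pulses_in_10_trains(self):
        spec = synth.TaggingSpec()
        pulses = spec.pulse_times()
        assert len(pulses) == 100
        gaps = np.diff(pulses)
        assert np.sum(gaps > 1.0) == 9  # 9 intertrain boundaries
        assert np.allclose(gaps[gaps < 1.0], 0.2)

    def test_tagged_unit_fires_reliably_in_test_window(self):
        spec = synth.TaggingSpec(reliability=0.8)
        pulses, spikes, _ = synth.gen_tagging_session(spec, 5.0, tagged=True, seed=1)
        n_test = sum(
            np.searchsorted(spikes, p + 0.010) - np.searchsorted(spikes, p)
            for p in pulses
        )
        # ~80 evoked + ~5 background expected
        assert 65 <= n_test <= 105

    def test_untagged_unit_has_unit_rate_ratio(self):
        spec = synth.TaggingSpec()
        ratios = []
        for s in range(5):
            pulses, spikes, _ = synth.gen_tagging_session(spec, 20.0, tagged=False, seed=s)
            n_test = sum(
                np.searchsorted(spikes, p + 0.010) - np.searchsorted(spikes, p)
                for p in pulses
            )
            n_base = sum(
                np.searchsorted(spikes, p) - np.searchsorted(spikes, p - 0.150)
                for p in pulses
            )
            ratios.append((n_test / 1.0) / (n_base / 15.0))
        assert abs(np.mean(ratios) - 1.0) < 0.25

    def test_invalid_reliability_rejected(self):
        with pytest.raises(ValueError):
            synth.TaggingSpec(reliability=1.5)
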