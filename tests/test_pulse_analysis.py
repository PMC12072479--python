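"""Beat segmentation, pulse-amplitude windows and P1/P2 morphology."""

import numpy as np
import pytest

from icpwaves.preprocess import detect_artifacts, smooth_bartlett
from icpwaves.pulse_analysis import (
    ABNORMAL,
    INDETERMINATE,
    NORMAL,
    Beat,
    PulseParams,
    classify_pulse_morphology,
    detect_beats,
    select_baseline_window,
    select_wavetop_window,
    window_pulse_amplitude,
)
from icpwaves.signal_io import IcpSignal
from icpwaves.slow_waves import B_LOW, SlowWaveTrain, detect_slow_wave_trains
from icpwaves.synthetic_data import BWaveTrainSpec, SimulationSpec, simulate_icp_recording


def _sig(x, fs=200.0):
    return IcpSignal("t", np.asarray(x, dtype=float), sampling_rate=fs)


class TestBeatDetection:
    def test_simulated_heart_rate_recovered(self):
        sig, _ = simulate_icp_recording(
            SimulationSpec(duration_s=60, sampling_rate=200, heart_rate_bpm=120, seed=1)
        )
        beats = detect_beats(sig)
        assert abs(len(beats) - 120) <= 2

    def test_constant_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_beats(_sig(np.full(4000, 15.0))) == []

    def test_pure_sinusoid_beats_and_amplitude(self):
        fs = 200.0
        t = np.arange(int(30 * fs)) / fs
        x = 15.0 + 2.0 * np.sin(2 * np.pi * 2.0 * t)  # 2 Hz, peak-to-trough 4
        beats = detect_beats(_sig(x, fs))
        assert len(beats) >= 55
        spacings = np.diff([b.start_idx for b in beats]) / fs
        np.testing.assert_allclose(spacings, 0.5, atol=0.05)
        amps = [b.amplitude for b in beats]
        np.testing.assert_allclose(amps, 4.0, atol=0.1)

    def test_beats_overlapping_artifacts_discarded(self):
        sig, _ = simulate_icp_recording(
            SimulationSpec(duration_s=60, sampling_rate=200, seed=2)
        )
        mask = detect_artifacts(sig)
        mask.valid[2000:4000] = False
        beats = detect_beats(sig, mask)
        assert all(b.end_idx <= 2000 or b.start_idx >= 4000 for b in beats)

    def test_beats_ordered_and_non_overlapping(self):
        sig, _ = simulate_icp_recording(SimulationSpec(duration_s=60, seed=3))
        beats = detect_beats(sig)
        for a, b in zip(beats, beats[1:]):
            assert a.end_idx <= b.start_idx
            assert a.dia_idx <= a.sys_idx
            assert a.amplitude >= 0


class TestWindowAmplitude:
    @staticmethod
    def _beat(i, amp, fs=200.0, period=0.5):
        a = int(i * period * fs)
        b = int((i + 1) * period * fs)
        return Beat(a, b, a, (a + b) // 2, 10.0, 10.0 + amp)

    def test_uniform_beats_recovered_exactly(self):
        beats = [self._beat(i, 4.0) for i in range(100)]
        amp, n = window_pulse_amplitude(beats, 0, 60, 200.0)
        assert amp == pytest.approx(4.0)
        assert n == 100

    def test_mean_of_mixed_amplitudes(self):
        beats = [self._beat(i, 3.0 if i % 2 else 5.0) for i in range(100)]
        amp, _ = window_pulse_amplitude(beats, 0, 60, 200.0)
        assert amp == pytest.approx(4.0)

    def test_too_few_beats_indeterminate(self):
        beats = [self._beat(i, 4.0) for i in range(10)]
        amp, n = window_pulse_amplitude(beats, 0, 60, 200.0)
        assert np.isnan(amp)
        assert n == 10

    def test_simulated_window_amplitude_within_half_mmhg(self):
        sig, truth = simulate_icp_recording(
            SimulationSpec(duration_s=660, sampling_rate=200, pulse_amplitude=11.0, seed=4)
        )
        beats = detect_beats(sig)
        amp, _ = window_pulse_amplitude(beats, 0, 600, sig.sampling_rate)
        assert amp == pytest.approx(truth.pulse_amp_baseline, abs=0.5)


class TestWindowSelection:
    def test_baseline_window_found_in_quiet_lowest_segment(self, overnight_results):
        res, truth, _ = overnight_results
        w = res.baseline_window
        assert w is not None
        assert w.duration_s == pytest.approx(600)
        # quiet baseline: no train overlap, mean near configured baseline
        for tr in res.trains:
            assert tr.overlap_s(w.start_s, w.end_s) == 0
        assert w.icp_amp == pytest.approx(truth.pulse_amp_baseline, abs=0.5)

    def test_all_wave_recording_has_no_baseline_window(self):
        spec = SimulationSpec(
            duration_s=3600,
            sampling_rate=100,
            noise_sd=0.2,
            b_wave_trains=(BWaveTrainSpec(0, 3600, 1.0, 8.0),),
            seed=5,
        )
        sig, _ = simulate_icp_recording(spec)
        mask = detect_artifacts(sig)
        trains = detect_slow_wave_trains(smooth_bartlett(sig), mask)
        beats = detect_beats(sig, mask)
        assert select_baseline_window(sig, mask, trains, beats) is None

    def test_tie_broken_to_earliest(self):
        # exactly periodic signal: every candidate window has the same mean,
        # so the earliest must win
        fs = 200.0
        t = np.arange(int(1500 * fs)) / fs
        x = 12.0 + 2.0 * np.sin(2 * np.pi * 2.0 * t)
        sig = _sig(x, fs)
        beats = detect_beats(sig)
        w = select_baseline_window(sig, None, [], beats)
        assert w is not None
        assert w.start_s == 0.0

    def test_wavetop_window_prefers_largest_train(self):
        spec = SimulationSpec(
            duration_s=7200,
            sampling_rate=100,
            noise_sd=0.2,
            amp_coupling=2.0,
            b_wave_trains=(
                BWaveTrainSpec(600, 1500, 1.0, 6.0),
                BWaveTrainSpec(4200, 1500, 1.0, 14.0),
            ),
            seed=7,
        )
        sig, _ = simulate_icp_recording(spec)
        mask = detect_artifacts(sig)
        sm = smooth_bartlett(sig)
        trains = detect_slow_wave_trains(sm, mask)
        beats = detect_beats(sig, mask)
        w = select_wavetop_window(sig, mask, trains, beats, sm)
        assert w is not None
        assert 4200 - 120 <= w.start_s <= 5700
        assert w.duration_s == pytest.approx(600)

    def test_no_trains_means_no_wavetop_window(self):
        sig, _ = simulate_icp_recording(SimulationSpec(duration_s=1200, sampling_rate=100, seed=8))
        sm = smooth_bartlett(sig)
        assert select_wavetop_window(sig, None, [], [], sm) is None

    def test_short_train_means_no_wavetop_window(self):
        sm_stub = IcpSignal("t", np.full(1000, 12.0), sampling_rate=1.0, channel_label="smoothed")
        tr = SlowWaveTrain(0, 480, B_LOW, [5.0] * 8)
        assert select_wavetop_window(sm_stub, None, [tr], [], sm_stub) is None

    def test_single_long_train_window_within_bounds(self, overnight_results):
        res, _, spec = overnight_results
        w = res.wavetop_window
        assert w is not None
        big = spec.b_wave_trains[1]
        assert big.start_s - 120 <= w.start_s
        assert w.end_s <= big.end_s + 120

    def test_coupled_amplitude_rises_on_wave_tops(self, overnight_results):
        res, _, _ = overnight_results
        assert res.wavetop_window.icp_amp > res.baseline_window.icp_amp
        assert res.wavetop_window.mean_icp >= res.baseline_window.mean_icp


class TestMorphology:
    @staticmethod
    def _beat_with_peaks(p1, p2):
        sub = [(0.1, p1)] if p2 is None else [(0.1, p1), (0.2, p2)]
        return Beat(0, 100, 0, 50, 10.0, 10.0 + p1, sub_peaks=sub)

    def test_p1_dominant_is_normal(self):
        beats = [self._beat_with_peaks(6.0, 4.0)] * 10
        assert classify_pulse_morphology(beats) == NORMAL

    def test_p2_dominant_is_abnormal(self):
        beats = [self._beat_with_peaks(4.0, 6.0)] * 10
        assert classify_pulse_morphology(beats) == ABNORMAL

    def test_single_peak_beats_indeterminate(self):
        beats = [self._beat_with_peaks(6.0, None)] * 10
        assert classify_pulse_morphology(beats) == INDETERMINATE

    @pytest.mark.parametrize("ratio, expected", [(0.8, NORMAL), (1.3, ABNORMAL)])
    def test_simulated_morphology_recovered(self, ratio, expected):
        sig, _ = simulate_icp_recording(
            SimulationSpec(duration_s=60, sampling_rate=200, p2_over_p1=ratio, seed=9)
        )
        beats = detect_beats(sig)
        assert classify_pulse_morphology(beats) == expected

    def test_elevated_threshold_semantics(self):
        from icpwaves.pulse_analysis import PulseWindow

        w = PulseWindow("baseline", 0, 600, 12.0, 5.0, 60)
        assert w.elevated() is True
        w2 = PulseWindow("baseline", 0, 600, 12.0, 4.9, 60)
        assert w2.elevated() is False
        w3 = PulseWindow("baseline", 0, 600, 12.0, float("nan"), 3)
        assert w3.elevated() is None
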