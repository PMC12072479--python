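"""B-wave train detection, classification, plateau waves and night burden."""

from datetime import datetime

import numpy as np
import pytest

from icpwaves.signal_io import IcpSignal
from icpwaves.slow_waves import (
    A_PLATEAU,
    B_HIGH,
    B_LOW,
    PlateauParams,
    SlowWaveParams,
    SlowWaveTrain,
    classify_train,
    detect_plateau_waves,
    detect_slow_wave_trains,
    nocturnal_wave_percentages,
)
from icpwaves.synthetic_data import (
    BWaveTrainSpec,
    PlateauSpec,
    SimulationSpec,
    simulate_icp_recording,
)


def sinusoid_signal(freq_per_min, p2t_mmhg, active_min, total_min=None, fs=2.0):
    """Smoothed-channel stand-in: baseline with one sinusoidal slow-wave
    segment of the given peak-to-trough amplitude in the middle."""
    total_min = total_min or active_min + 20
    t = np.arange(int(total_min * 60 * fs)) / fs
    start = (total_min - active_min) / 2 * 60
    x = np.full(t.size, 15.0)
    inside = (t >= start) & (t < start + active_min * 60)
    x[inside] += (p2t_mmhg / 2) * np.sin(2 * np.pi * (freq_per_min / 60) * (t[inside] - start))
    return IcpSignal("t", x, sampling_rate=fs, channel_label="smoothed"), start


class TestTrainDetection:
    def test_in_band_sinusoid_detected_with_wave_count(self):
        sig, start = sinusoid_signal(1.0, 6.0, 20)
        trains = detect_slow_wave_trains(sig)
        assert len(trains) == 1
        tr = trains[0]
        assert tr.wave_class == B_LOW
        assert abs(tr.wave_count - 20) <= 1
        assert 0.5 <= tr.mean_frequency_per_min <= 3.0
        assert tr.start_s == pytest.approx(start, abs=90)

    def test_above_band_frequency_never_a_train(self):
        sig, _ = sinusoid_signal(4.0, 6.0, 20)
        assert detect_slow_wave_trains(sig) == []

    def test_too_short_episode_never_a_train(self):
        sig, _ = sinusoid_signal(1.0, 6.0, 8)
        assert detect_slow_wave_trains(sig) == []

    def test_sub_threshold_amplitude_ignored(self):
        sig, _ = sinusoid_signal(1.0, 1.0, 20)
        assert detect_slow_wave_trains(sig) == []

    def test_reported_trains_satisfy_definition_invariants(self, overnight_results):
        res, _, _ = overnight_results
        for tr in res.trains:
            assert tr.duration_s >= 600.0
            assert 0.5 <= tr.mean_frequency_per_min <= 3.0
            expected = B_HIGH if tr.median_amplitude >= 10.0 else B_LOW
            assert tr.wave_class == expected

    def test_raising_amplitude_floor_never_adds_wave_time(self):
        sig, _ = sinusoid_signal(1.0, 6.0, 30)

        def total(min_amp):
            trains = detect_slow_wave_trains(
                sig, params=SlowWaveParams(min_wave_amp_mmhg=min_amp)
            )
            return sum(tr.duration_s for tr in trains)

        times = [total(a) for a in (1.0, 2.0, 4.0, 7.0)]
        assert all(a >= b for a, b in zip(times, times[1:]))


class TestClassification:
    @pytest.mark.parametrize(
        "amps, expected",
        [
            ([10.0, 10.0, 10.0], B_HIGH),  # boundary inclusive
            ([9.9, 9.9], B_LOW),
            ([6.0, 12.0, 14.0], B_HIGH),  # median 12
            ([6.0, 6.0, 14.0], B_LOW),  # median 6
        ],
    )
    def test_median_amplitude_rule(self, amps, expected):
        assert classify_train(amps) == expected

    def test_empty_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            classify_train([])


class TestPlateau:
    def test_simulated_plateau_recovered_at_bounds(self):
        spec = SimulationSpec(
            duration_s=5400,
            sampling_rate=100,
            noise_sd=0.2,
            plateau_waves=(PlateauSpec(start_s=2400, duration_s=480, rise_mmhg=25),),
            seed=4,
        )
        sig, _ = simulate_icp_recording(spec)
        from icpwaves.preprocess import detect_artifacts, smooth_bartlett

        plateaus = detect_plateau_waves(smooth_bartlett(sig), detect_artifacts(sig))
        assert len(plateaus) == 1
        pl = plateaus[0]
        assert pl.wave_class == A_PLATEAU
        assert pl.start_s == pytest.approx(2400, abs=30)
        assert pl.end_s == pytest.approx(2880, abs=30)

    def test_flat_recording_has_no_plateau(self):
        sig, _ = simulate_icp_recording(
            SimulationSpec(duration_s=5400, sampling_rate=50, seed=5)
        )
        from icpwaves.preprocess import smooth_bartlett

        assert detect_plateau_waves(smooth_bartlett(sig)) == []

    def test_small_rise_below_threshold_ignored(self):
        spec = SimulationSpec(
            duration_s=5400,
            sampling_rate=100,
            noise_sd=0.2,
            plateau_waves=(PlateauSpec(start_s=2400, duration_s=480, rise_mmhg=5),),
            seed=4,
        )
        sig, _ = simulate_icp_recording(spec)
        from icpwaves.preprocess import smooth_bartlett

        assert detect_plateau_waves(smooth_bartlett(sig)) == []


class TestNightPercentages:
    @staticmethod
    def _night_signal(hours=12.0):
        # 20:00 start: night window 22:01-08:00 lies inside
        n = int(hours * 3600)
        return IcpSignal(
            "t",
            np.full(n, 12.0),
            sampling_rate=1.0,
            start_clock=datetime(2000, 1, 1, 20, 0, 0),
        )

    def test_half_night_of_trains_is_fifty_percent(self):
        sig = self._night_signal()
        night_start = (2 * 60 + 1) * 60  # 22:01
        night_len = sig.n_samples - night_start
        tr = SlowWaveTrain(
            start_s=night_start,
            end_s=night_start + night_len / 2,
            wave_class=B_LOW,
            per_wave_amplitudes=[5.0] * 10,
        )
        pct = nocturnal_wave_percentages([tr], sig)
        assert pct.pct_b_low == pytest.approx(50.0, abs=0.1)
        assert pct.pct_b_total == pct.pct_b_low + pct.pct_b_high

    def test_no_trains_all_zero(self):
        pct = nocturnal_wave_percentages([], self._night_signal())
        assert pct.pct_b_total == 0.0
        assert not pct.plateau_present

    def test_plateau_sets_flag_but_not_b_percentages(self):
        sig = self._night_signal()
        pl = SlowWaveTrain(
            start_s=4 * 3600, end_s=4 * 3600 + 600, wave_class=A_PLATEAU,
            per_wave_amplitudes=[25.0],
        )
        pct = nocturnal_wave_percentages([pl], sig)
        assert pct.plateau_present
        assert pct.pct_b_total == 0.0

    def test_strict_600min_denominator(self):
        sig = self._night_signal()
        night_start = (2 * 60 + 1) * 60
        tr = SlowWaveTrain(
            start_s=night_start,
            end_s=night_start + 300 * 60,
            wave_class=B_HIGH,
            per_wave_amplitudes=[12.0] * 10,
        )
        pct = nocturnal_wave_percentages([tr], sig, strict_10h=True)
        assert pct.pct_b_high == pytest.approx(100 * 300 / 600)

    def test_simulated_night_burden_recovered(self, overnight_results):
        res, truth, _ = overnight_results
        assert res.percentages.pct_b_total == pytest.approx(truth.pct_b_total, abs=5)
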