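"""Cardiac pulse analysis of the ICP trace.

Each heartbeat stamps a pulse wave onto the pressure signal.  Its
time-domain amplitude — systolic maximum minus diastolic minimum, written
ICP_AMP — and its shape carry information about intracranial compliance: an
amplitude of 5 mmHg or more, or a second sub-peak (P2) overtaking the first
(P1), indicates a stiff intracranial system.  Two 10-minute windows are
summarized per recording: ICP_AMP1 on a quiet, artifact-free baseline
stretch at the lowest mean ICP without slow waves, and ICP_AMP2 on top of
the largest-amplitude B- or A-wave train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import ArtifactMask, IcpSignal
from .slow_waves import SlowWaveTrain

__all__ = [
    "PulseParams",
    "Beat",
    "PulseWindow",
    "detect_beats",
    "window_pulse_amplitude",
    "select_baseline_window",
    "select_wavetop_window",
    "classify_pulse_morphology",
    "NORMAL",
    "ABNORMAL",
    "INDETERMINATE",
]

NORMAL = "normal"
ABNORMAL = "abnormal"
INDETERMINATE = "indeterminate"

BASELINE = "baseline"
WAVE_TOP = "wave_top"


@dataclass(frozen=True)
class PulseParams:
    """Settings of the beat detector and window summaries.

    hr_band_bpm is the admissible heart-rate range (pediatric default
    60–220 bpm); min_prominence_mmhg the smallest excursion accepted as a
    P1/P2 sub-peak; elevated_amp_mmhg the compliance threshold on ICP_AMP;
    measure_lowpass_hz removes broadband noise before per-beat min/max
    measurement (cardiac energy in ICP lies well below 15 Hz).
    wavetop_tertile keeps only beats whose smoothed-channel level lies in
    the top third of the window when measuring ICP_AMP2.
    """

    hr_band_bpm: tuple[float, float] = (60.0, 220.0)
    min_prominence_mmhg: float = 0.5
    window_minutes: float = 10.0
    elevated_amp_mmhg: float = 5.0
    min_beats_per_window: int = 30
    measure_lowpass_hz: float = 15.0
    wavetop_tertile: float = 1.0 / 3.0
    stride_s: float = 60.0


@dataclass
class Beat:
    """One cardiac cycle of the ICP trace.

    Indices are sample positions in the parent signal; sub_peaks holds
    (time_s, height_mmhg) of local maxima after the diastolic trough, with
    heights measured above the diastolic minimum.
    """

    start_idx: int
    end_idx: int
    dia_idx: int
    sys_idx: int
    diastolic_min: float
    systolic_max: float
    sub_peaks: list[tuple[float, float]] = field(default_factory=list)

    @property
    def amplitude(self) -> float:
        return self.systolic_max - self.diastolic_min

    @property
    def p1_height(self) -> float | None:
        return self.sub_peaks[0][1] if len(self.sub_peaks) >= 1 else None

    @property
    def p2_height(self) -> float | None:
        return self.sub_peaks[1][1] if len(self.sub_peaks) >= 2 else None


@dataclass
class PulseWindow:
    """A 10-minute pulse-amplitude summary window.

    context is ``"baseline"`` (ICP_AMP1) or ``"wave_top"`` (ICP_AMP2);
    icp_amp is the mean of per-beat amplitudes, NaN when fewer than
    min_beats_per_window beats were available (indeterminate).
    """

    context: str
    start_s: float
    end_s: float
    mean_icp: float
    icp_amp: float
    n_beats: int
    morphology: str = INDETERMINATE

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def indeterminate(self) -> bool:
        return not np.isfinite(self.icp_amp)

    def elevated(self, threshold: float = 5.0) -> bool | None:
        """Abnormal pulse amplitude (low compliance) iff icp_amp >= 5 mmHg."""
        if self.indeterminate:
            return None
        return bool(self.icp_amp >= threshold)


def _dominant_cardiac_frequency(
    x: np.ndarray, fs: float, hr_band_bpm: tuple[float, float]
) -> float | None:
    """Spectral peak inside the heart-rate band, or None if no clear beat."""
    lo, hi = hr_band_bpm[0] / 60.0, hr_band_bpm[1] / 60.0
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        return None
    nperseg = min(x.size, max(int(30 * fs), 256))
    freqs, psd = sps.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any() or not np.any(psd[band] > 0):
        return None
    pk = psd[band].max()
    med = np.median(psd[band])
    # a real cardiac line towers over the in-band noise floor
    if pk < 1e-8 or (med > 0 and pk < 5 * med):
        return None
    return float(freqs[band][np.argmax(psd[band])])


def detect_beats(
    signal: IcpSignal,
    mask: ArtifactMask | None = None,
    params: PulseParams = PulseParams(),
) -> list[Beat]:
    """Segment the recording into cardiac beats.

    The dominant cardiac frequency is found spectrally inside hr_band_bpm;
    the signal is band-passed around it and troughs of the band-passed
    trace delimit beats.  Within each beat the diastolic minimum is located
    first and the systolic maximum is searched after it, both on a
    lightly low-passed copy of the raw trace.  Beats touching invalid
    samples are discarded.  If no cardiac periodicity is detectable the
    function warns and returns an empty list.
    """
    x = signal.samples
    fs = signal.sampling_rate
    valid = mask.valid if mask is not None else np.ones(x.size, dtype=bool)
    xc = np.where(np.isfinite(x), x, 0.0)

    if not valid.any() or np.std(xc[valid]) < 0.05:
        warnings.warn("no cardiac pulsatility detectable (flat signal)", stacklevel=2)
        return []
    f0 = _dominant_cardiac_frequency(xc[valid], fs, params.hr_band_bpm)
    if f0 is None:
        warnings.warn("no cardiac periodicity found in the heart-rate band", stacklevel=2)
        return []

    lo, hi = 0.6 * f0, min(1.8 * f0, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, xc)
    troughs, _ = sps.find_peaks(-bp, distance=max(int(0.6 * fs / f0), 1))

    lp_hz = min(params.measure_lowpass_hz, 0.45 * fs)
    if lp_hz > 2.5 * f0:
        sos_lp = sps.butter(4, lp_hz, btype="lowpass", fs=fs, output="sos")
        lp = sps.sosfiltfilt(sos_lp, xc)
    else:
        lp = xc  # low sampling rates: nothing above the cardiac band anyway

    period = fs / f0
    beats: list[Beat] = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        if not (0.5 * period <= b - a <= 2.0 * period):
            continue
        if not valid[a:b].all():
            continue
        dia_rel = int(np.argmin(lp[a : a + max(int(0.5 * period), 2)]))
        dia = a + dia_rel
        if dia >= b - 1:
            continue
        sys_idx = dia + int(np.argmax(lp[dia:b]))
        seg = lp[dia:b]
        prom = params.min_prominence_mmhg
        pk_idx, _ = sps.find_peaks(seg, prominence=prom)
        sub_peaks = [
            ((dia + int(i)) / fs, float(lp[dia + int(i)] - lp[dia])) for i in pk_idx
        ]
        beats.append(
            Beat(
                start_idx=int(a),
                end_idx=int(b),
                dia_idx=int(dia),
                sys_idx=int(sys_idx),
                diastolic_min=float(lp[dia]),
                systolic_max=float(lp[sys_idx]),
                sub_peaks=sub_peaks[:3],
            )
        )
    return beats


def window_pulse_amplitude(
    beats: Sequence[Beat],
    start_s: float,
    end_s: float,
    sampling_rate: float,
    min_beats: int = 30,
) -> tuple[float, int]:
    """Mean per-beat amplitude over beats fully inside [start_s, end_s).

    Returns (icp_amp, n_beats); icp_amp is NaN (indeterminate) when fewer
    than min_beats qualify.
    """
    a, b = start_s * sampling_rate, end_s * sampling_rate
    amps = [bt.amplitude for bt in beats if bt.start_idx >= a and bt.end_idx <= b]
    if len(amps) < min_beats:
        return float("nan"), len(amps)
    return float(np.mean(amps)), len(amps)


def classify_pulse_morphology(beats: Sequence[Beat]) -> str:
    """Pulse-wave shape over a set of beats.

    abnormal iff the median P2 height exceeds the median P1 height among
    beats where both sub-peaks resolved; indeterminate when fewer than half
    the beats have two resolvable sub-peaks.
    """
    if not beats:
        return INDETERMINATE
    resolved = [bt for bt in beats if bt.p1_height is not None and bt.p2_height is not None]
    if len(resolved) < 0.5 * len(beats):
        return INDETERMINATE
    p1 = float(np.median([bt.p1_height for bt in resolved]))
    p2 = float(np.median([bt.p2_height for bt in resolved]))
    return ABNORMAL if p2 > p1 else NORMAL


def _window_mean_icp(
    cum: np.ndarray, cum_n: np.ndarray, a: int, b: int
) -> float:
    n = cum_n[b] - cum_n[a]
    return float((cum[b] - cum[a]) / n) if n > 0 else float("nan")


def _valid_cumsums(x: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.where(valid, np.where(np.isfinite(x), x, 0.0), 0.0)
    cum = np.concatenate([[0.0], np.cumsum(xs)])
    cum_n = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    return cum, cum_n


def select_baseline_window(
    signal: IcpSignal,
    mask: ArtifactMask | None,
    trains: Sequence[SlowWaveTrain],
    beats: Sequence[Beat],
    params: PulseParams = PulseParams(),
) -> PulseWindow | None:
    """The ICP_AMP1 window: stable, lowest mean ICP, no slow waves.

    Candidate 10-min windows advance by stride_s; a candidate must be
    wholly artifact-free and overlap no detected train.  The candidate with
    the lowest mean ICP wins, ties going to the earliest.  Returns None
    when no window qualifies.
    """
    fs = signal.sampling_rate
    valid = mask.valid if mask is not None else np.ones(signal.n_samples, dtype=bool)
    w = int(params.window_minutes * 60 * fs)
    stride = max(int(params.stride_s * fs), 1)
    if signal.n_samples < w:
        return None
    cum, cum_n = _valid_cumsums(signal.samples, valid)

    best: tuple[float, int] | None = None
    for a in range(0, signal.n_samples - w + 1, stride):
        b = a + w
        if cum_n[b] - cum_n[a] != w:  # any invalid sample disqualifies
            continue
        t0, t1 = a / fs, b / fs
        if any(tr.overlap_s(t0, t1) > 0 for tr in trains):
            continue
        m = _window_mean_icp(cum, cum_n, a, b)
        if best is None or m < best[0] - 1e-12:
            best = (m, a)
    if best is None:
        return None
    m, a = best
    b = a + w
    amp, n = window_pulse_amplitude(
        beats, a / fs, b / fs, fs, min_beats=params.min_beats_per_window
    )
    in_win = [bt for bt in beats if bt.start_idx >= a and bt.end_idx <= b]
    return PulseWindow(
        context=BASELINE,
        start_s=a / fs,
        end_s=b / fs,
        mean_icp=m,
        icp_amp=amp,
        n_beats=n,
        morphology=classify_pulse_morphology(in_win),
    )


def select_wavetop_window(
    signal: IcpSignal,
    mask: ArtifactMask | None,
    trains: Sequence[SlowWaveTrain],
    beats: Sequence[Beat],
    smoothed: IcpSignal,
    params: PulseParams = PulseParams(),
) -> PulseWindow | None:
    """The ICP_AMP2 window: on top of the largest-amplitude wave train.

    Among 10-min windows lying inside trains of at least window length, the
    one maximizing the mean per-wave amplitude of the waves it contains is
    chosen.  ICP_AMP is then computed over beats near the wave crests —
    those whose smoothed-channel level falls in the top tertile of the
    window.  Returns None when no train is long enough.
    """
    fs = signal.sampling_rate
    w_s = params.window_minutes * 60.0
    long_trains = [tr for tr in trains if tr.duration_s >= w_s]
    if not long_trains:
        return None

    best: tuple[float, float] | None = None  # (score, start_s)
    for tr in long_trains:
        start = tr.start_s
        while start + w_s <= tr.end_s + 1e-9:
            in_win = (tr.peak_times_s >= start) & (tr.peak_times_s < start + w_s)
            if in_win.any():
                score = float(tr.per_wave_amplitudes[in_win].mean())
                if best is None or score > best[0] + 1e-12:
                    best = (score, start)
            start += params.stride_s
    if best is None:
        return None
    _, t0 = best
    t1 = t0 + w_s
    a, b = int(t0 * fs), int(t1 * fs)
    valid = mask.valid if mask is not None else np.ones(signal.n_samples, dtype=bool)
    cum, cum_n = _valid_cumsums(signal.samples, valid)
    b = min(b, signal.n_samples)
    mean_icp = _window_mean_icp(cum, cum_n, a, b)

    in_win = [bt for bt in beats if bt.start_idx >= a and bt.end_idx <= b]
    if in_win:
        levels = np.array([smoothed.samples[bt.sys_idx] for bt in in_win])
        cut = np.quantile(levels, 1.0 - params.wavetop_tertile)
        crest = [bt for bt, lv in zip(in_win, levels) if lv >= cut]
    else:
        crest = []
    if len(crest) >= params.min_beats_per_window:
        amp = float(np.mean([bt.amplitude for bt in crest]))
        n = len(crest)
    else:
        amp, n = float("nan"), len(crest)
    return PulseWindow(
        context=WAVE_TOP,
        start_s=t0,
        end_s=t1,
        mean_icp=mean_icp,
        icp_amp=amp,
        n_beats=n,
        morphology=classify_pulse_morphology(crest),
    )
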