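"""Detection and quantification of slow ICP waves (Lundberg B- and A-waves).

B-waves are slow oscillations of intracranial pressure at 0.5–3 waves/min
sustained for at least 10 minutes; they are subdivided by amplitude into
low- (< 10 mmHg) and high-amplitude (>= 10 mmHg) classes.  Plateau (A-)
waves are abrupt, sustained elevations of tens of mmHg above the running
baseline lasting minutes.  Nocturnal burden is reported as the percentage
of the night (22:01–07:59) occupied by wave trains.

The detector works on the smoothed display channel: it is resampled to a
1 Hz slow channel, band-passed to the B-wave frequency band with a
zero-phase Butterworth filter, and successive peak–trough excursions above
an amplitude floor are merged into trains when their cycle period stays
inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import ArtifactMask, ClockPartition, DEFAULT_PARTITION, IcpSignal, partition_day_night

__all__ = [
    "SlowWaveParams",
    "PlateauParams",
    "SlowWaveTrain",
    "WavePercentages",
    "detect_slow_wave_trains",
    "classify_train",
    "detect_plateau_waves",
    "nocturnal_wave_percentages",
]

B_LOW = "B_low"
B_HIGH = "B_high"
A_PLATEAU = "A_plateau"

#: Amplitude boundary (mmHg) separating low- from high-amplitude B-waves.
HIGH_AMPLITUDE_MMHG = 10.0
#: Minimum sustained duration (s) for a B-wave train.
MIN_TRAIN_S = 600.0
#: Cycle-period band (s) corresponding to 0.5–3 waves/min.
PERIOD_BAND_S = (20.0, 120.0)


@dataclass(frozen=True)
class SlowWaveParams:
    """Tunable settings of the B-wave train detector.

    band_per_min is the passband in waves/min; min_wave_amp_mmhg is the
    smallest peak-to-trough excursion counted as a wave; merge_gap_s merges
    trains separated by short sub-threshold lulls; gap_tolerance_s is the
    longest artifact gap a train may straddle.
    """

    band_per_min: tuple[float, float] = (0.5, 3.0)
    min_wave_amp_mmhg: float = 2.0
    min_train_s: float = MIN_TRAIN_S
    merge_gap_s: float = 120.0
    gap_tolerance_s: float = 30.0
    slow_fs: float = 1.0


@dataclass(frozen=True)
class PlateauParams:
    """Plateau (A-wave) detector settings.

    rise_mmhg is the elevation above the trailing-median baseline that
    defines a plateau; the elevated segment must last between plateau_min_s
    and plateau_max_s and be genuinely flat (coefficient of variation below
    max_cv).
    """

    rise_mmhg: float = 20.0
    plateau_min_s: float = 300.0
    plateau_max_s: float = 1800.0
    baseline_window_s: float = 1800.0
    max_cv: float = 0.15
    hold_fraction: float = 0.6


@dataclass
class SlowWaveTrain:
    """A detected episode of slow-wave activity.

    Times are seconds from the start of the recording.  For B-wave classes
    the per-wave amplitudes are peak-to-trough excursions on the
    band-passed slow channel; a plateau stores its single elevation instead.
    """

    start_s: float
    end_s: float
    wave_class: str
    per_wave_amplitudes: np.ndarray
    peak_times_s: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.per_wave_amplitudes = np.asarray(self.per_wave_amplitudes, dtype=float)
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.end_s <= self.start_s:
            raise ValueError("train must have positive duration")
        if self.wave_class not in (B_LOW, B_HIGH, A_PLATEAU):
            raise ValueError(f"unknown wave_class {self.wave_class!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def wave_count(self) -> int:
        return int(self.per_wave_amplitudes.size)

    @property
    def mean_frequency_per_min(self) -> float:
        return self.wave_count / (self.duration_s / 60.0)

    @property
    def median_amplitude(self) -> float:
        return float(np.median(self.per_wave_amplitudes))

    def overlap_s(self, start_s: float, end_s: float) -> float:
        return max(0.0, min(self.end_s, end_s) - max(self.start_s, start_s))


def classify_train(per_wave_amplitudes: Sequence[float] | SlowWaveTrain) -> str:
    """B_high iff the median per-wave amplitude is >= 10 mmHg, else B_low."""
    if isinstance(per_wave_amplitudes, SlowWaveTrain):
        amps = per_wave_amplitudes.per_wave_amplitudes
    else:
        amps = np.asarray(per_wave_amplitudes, dtype=float)
    if amps.size == 0:
        raise ValueError("per_wave_amplitudes must be non-empty")
    return B_HIGH if np.median(amps) >= HIGH_AMPLITUDE_MMHG else B_LOW


def _resample_slow(
    signal: IcpSignal, mask: ArtifactMask | None, slow_fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Block-average the smoothed channel down to the slow sampling rate.

    Returns (values, valid, block-center times, fs).  A 1-s block is valid
    when at least half of its raw samples are.
    """
    fs = signal.sampling_rate
    x = signal.samples
    valid = mask.valid if mask is not None else np.ones(x.size, dtype=bool)
    block = int(round(fs / slow_fs))
    if block <= 1:
        t = signal.time_s
        return x.astype(float), valid.copy(), t, fs
    n = (x.size // block) * block
    xb = np.where(valid[:n], x[:n], np.nan).reshape(-1, block)
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(xb, axis=1)
    frac = valid[:n].reshape(-1, block).mean(axis=1)
    ok = (frac >= 0.5) & np.isfinite(vals)
    vals = np.where(np.isfinite(vals), vals, 0.0)
    t = (np.arange(vals.size) + 0.5) * block / fs
    return vals, ok, t, fs / block


def _bandpass_slow(x: np.ndarray, fs: float, band_per_min: tuple[float, float]) -> np.ndarray:
    lo, hi = band_per_min[0] / 60.0, band_per_min[1] / 60.0
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _alternating_extrema(
    bp: np.ndarray, min_wave_amp: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of troughs and peaks, forced to alternate.

    Among consecutive same-type extrema the more extreme one survives.
    Returns (indices, kinds) with kind +1 for peak, -1 for trough.
    """
    distance = max(int(round(0.6 * PERIOD_BAND_S[0] * fs)), 1)
    prom = min_wave_amp / 2.0
    peaks, _ = sps.find_peaks(bp, distance=distance, prominence=prom)
    troughs, _ = sps.find_peaks(-bp, distance=distance, prominence=prom)
    idx = np.concatenate([peaks, troughs])
    kind = np.concatenate([np.ones(peaks.size, int), -np.ones(troughs.size, int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    keep_idx: list[int] = []
    keep_kind: list[int] = []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            better = bp[i] > bp[prev] if k == 1 else bp[i] < bp[prev]
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(int(i))
            keep_kind.append(int(k))
    return np.array(keep_idx, dtype=int), np.array(keep_kind, dtype=int)


def detect_slow_wave_trains(
    smoothed: IcpSignal,
    mask: ArtifactMask | None = None,
    params: SlowWaveParams = SlowWaveParams(),
) -> list[SlowWaveTrain]:
    """Detect B-wave trains on the smoothed channel.

    Pipeline: (1) zero-phase band-pass of the 1 Hz slow channel to the
    0.5–3 waves/min band; (2) peak–trough excursions >= min_wave_amp_mmhg
    become candidate waves; (3) consecutive waves whose peak spacing lies in
    the 20–120 s period band merge into trains; (4) trains shorter than
    10 min, outside the frequency band, or straddling artifact gaps longer
    than gap_tolerance_s are rejected.  Returned trains satisfy the B-wave
    definition exactly (duration, frequency and amplitude-class rules).
    """
    if mask is not None:
        mask.check_against(smoothed)
    vals, ok, t, fs = _resample_slow(smoothed, mask, params.slow_fs)
    if vals.size < 240:  # < 4 min of slow channel: nothing sustainable
        return []
    bp = _bandpass_slow(vals, fs, params.band_per_min)
    idx, kind = _alternating_extrema(bp, params.min_wave_amp_mmhg, fs)

    invalid_cum = np.concatenate([[0.0], np.cumsum(~ok) / fs])

    def invalid_between(i: int, j: int) -> float:
        return float(invalid_cum[j] - invalid_cum[i])

    # Candidate waves: trough -> peak pairs with sufficient excursion and
    # valid extrema.  The rise must fit a half-cycle of the slowest in-band
    # wave, otherwise a quiet stretch between two episodes would pair the
    # last trough of one with the first peak of the next.
    max_rise_s = 0.75 * PERIOD_BAND_S[1]
    waves = []  # (trough_idx, peak_idx, next_trough_idx or -1, amplitude)
    for pos in range(1, idx.size):
        if kind[pos] == 1 and kind[pos - 1] == -1:
            tr, pk = idx[pos - 1], idx[pos]
            amp = bp[pk] - bp[tr]
            if amp < params.min_wave_amp_mmhg:
                continue
            if (pk - tr) / fs > max_rise_s:
                continue
            if not (ok[tr] and ok[pk]):
                continue
            nxt = idx[pos + 1] if pos + 1 < idx.size and kind[pos + 1] == -1 else -1
            waves.append((int(tr), int(pk), int(nxt), float(amp)))

    if not waves:
        return []

    lo_s, hi_s = PERIOD_BAND_S
    groups: list[list[tuple[int, int, int, float]]] = []
    current = [waves[0]]
    for w in waves[1:]:
        spacing = (w[1] - current[-1][1]) / fs
        if lo_s <= spacing <= hi_s and invalid_between(current[-1][1], w[1]) <= params.gap_tolerance_s:
            current.append(w)
        else:
            groups.append(current)
            current = [w]
    groups.append(current)

    def group_bounds(g: list[tuple[int, int, int, float]]) -> tuple[float, float]:
        start = max(t[g[0][0]], t[g[0][1]] - max_rise_s)
        last = g[-1]
        if last[2] >= 0:
            end = min(t[last[2]], t[last[1]] + max_rise_s)
        else:
            # no closing trough found: extend by half the median period
            periods = np.diff([w[1] for w in g]) / fs
            half = float(np.median(periods)) / 2 if periods.size else lo_s
            end = min(t[-1], t[last[1]] + half)
        return float(start), float(end)

    # Merge groups separated by short sub-threshold lulls, provided the
    # merged episode still satisfies the frequency band and artifact rule.
    merged: list[list[tuple[int, int, int, float]]] = []
    for g in groups:
        if merged:
            prev = merged[-1]
            gap = (t[g[0][0]] - group_bounds(prev)[1])
            if gap < params.merge_gap_s and invalid_between(prev[-1][1], g[0][1]) <= params.gap_tolerance_s:
                cand = prev + g
                s, e = t[cand[0][0]], group_bounds(cand)[1]
                freq = len(cand) / ((e - s) / 60.0)
                if params.band_per_min[0] <= freq <= params.band_per_min[1]:
                    merged[-1] = cand
                    continue
        merged.append(g)

    trains: list[SlowWaveTrain] = []
    for g in merged:
        start, end = group_bounds(g)
        dur = end - start
        if dur < params.min_train_s:
            continue
        freq = len(g) / (dur / 60.0)
        if not (params.band_per_min[0] <= freq <= params.band_per_min[1]):
            continue
        amps = np.array([w[3] for w in g])
        trains.append(
            SlowWaveTrain(
                start_s=start,
                end_s=end,
                wave_class=classify_train(amps),
                per_wave_amplitudes=amps,
                peak_times_s=t[np.array([w[1] for w in g])],
            )
        )
    return trains


def detect_plateau_waves(
    smoothed: IcpSignal,
    mask: ArtifactMask | None = None,
    params: PlateauParams = PlateauParams(),
) -> list[SlowWaveTrain]:
    """Detect plateau (A-) waves on the smoothed channel.

    A plateau is an abrupt elevation >= rise_mmhg above a trailing-median
    baseline, sustained 5–30 min with a flat top (CV < 0.15).  The baseline
    is the rolling median of the preceding 30 min; once a plateau onset is
    found the pre-onset baseline is frozen so a long plateau cannot absorb
    itself into its own baseline.
    """
    if mask is not None:
        mask.check_against(smoothed)
    vals, ok, t, fs = _resample_slow(smoothed, mask, 1.0)
    n = vals.size
    win = int(round(params.baseline_window_s * fs))
    if n < max(2 * int(params.plateau_min_s * fs), win // 3):
        return []

    import pandas as pd

    base = (
        pd.Series(np.where(ok, vals, np.nan))
        .rolling(window=win, min_periods=max(win // 6, 30))
        .median()
        .bfill()
        .to_numpy()
    )
    elev = vals - base

    hold = params.hold_fraction * params.rise_mmhg
    plateaus: list[SlowWaveTrain] = []
    i = 0
    while i < n:
        if elev[i] >= params.rise_mmhg and ok[i]:
            b0 = base[i]
            j = i
            while j + 1 < n and vals[j + 1] >= b0 + hold:
                j += 1
            k = i
            while k - 1 >= 0 and vals[k - 1] >= b0 + hold:
                k -= 1
            dur = (j - k + 1) / fs
            seg = vals[k : j + 1][ok[k : j + 1]]
            if (
                params.plateau_min_s <= dur <= params.plateau_max_s
                and seg.size
                and abs(seg.mean()) > 0
                and seg.std() / abs(seg.mean()) < params.max_cv
            ):
                plateaus.append(
                    SlowWaveTrain(
                        start_s=float(t[k]),
                        end_s=float(t[j]),
                        wave_class=A_PLATEAU,
                        per_wave_amplitudes=np.array([float(np.median(seg) - b0)]),
                        peak_times_s=np.array([float(t[(k + j) // 2])]),
                    )
                )
            i = j + 1
        else:
            i += 1
    return plateaus


@dataclass(frozen=True)
class WavePercentages:
    """Share of the night occupied by slow-wave activity, in percent.

    pct_b_total is the sum of the low- and high-amplitude shares (trains
    never overlap); plateau_present records whether any A-wave touched the
    night.  When a recording spans several nights the per-night percentages
    are averaged.
    """

    pct_b_low: float
    pct_b_high: float
    plateau_present: bool
    n_nights: int = 1

    @property
    def pct_b_total(self) -> float:
        return self.pct_b_low + self.pct_b_high


def _night_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of nocturnal samples as half-open index intervals."""
    noct = labels == "nocturnal"
    if not noct.any():
        return []
    d = np.diff(noct.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if noct[0]:
        starts.insert(0, 0)
    if noct[-1]:
        ends.append(noct.size)
    return list(zip(starts, ends))


def nocturnal_wave_percentages(
    trains: Sequence[SlowWaveTrain],
    signal: IcpSignal,
    partition: ClockPartition = DEFAULT_PARTITION,
    strict_10h: bool = False,
) -> WavePercentages:
    """Percentage of the night occupied by B-wave trains.

    For each nocturnal window in the recording the summed train time inside
    it is divided by the window duration (or by a fixed 600 min when
    strict_10h reproduces the nominal "10-h night"); multiple nights are
    averaged.  Plateau waves set plateau_present but are not counted in the
    B-wave percentages.
    """
    labels = partition_day_night(signal, partition)
    runs = _night_runs(labels)
    fs = signal.sampling_rate
    if not runs:
        return WavePercentages(0.0, 0.0, False, n_nights=0)

    per_night_low, per_night_high = [], []
    plateau_present = False
    for a, b in runs:
        t0, t1 = a / fs, b / fs
        denom = 600.0 * 60.0 if strict_10h else (t1 - t0)
        low = sum(tr.overlap_s(t0, t1) for tr in trains if tr.wave_class == B_LOW)
        high = sum(tr.overlap_s(t0, t1) for tr in trains if tr.wave_class == B_HIGH)
        plateau_present |= any(
            tr.overlap_s(t0, t1) > 0 for tr in trains if tr.wave_class == A_PLATEAU
        )
        per_night_low.append(100.0 * low / denom)
        per_night_high.append(100.0 * high / denom)
    return WavePercentages(
        pct_b_low=float(np.mean(per_night_low)),
        pct_b_high=float(np.mean(per_night_high)),
        plateau_present=bool(plateau_present),
        n_nights=len(runs),
    )
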