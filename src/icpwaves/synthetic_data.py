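"""Seeded synthetic ICP recordings with ground-truth annotations.

The generator composes a pressure trace the way overnight pediatric ICP
recordings look: a baseline level, slow-wave trains (sinusoidal or
ramp-like oscillations at 0.5–3 waves/min riding upward from baseline),
occasional plateau elevations, a cardiac pulse wave built from three
sub-peak bumps (P1/P2/P3) with a configurable P2/P1 ratio, respiratory
modulation, band-limited noise, and injected motion/dropout artifacts.
Cardiac pulse amplitude optionally scales up on wave tops (amp_coupling),
reproducing the observed rise of pulsatility during B-wave activity.

Every draw is reproducible from the spec's seed, and the accompanying
:class:`GroundTruth` records exactly what was put in, so detectors can be
scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics_summary import classify_developmental_delay, evaluate_shunt_criteria
from .signal_io import ClockPartition, DEFAULT_PARTITION, IcpSignal, partition_day_night
from .slow_waves import A_PLATEAU, B_HIGH, B_LOW, HIGH_AMPLITUDE_MMHG, _night_runs

__all__ = [
    "BWaveTrainSpec",
    "PlateauSpec",
    "ArtifactSpec",
    "SimulationSpec",
    "GroundTruth",
    "simulate_icp_recording",
    "simulate_cohort",
]

RAMP_S = 30.0  # on/off ramp of slow-wave envelopes and plateau edges


@dataclass(frozen=True)
class BWaveTrainSpec:
    """One slow-wave train: starts at start_s, lasts duration_s, oscillates
    at freq_per_min with the given peak-to-trough amplitude (mmHg)."""

    start_s: float
    duration_s: float
    freq_per_min: float
    amplitude: float
    waveform: str = "sine"  # sine | ramp

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def qualifies_as_b(self) -> bool:
        """Whether this train meets the B-wave definition (0.5–3 waves/min
        sustained >= 10 min); out-of-band or too-short segments are stressor
        content a detector must NOT report."""
        return 0.5 <= self.freq_per_min <= 3.0 and self.duration_s >= 600.0

    @property
    def true_class(self) -> str:
        if not self.qualifies_as_b:
            return "non_B"
        return B_HIGH if self.amplitude >= HIGH_AMPLITUDE_MMHG else B_LOW


@dataclass(frozen=True)
class PlateauSpec:
    """A plateau (A-) wave: a trapezoidal rise of rise_mmhg above baseline."""

    start_s: float
    duration_s: float
    rise_mmhg: float = 25.0

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ArtifactSpec:
    """An injected artifact: kind is 'spike' (violent transducer motion) or
    'dropout' (flat zero segment, e.g. disconnection)."""

    kind: str
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of one synthetic recording.

    Defaults describe a quiet overnight pediatric recording: 200 Hz
    sampling starting 20:00, baseline 12 mmHg, heart rate 120 bpm with a
    4 mmHg pulse of normal morphology (P2/P1 = 0.8), gentle respiratory
    modulation and 0.2 mmHg band-limited noise.  Waves, plateaus, coupling
    and artifacts are opt-in.
    """

    patient_id: str = "sim"
    duration_s: float = 3600.0
    sampling_rate: float = 200.0
    start_clock: datetime = datetime(2000, 1, 1, 20, 0, 0)
    baseline_icp: float = 12.0
    heart_rate_bpm: float = 120.0
    pulse_amplitude: float = 4.0
    p2_over_p1: float = 0.8
    p3_over_p1: float = 0.5
    respiratory_rate_per_min: float = 30.0
    respiratory_amp: float = 1.0
    noise_sd: float = 0.2
    b_wave_trains: tuple[BWaveTrainSpec, ...] = ()
    plateau_waves: tuple[PlateauSpec, ...] = ()
    amp_coupling: float = 1.0
    artifact_events: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "heart_rate_bpm", "respiratory_rate_per_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        object.__setattr__(self, "b_wave_trains", tuple(self.b_wave_trains))
        object.__setattr__(self, "plateau_waves", tuple(self.plateau_waves))
        object.__setattr__(self, "artifact_events", tuple(self.artifact_events))
        for tr in self.b_wave_trains:
            if not (0 < tr.freq_per_min <= 6):
                raise ValueError(f"train frequency {tr.freq_per_min}/min outside (0, 6]")
            for pl in self.plateau_waves:
                if min(tr.end_s, pl.end_s) > max(tr.start_s, pl.start_s):
                    raise ValueError(
                        "overlapping plateau and B-wave train specifications make the "
                        "ground truth ambiguous"
                    )


@dataclass
class GroundTruth:
    """What the generator actually put into the signal.

    Intervals are (start_s, end_s) pairs; classes follow the 10 mmHg
    amplitude rule.  Mean ICPs are computed from the clean (pre-artifact)
    trace; pulse amplitudes are the configured per-beat values at baseline
    and on wave tops.
    """

    train_intervals: list[tuple[float, float, str]]
    plateau_intervals: list[tuple[float, float]]
    artifact_intervals: list[tuple[float, float, str]]
    pulse_amp_baseline: float
    pulse_amp_wavetop: float
    mean_icp_total: float
    mean_icp_diurnal: float
    mean_icp_nocturnal: float
    pct_b_low: float
    pct_b_high: float

    @property
    def pct_b_total(self) -> float:
        return self.pct_b_low + self.pct_b_high


def _ramp_envelope(t: np.ndarray, start: float, end: float, ramp: float = RAMP_S) -> np.ndarray:
    """Smooth 0->1->0 envelope over [start, end] with raised-cosine ramps."""
    env = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    ti = t[inside]
    up = np.clip((ti - start) / ramp, 0, 1)
    down = np.clip((end - ti) / ramp, 0, 1)
    env[inside] = 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))
    return env


def _beat_template(phase: np.ndarray, p2_over_p1: float, p3_over_p1: float) -> np.ndarray:
    """Pulse-wave shape on phase in [0, 1): three Gaussian sub-peak bumps
    (P1, P2, P3), normalized so max - min = 1 and min = 0."""

    def bumps(ph: np.ndarray) -> np.ndarray:
        out = np.zeros_like(ph)
        for center, width, height in (
            (0.15, 0.055, 1.0),
            (0.40, 0.085, p2_over_p1),
            (0.65, 0.085, p3_over_p1),
        ):
            out += height * np.exp(-0.5 * ((ph - center) / width) ** 2)
        return out

    grid = bumps(np.linspace(0, 1, 2001))
    lo, hi = grid.min(), grid.max()
    return (bumps(phase) - lo) / (hi - lo)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Gaussian noise low-passed at 10 Hz and rescaled to the target sd —
    sensor noise in ICP traces is band-limited, not white at 200 Hz."""
    if sd <= 0:
        return np.zeros(n)
    from scipy import signal as sps

    white = rng.standard_normal(n)
    cutoff = min(10.0, 0.4 * fs)
    sos = sps.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else np.zeros(n)


def _stratum_means(
    clean: np.ndarray, signal: IcpSignal, partition: ClockPartition
) -> tuple[float, float, float]:
    labels = partition_day_night(signal, partition)
    total = float(clean.mean())
    d = labels == "diurnal"
    n = labels == "nocturnal"
    diurnal = float(clean[d].mean()) if d.any() else float("nan")
    nocturnal = float(clean[n].mean()) if n.any() else float("nan")
    return total, diurnal, nocturnal


def _true_wave_percentages(
    spec: SimulationSpec, signal: IcpSignal, partition: ClockPartition
) -> tuple[float, float]:
    labels = partition_day_night(signal, partition)
    runs = _night_runs(labels)
    fs = signal.sampling_rate
    if not runs:
        return 0.0, 0.0
    low_pcts, high_pcts = [], []
    for a, b in runs:
        t0, t1 = a / fs, b / fs
        denom = t1 - t0
        low = sum(
            max(0.0, min(tr.end_s, t1) - max(tr.start_s, t0))
            for tr in spec.b_wave_trains
            if tr.true_class == B_LOW
        )
        high = sum(
            max(0.0, min(tr.end_s, t1) - max(tr.start_s, t0))
            for tr in spec.b_wave_trains
            if tr.true_class == B_HIGH
        )
        low_pcts.append(100.0 * low / denom)
        high_pcts.append(100.0 * high / denom)
    return float(np.mean(low_pcts)), float(np.mean(high_pcts))


def simulate_icp_recording(
    spec: SimulationSpec, partition: ClockPartition = DEFAULT_PARTITION
) -> tuple[IcpSignal, GroundTruth]:
    """Generate one annotated recording.

    The trace is baseline + slow-wave trains + plateaus + cardiac pulse +
    respiration + band-limited noise, with artifacts stamped in last.
    Identical specs (same seed) produce bit-identical signals.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    from scipy import signal as sps

    # --- slow-wave component; activation tracks the instantaneous wave
    # height in [0, 1] for pulse-amplitude coupling
    slow = np.zeros(n)
    activation = np.zeros(n)
    for tr in spec.b_wave_trains:
        env = _ramp_envelope(t, tr.start_s, tr.end_s)
        tau = t - tr.start_s
        f = tr.freq_per_min / 60.0
        if tr.waveform == "sine":
            osc = 0.5 - 0.5 * np.cos(2 * np.pi * f * tau)  # starts at trough
        elif tr.waveform == "ramp":
            osc = 0.5 + 0.5 * sps.sawtooth(2 * np.pi * f * tau, width=0.85)
        else:
            raise ValueError(f"unknown waveform {tr.waveform!r}")
        contrib = tr.amplitude * env * osc
        slow += contrib
        activation = np.maximum(activation, env * osc)

    plateau = np.zeros(n)
    for pl in spec.plateau_waves:
        env = _ramp_envelope(t, pl.start_s, pl.end_s)
        plateau += pl.rise_mmhg * np.minimum(env * 4, 1.0)  # fast rise, flat top
        activation = np.maximum(activation, np.minimum(env * 4, 1.0))

    # --- cardiac component: beat onsets with mild cycle-length jitter
    mean_period = 60.0 / spec.heart_rate_bpm
    n_beats = int(np.ceil(spec.duration_s / mean_period)) + 2
    periods = mean_period * (1 + 0.01 * rng.standard_normal(n_beats))
    onsets = np.concatenate([[0.0], np.cumsum(periods)])
    k = np.searchsorted(onsets, t, side="right") - 1
    phase = (t - onsets[k]) / periods[np.minimum(k, n_beats - 1)]
    template = _beat_template(np.clip(phase, 0, 1), spec.p2_over_p1, spec.p3_over_p1)
    beat_amp = spec.pulse_amplitude * (1 + (spec.amp_coupling - 1) * activation)
    cardiac = beat_amp * template

    resp = 0.5 * spec.respiratory_amp * np.sin(
        2 * np.pi * (spec.respiratory_rate_per_min / 60.0) * t
    )
    noise = _bandlimited_noise(rng, n, fs, spec.noise_sd)

    clean = spec.baseline_icp + slow + plateau + cardiac + resp + noise

    x = clean.copy()
    artifact_intervals = []
    for ev in spec.artifact_events:
        a, b = int(ev.start_s * fs), min(int(ev.end_s * fs), n)
        if b <= a:
            continue
        if ev.kind == "spike":
            burst = 90.0 * np.sign(np.sin(2 * np.pi * 7.0 * t[a:b]))
            x[a:b] = spec.baseline_icp + burst
        elif ev.kind == "dropout":
            x[a:b] = 0.0
        else:
            raise ValueError(f"unknown artifact kind {ev.kind!r}")
        artifact_intervals.append((ev.start_s, ev.end_s, ev.kind))

    signal = IcpSignal(
        patient_id=spec.patient_id,
        samples=x,
        sampling_rate=fs,
        start_clock=spec.start_clock,
    )
    total, diurnal, nocturnal = _stratum_means(clean, signal, partition)
    pct_low, pct_high = _true_wave_percentages(spec, signal, partition)
    truth = GroundTruth(
        train_intervals=[(tr.start_s, tr.end_s, tr.true_class) for tr in spec.b_wave_trains],
        plateau_intervals=[(pl.start_s, pl.end_s) for pl in spec.plateau_waves],
        artifact_intervals=artifact_intervals,
        pulse_amp_baseline=spec.pulse_amplitude,
        pulse_amp_wavetop=spec.pulse_amplitude * spec.amp_coupling,
        mean_icp_total=total,
        mean_icp_diurnal=diurnal,
        mean_icp_nocturnal=nocturnal,
        pct_b_low=pct_low,
        pct_b_high=pct_high,
    )
    return signal, truth


# ---------------------------------------------------------------------------
# cohort-level generation

#: Distribution choices mirror the published cohort's ranges: mean ICP
#: spanning ~6.7–29 mmHg, nocturnal B-wave burden ~23–75%, ICP_AMP1 around
#: 4 mmHg, ICP_AMP2 around 11 mmHg, Evans' index 0.23–0.34.
DEFAULT_COHORT_PARAMS: dict = {
    "p_boy": 22 / 36,
    "p_preterm": 16 / 36,
    "p_isolated": 23 / 36,
    "mean_icp_range": (6.7, 29.0),
    "pct_b_total_range": (23.2, 75.0),
    "low_share_range": (0.4, 0.8),
    "amp1_log_mean": np.log(4.0),
    "amp1_log_sd": 0.25,
    "amp1_range": (2.8, 9.0),
    "amp2_log_mean": np.log(11.0),
    "amp2_log_sd": 0.3,
    "amp2_range": (5.5, 21.0),
    "evans_range": (0.23, 0.34),
    "p_plateau": 3 / 36,
}


def simulate_cohort(
    n_patients: int,
    distribution_params: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SimulationSpec]]:
    """Draw a reproducible cohort of per-patient records and matching
    recording specs.

    Returns a per-patient table (demographics, imaging, ICP metrics and
    the shunt decision) ready for the cohort comparison machinery, plus one
    :class:`SimulationSpec` per patient so full signals can be generated on
    demand (they are not materialized here; a cohort of full-night traces
    is large).
    """
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    p = dict(DEFAULT_COHORT_PARAMS)
    if distribution_params:
        p.update(distribution_params)
    rng = np.random.default_rng(seed)

    rows = []
    specs: list[SimulationSpec] = []
    for i in range(n_patients):
        boy = rng.random() < p["p_boy"]
        preterm = rng.random() < p["p_preterm"]
        ga = rng.uniform(25, 36.9) if preterm else rng.uniform(37, 41)
        bw = float(np.clip(rng.normal(2.0 if preterm else 3.3, 0.5), 0.5, 4.6))
        isolated = rng.random() < p["p_isolated"]
        age = float(np.clip(rng.gamma(3.5, 6.8), 6, 65))

        mean_icp = rng.uniform(*p["mean_icp_range"])
        pct_total = rng.uniform(*p["pct_b_total_range"])
        low_share = rng.uniform(*p["low_share_range"])
        pct_low = pct_total * low_share
        pct_high = pct_total - pct_low
        amp1 = float(np.clip(rng.lognormal(p["amp1_log_mean"], p["amp1_log_sd"]), *p["amp1_range"]))
        amp2 = float(np.clip(rng.lognormal(p["amp2_log_mean"], p["amp2_log_sd"]), *p["amp2_range"]))
        plateau_present = rng.random() < p["p_plateau"]

        scaled = {
            "cognitive": float(np.clip(np.round(rng.normal(8, 3)), 1, 19)),
            "gross_motor": float(np.clip(np.round(rng.normal(8, 3)), 1, 19)),
        }
        composite = {"language_composite": float(np.clip(np.round(rng.normal(90, 15)), 40, 160))}
        delay = classify_developmental_delay(scaled, composite)

        row = {
            "patient_id": f"sim{i:03d}",
            "sex": "boy" if boy else "girl",
            "gestational_age_weeks": round(ga, 1),
            "preterm": bool(ga < 37),
            "birth_weight_kg": round(bw, 2),
            "head_circumference_cm": round(float(rng.normal(34.3, 3.0)), 1),
            "age_at_monitoring_months": round(age, 1),
            "group": "isolated_BEH" if isolated else "BEH_associated",
            "evans_index": round(rng.uniform(*p["evans_range"]), 3),
            "third_ventricle_mm": round(rng.uniform(3.0, 14.0), 1),
            "craniocortical_mm": round(rng.uniform(7.0, 18.0), 1),
            "sinocortical_mm": round(rng.uniform(4.6, 20.7), 1),
            "interhemispheric_mm": round(rng.uniform(6.0, 24.7), 1),
            "mean_icp_total": round(mean_icp, 2),
            "mean_icp_diurnal": round(mean_icp + rng.normal(0, 1.0), 2),
            "mean_icp_nocturnal": round(mean_icp + rng.normal(1.0, 1.0), 2),
            "pct_b_low": round(pct_low, 2),
            "pct_b_high": round(pct_high, 2),
            "pct_b_total": round(pct_total, 2),
            "plateau_present": bool(plateau_present),
            "icp_amp1": round(amp1, 2),
            "icp_amp2": round(amp2, 2),
            "delay_any": bool(any(delay.values())),
        }
        decision = evaluate_shunt_criteria(row)
        row["shunt_criteria_met"] = decision.met
        row["criterion_triggered"] = decision.criterion
        rows.append(row)

        # matching overnight recording spec (night 22:01–07:59 within a
        # 20:00-start recording); two trains reproduce the drawn burden
        night_len = 9 * 3600
        amp_low = float(rng.uniform(4, 8))
        amp_high = float(rng.uniform(11, 16))
        t_low = BWaveTrainSpec(
            start_s=2.5 * 3600,
            duration_s=max(600.0, pct_low / 100.0 * night_len),
            freq_per_min=float(rng.uniform(0.7, 2.0)),
            amplitude=amp_low,
        )
        t_high = BWaveTrainSpec(
            start_s=t_low.end_s + 1800,
            duration_s=max(600.0, pct_high / 100.0 * night_len),
            freq_per_min=float(rng.uniform(0.7, 2.0)),
            amplitude=amp_high,
        )
        specs.append(
            SimulationSpec(
                patient_id=row["patient_id"],
                duration_s=12 * 3600,
                sampling_rate=100.0,
                baseline_icp=mean_icp,
                pulse_amplitude=amp1,
                amp_coupling=amp2 / amp1,
                b_wave_trains=(t_low, t_high),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return pd.DataFrame(rows), specs
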