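"""Reading, writing and clock handling for continuous ICP recordings.

The central container is :class:`IcpSignal`, a uniformly sampled pressure
trace (mmHg) with a wall-clock anchor.  Every downstream stage — smoothing,
artifact masking, slow-wave detection, pulse analysis — consumes this object.
Clock context matters because the summary metrics are stratified into a
diurnal window (08:00–22:00 local clock) and its nocturnal complement
(22:01–07:59), the convention used for overnight monitoring in pediatric
hydrocephalus work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IcpSignal",
    "ArtifactMask",
    "ClockPartition",
    "DEFAULT_PARTITION",
    "read_signal_csv",
    "read_signal_edf",
    "write_signal_csv",
    "partition_day_night",
    "write_metrics_table",
    "read_metrics_table",
    "METRICS_COLUMNS",
]

SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class IcpSignal:
    """A uniformly sampled intracranial-pressure trace.

    Parameters
    ----------
    patient_id : str
        Opaque identifier carried through to the metrics table.
    samples : ndarray
        Pressure in mmHg, one value per sample.  Non-finite values are
        permitted here (they are flagged by the artifact detector, never
        silently dropped), but at least one sample must be finite.
    sampling_rate : float
        Samples per second; clinical acquisitions use 200 Hz.
    start_clock : datetime
        Naive local wall-clock time of the first sample.
    channel_label : str
        ``"raw"`` for the acquired trace, ``"smoothed"`` for the
        slow-wave display channel produced by the Bartlett filter.
    """

    patient_id: str
    samples: np.ndarray
    sampling_rate: float = 200.0
    start_clock: datetime = datetime(2000, 1, 1, 20, 0, 0)
    channel_label: str = "raw"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.isfinite(samples).any():
            raise ValueError("signal contains no finite samples")
        if self.channel_label not in ("raw", "smoothed"):
            raise ValueError(f"unknown channel_label {self.channel_label!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        """Sample times in seconds since ``start_clock``."""
        return np.arange(self.n_samples) / self.sampling_rate

    def seconds_of_day(self) -> np.ndarray:
        """Clock time of each sample, as seconds past local midnight."""
        t0 = (
            self.start_clock.hour * 3600
            + self.start_clock.minute * 60
            + self.start_clock.second
            + self.start_clock.microsecond / 1e6
        )
        return (t0 + self.time_s) % SECONDS_PER_DAY

    def clock_at(self, sample_index: int) -> datetime:
        return self.start_clock + timedelta(seconds=sample_index / self.sampling_rate)

    def with_samples(self, samples: np.ndarray, channel_label: str | None = None) -> "IcpSignal":
        return IcpSignal(
            patient_id=self.patient_id,
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            start_clock=self.start_clock,
            channel_label=channel_label or self.channel_label,
        )


@dataclass(frozen=True)
class ArtifactMask:
    """Per-sample validity flags aligned with an :class:`IcpSignal`.

    ``valid[i]`` is True where sample ``i`` is usable.  Operationalizes the
    "artifact-free" window selection that was done by eye in the clinical
    workflow.
    """

    valid: np.ndarray

    def __post_init__(self) -> None:
        valid = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "valid", valid)
        if valid.ndim != 1:
            raise ValueError("valid must be 1-D")

    def __len__(self) -> int:
        return self.valid.size

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0

    @classmethod
    def all_valid(cls, n: int) -> "ArtifactMask":
        return cls(np.ones(n, dtype=bool))

    def check_against(self, signal: IcpSignal) -> None:
        if len(self) != signal.n_samples:
            raise ValueError(
                f"mask length {len(self)} does not match signal length {signal.n_samples}"
            )


@dataclass(frozen=True)
class ClockPartition:
    """Half-open diurnal window on the local clock; night is the complement.

    The diurnal window [08:00:00, 22:01:00) follows the convention that the
    day stratum runs 08:00–22:00 and the night stratum 22:01–07:59.  The
    half-open bound assigns the printed-but-ambiguous minute 22:00:xx to the
    day so that every sample carries exactly one label.
    """

    day_start: time = time(8, 0, 0)
    day_end: time = time(22, 1, 0)

    def _bounds_s(self) -> tuple[float, float]:
        a = self.day_start.hour * 3600 + self.day_start.minute * 60 + self.day_start.second
        b = self.day_end.hour * 3600 + self.day_end.minute * 60 + self.day_end.second
        return float(a), float(b)

    def is_diurnal(self, seconds_of_day: np.ndarray) -> np.ndarray:
        a, b = self._bounds_s()
        s = np.asarray(seconds_of_day, dtype=float)
        if a <= b:
            return (s >= a) & (s < b)
        return (s >= a) | (s < b)

    @property
    def night_duration_s(self) -> float:
        """Length of one nocturnal window (complement of the day window)."""
        a, b = self._bounds_s()
        day = (b - a) % SECONDS_PER_DAY
        return SECONDS_PER_DAY - day


DEFAULT_PARTITION = ClockPartition()


def partition_day_night(
    signal: IcpSignal, partition: ClockPartition = DEFAULT_PARTITION
) -> np.ndarray:
    """Label every sample ``'diurnal'`` or ``'nocturnal'``.

    Returns an array of dtype ``<U9`` covering all samples; the two labels
    partition the recording exhaustively.
    """
    diurnal = partition.is_diurnal(signal.seconds_of_day())
    return np.where(diurnal, "diurnal", "nocturnal")


def read_signal_csv(
    path: str | Path,
    sampling_rate: float = 200.0,
    start_clock: datetime | str = datetime(2000, 1, 1, 20, 0, 0),
    patient_id: str | None = None,
    pressure_column: str = "icp_mmhg",
    time_column: str = "time_s",
) -> IcpSignal:
    """Load an ICP trace from CSV.

    The file must contain a pressure column (mmHg); a ``time_s`` column is
    optional and, when present, must be monotonically increasing and
    consistent with ``sampling_rate``.  Non-finite pressure values are kept
    in place (the artifact mask flags them later) rather than dropped, so
    sample indices stay aligned with the clock.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip", skip_blank_lines=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: file has no data rows")
    if pressure_column not in df.columns:
        raise ValueError(
            f"{path}: missing pressure column {pressure_column!r}; found {list(df.columns)}"
        )
    if time_column in df.columns:
        t = df[time_column].to_numpy(dtype=float)
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError(f"{path}: timestamps in {time_column!r} are not monotonic")
            implied = 1.0 / np.median(dt)
            if not np.isclose(implied, sampling_rate, rtol=0.01):
                raise ValueError(
                    f"{path}: timestamps imply {implied:.3f} Hz but sampling_rate={sampling_rate}"
                )
    if isinstance(start_clock, str):
        start_clock = datetime.fromisoformat(start_clock)
    return IcpSignal(
        patient_id=patient_id or path.stem,
        samples=df[pressure_column].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
        start_clock=start_clock,
    )


def write_signal_csv(signal: IcpSignal, path: str | Path, include_time: bool = True) -> Path:
    """Write a signal to CSV (columns ``time_s``, ``icp_mmhg``); round-trips
    bit-exactly through :func:`read_signal_csv` via full-precision floats."""
    path = Path(path)
    cols = {}
    if include_time:
        cols["time_s"] = signal.time_s
    cols["icp_mmhg"] = signal.samples
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


def read_signal_edf(
    path: str | Path,
    channel_label: str,
    patient_id: str | None = None,
) -> IcpSignal:
    """Load an ICP channel from an EDF file (requires the optional mne
    dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), include=[channel_label], preload=True, verbose="error")
    data = raw.get_data(picks=[channel_label])[0]
    start = raw.info["meas_date"]
    start_clock = (
        datetime(2000, 1, 1, 20, 0, 0) if start is None else start.replace(tzinfo=None)
    )
    return IcpSignal(
        patient_id=patient_id or Path(path).stem,
        samples=data,
        sampling_rate=float(raw.info["sfreq"]),
        start_clock=start_clock,
    )


#: Fixed column order of the per-patient metrics table (the data dictionary).
METRICS_COLUMNS = [
    "patient_id",
    "mean_icp_total",
    "mean_icp_diurnal",
    "mean_icp_nocturnal",
    "pct_b_low",
    "pct_b_high",
    "pct_b_total",
    "plateau_present",
    "icp_amp1",
    "icp_amp2",
    "morphology_baseline",
    "morphology_wavetop",
    "shunt_criteria_met",
    "criterion_triggered",
]


def write_metrics_table(records: Sequence, path: str | Path) -> Path:
    """Write per-patient metrics to CSV, one row per patient.

    ``records`` may be :class:`~icpwaves.metrics_summary.PatientMetrics`
    objects or dicts with the same keys.  An empty list yields a header-only
    file, and a write-then-read round-trip reproduces the input values.
    """
    path = Path(path)
    rows = []
    for rec in records:
        d = rec if isinstance(rec, dict) else rec.to_dict()
        rows.append({c: d.get(c) for c in METRICS_COLUMNS})
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics table written by :func:`write_metrics_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metrics table missing columns {missing}")
    return df[METRICS_COLUMNS]
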