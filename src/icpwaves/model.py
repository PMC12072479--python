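"""Model/Results interface over the analysis pipeline.

:class:`RecordingAnalysis` is built from one ICP recording and a
configuration; ``fit()`` runs artifact masking, Bartlett smoothing,
slow-wave and plateau detection, beat segmentation, the two
pulse-amplitude windows and the shunt rule, returning a
:class:`RecordingResults` that carries the per-patient metrics, the
detected objects and a printable summary.  :class:`CohortComparison` plays
the same role for a per-patient table, producing the two-group comparison
rows of a cohort report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort_stats, pulse_analysis, slow_waves
from .config import AnalysisConfig
from .metrics_summary import PatientMetrics, compute_mean_icp, evaluate_shunt_criteria
from .preprocess import detect_artifacts, smooth_bartlett
from .signal_io import (
    ArtifactMask,
    ClockPartition,
    DEFAULT_PARTITION,
    IcpSignal,
    partition_day_night,
    read_signal_csv,
)

__all__ = ["RecordingAnalysis", "RecordingResults", "CohortComparison", "CohortResults"]


class RecordingAnalysis:
    """Full analysis of one continuous ICP recording.

    Parameters
    ----------
    signal : IcpSignal
        The raw pressure trace.
    config : AnalysisConfig, optional
        Stage settings; defaults reproduce the standard workflow
        (255-sample Bartlett channel, 0.5–3 waves/min B-wave band,
        10-minute pulse windows, 5 mmHg amplitude threshold).
    partition : ClockPartition, optional
        Day/night convention; defaults to diurnal [08:00, 22:01).
    """

    def __init__(
        self,
        signal: IcpSignal,
        config: AnalysisConfig | None = None,
        partition: ClockPartition = DEFAULT_PARTITION,
    ) -> None:
        self.signal = signal
        self.config = config or AnalysisConfig()
        self.partition = partition

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        sampling_rate: float = 200.0,
        start_clock: datetime | str = datetime(2000, 1, 1, 20, 0, 0),
        config: AnalysisConfig | None = None,
    ) -> "RecordingAnalysis":
        return cls(read_signal_csv(path, sampling_rate, start_clock), config=config)

    def fit(self) -> "RecordingResults":
        cfg = self.config
        sig = self.signal
        mask = detect_artifacts(sig, cfg.artifacts)
        smoothed = smooth_bartlett(sig, cfg.filter)
        labels = partition_day_night(sig, self.partition)

        trains = slow_waves.detect_slow_wave_trains(smoothed, mask, cfg.slow_waves)
        plateaus = slow_waves.detect_plateau_waves(smoothed, mask, cfg.plateau)
        all_trains = list(trains) + list(plateaus)
        pct = slow_waves.nocturnal_wave_percentages(
            all_trains, sig, self.partition, strict_10h=cfg.strict_10h
        )

        beats = pulse_analysis.detect_beats(sig, mask, cfg.pulse)
        win1 = pulse_analysis.select_baseline_window(sig, mask, all_trains, beats, cfg.pulse)
        win2 = pulse_analysis.select_wavetop_window(
            sig, mask, all_trains, beats, smoothed, cfg.pulse
        )

        total, diurnal, nocturnal = compute_mean_icp(sig, mask, labels)
        metrics = PatientMetrics(
            patient_id=sig.patient_id,
            mean_icp_total=total,
            mean_icp_diurnal=diurnal,
            mean_icp_nocturnal=nocturnal,
            pct_b_low=pct.pct_b_low,
            pct_b_high=pct.pct_b_high,
            pct_b_total=pct.pct_b_total,
            plateau_present=pct.plateau_present,
            icp_amp1=win1.icp_amp if win1 is not None else float("nan"),
            icp_amp2=win2.icp_amp if win2 is not None else float("nan"),
            morphology_baseline=win1.morphology if win1 is not None else "indeterminate",
            morphology_wavetop=win2.morphology if win2 is not None else "indeterminate",
        )

        decision_metrics = metrics.to_dict()
        if cfg.criterion_b_basis == "total":
            # re-express the low-amplitude burden as percent of the whole
            # recording rather than of the night
            noct_s = float((labels == "nocturnal").sum()) / sig.sampling_rate
            decision_metrics["pct_b_low"] = (
                metrics.pct_b_low * noct_s / sig.duration_s if sig.duration_s else 0.0
            )
        decision = evaluate_shunt_criteria(decision_metrics)
        metrics.shunt_criteria_met = decision.met
        metrics.criterion_triggered = decision.criterion

        return RecordingResults(
            model=self,
            metrics=metrics,
            mask=mask,
            smoothed=smoothed,
            labels=labels,
            trains=list(trains),
            plateaus=list(plateaus),
            beats=beats,
            baseline_window=win1,
            wavetop_window=win2,
            percentages=pct,
        )


@dataclass
class RecordingResults:
    """Everything :meth:`RecordingAnalysis.fit` computed."""

    model: RecordingAnalysis
    metrics: PatientMetrics
    mask: ArtifactMask
    smoothed: IcpSignal
    labels: np.ndarray
    trains: list
    plateaus: list
    beats: list
    baseline_window: pulse_analysis.PulseWindow | None
    wavetop_window: pulse_analysis.PulseWindow | None
    percentages: slow_waves.WavePercentages

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.metrics.to_dict()])

    def summary(self) -> str:
        m = self.metrics
        sig = self.model.signal
        amp_thr = self.model.config.pulse.elevated_amp_mmhg

        def fmt(v: float, unit: str = "") -> str:
            return f"{v:.1f}{unit}" if np.isfinite(v) else "indeterminate"

        lines = [
            "ICP recording analysis",
            "=" * 54,
            f"patient            {m.patient_id}",
            f"duration           {sig.duration_s / 3600:.1f} h at {sig.sampling_rate:g} Hz",
            f"valid samples      {100 * self.mask.valid_fraction:.1f}%",
            "-" * 54,
            f"mean ICP           total {fmt(m.mean_icp_total, ' mmHg')}, "
            f"day {fmt(m.mean_icp_diurnal)}, night {fmt(m.mean_icp_nocturnal)}",
            f"B-wave trains      {len(self.trains)} "
            f"(low {sum(t.wave_class == slow_waves.B_LOW for t in self.trains)}, "
            f"high {sum(t.wave_class == slow_waves.B_HIGH for t in self.trains)}); "
            f"plateau waves {len(self.plateaus)}",
            f"nocturnal B-waves  low {m.pct_b_low:.1f}%, high {m.pct_b_high:.1f}%, "
            f"total {m.pct_b_total:.1f}% of the night",
            f"ICP_AMP1           {fmt(m.icp_amp1, ' mmHg')} "
            f"({'abnormal' if np.isfinite(m.icp_amp1) and m.icp_amp1 >= amp_thr else 'normal' if np.isfinite(m.icp_amp1) else '-'}"
            f", morphology {m.morphology_baseline})",
            f"ICP_AMP2           {fmt(m.icp_amp2, ' mmHg')} "
            f"({'abnormal' if np.isfinite(m.icp_amp2) and m.icp_amp2 >= amp_thr else 'normal' if np.isfinite(m.icp_amp2) else '-'}"
            f", morphology {m.morphology_wavetop})",
            "-" * 54,
            f"shunt criteria     met={m.shunt_criteria_met} "
            f"(criterion {m.criterion_triggered})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overview plot: raw and smoothed traces with detected trains,
        plateaus and the two pulse windows shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 4))
        sig = self.model.signal
        t_h = sig.time_s / 3600.0
        step = max(1, sig.n_samples // 200_000)  # decimate for display only
        ax.plot(t_h[::step], sig.samples[::step], lw=0.3, color="0.6", label="raw")
        ax.plot(t_h[::step], self.smoothed.samples[::step], lw=0.8, color="C0", label="smoothed")
        for tr in self.trains:
            color = "C1" if tr.wave_class == slow_waves.B_HIGH else "C2"
            ax.axvspan(tr.start_s / 3600, tr.end_s / 3600, alpha=0.15, color=color)
        for pl in self.plateaus:
            ax.axvspan(pl.start_s / 3600, pl.end_s / 3600, alpha=0.2, color="C3")
        for win, color in ((self.baseline_window, "C4"), (self.wavetop_window, "C5")):
            if win is not None:
                ax.axvspan(win.start_s / 3600, win.end_s / 3600, alpha=0.25, color=color)
        ax.set_xlabel("time since start (h)")
        ax.set_ylabel("ICP (mmHg)")
        ax.legend(loc="upper right", fontsize=8)
        return ax


class CohortComparison:
    """Two-group comparison of a per-patient metrics table."""

    def __init__(
        self,
        records: pd.DataFrame,
        grouping: str,
        variables: Sequence[str] | None = None,
    ) -> None:
        self.records = records
        self.grouping = grouping
        self.variables = variables

    @classmethod
    def from_csv(cls, path: str | Path, grouping: str, **kw) -> "CohortComparison":
        return cls(pd.read_csv(path), grouping, **kw)

    def fit(self) -> "CohortResults":
        rows = cohort_stats.summarize_groups(self.records, self.grouping, self.variables)
        return CohortResults(model=self, comparisons=rows)


@dataclass
class CohortResults:
    model: CohortComparison
    comparisons: list

    def to_frame(self) -> pd.DataFrame:
        return cohort_stats.comparisons_to_frame(self.comparisons)

    def summary(self) -> str:
        df = self.to_frame()
        with pd.option_context("display.width", 120, "display.max_columns", 20):
            header = (
                f"Cohort comparison by {self.model.grouping!r} "
                f"(n={len(self.model.records)})"
            )
            return header + "\n" + df.to_string(index=False)

    def to_markdown(self) -> str:
        return self.to_frame().to_markdown(index=False)
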