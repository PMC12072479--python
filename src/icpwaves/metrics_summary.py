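"""Per-patient summary metrics and clinical decision rules.

Assembles the quantities a monitoring report carries — mean ICP overall and
by day/night stratum, nocturnal B-wave percentages, the two pulse-amplitude
windows and their morphology — and applies the shunt-decision rule used
for benign external hydrocephalus:

* criterion A: any amount of high-amplitude B-waves or plateau (A-) waves;
* criterion B: low-amplitude B-waves in more than 10% of the recording
  time, combined with ICP_AMP1 >= 5 mmHg or ICP_AMP2 > 5 mmHg (the mixed
  inclusive/exclusive bounds are deliberate and kept as printed).

Also houses two small threshold classifiers from the clinical work-up:
Evans' index (ventricular width ratio, abnormal at >= 0.30) and Bayley-III
developmental-delay flags (scaled score < 7, composite score < 85).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .signal_io import ArtifactMask, IcpSignal

__all__ = [
    "PatientMetrics",
    "ShuntDecision",
    "compute_mean_icp",
    "evaluate_shunt_criteria",
    "compute_evans_index",
    "classify_developmental_delay",
    "EVANS_ABNORMAL_THRESHOLD",
]

EVANS_ABNORMAL_THRESHOLD = 0.30
SCALED_DELAY_BELOW = 7.0
COMPOSITE_DELAY_BELOW = 85.0

CRITERION_A = "A"
CRITERION_B = "B"
CRITERION_NONE = "none"
CRITERION_INDETERMINATE = "indeterminate"


@dataclass
class PatientMetrics:
    """One patient's monitoring summary row.

    Amplitudes and means are in mmHg, wave burdens in percent of the
    night; NaN marks indeterminate quantities (e.g. too few clean beats in
    a window).
    """

    patient_id: str
    mean_icp_total: float
    mean_icp_diurnal: float
    mean_icp_nocturnal: float
    pct_b_low: float
    pct_b_high: float
    pct_b_total: float
    plateau_present: bool
    icp_amp1: float = float("nan")
    icp_amp2: float = float("nan")
    morphology_baseline: str = "indeterminate"
    morphology_wavetop: str = "indeterminate"
    shunt_criteria_met: bool | None = None
    criterion_triggered: str = CRITERION_NONE

    def __post_init__(self) -> None:
        strata = [self.mean_icp_diurnal, self.mean_icp_nocturnal]
        finite = [s for s in strata if np.isfinite(s)]
        if finite and np.isfinite(self.mean_icp_total):
            if not (min(finite) - 1e-9 <= self.mean_icp_total <= max(finite) + 1e-9):
                raise ValueError(
                    "mean_icp_total must lie between the diurnal and nocturnal means"
                )

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "mean_icp_total": self.mean_icp_total,
            "mean_icp_diurnal": self.mean_icp_diurnal,
            "mean_icp_nocturnal": self.mean_icp_nocturnal,
            "pct_b_low": self.pct_b_low,
            "pct_b_high": self.pct_b_high,
            "pct_b_total": self.pct_b_total,
            "plateau_present": self.plateau_present,
            "icp_amp1": self.icp_amp1,
            "icp_amp2": self.icp_amp2,
            "morphology_baseline": self.morphology_baseline,
            "morphology_wavetop": self.morphology_wavetop,
            "shunt_criteria_met": self.shunt_criteria_met,
            "criterion_triggered": self.criterion_triggered,
        }


@dataclass(frozen=True)
class ShuntDecision:
    """Outcome of the shunt rule: met/not-met/indeterminate plus which
    criterion fired (A wins when both do)."""

    met: bool | None
    criterion: str


def compute_mean_icp(
    signal: IcpSignal,
    mask: ArtifactMask | None,
    labels: np.ndarray,
) -> tuple[float, float, float]:
    """(total, diurnal, nocturnal) arithmetic means over valid samples.

    A stratum with no valid samples yields NaN (indeterminate) rather than
    an exception, so partial recordings still summarize.
    """
    x = signal.samples
    valid = (mask.valid if mask is not None else np.ones(x.size, dtype=bool)) & np.isfinite(x)

    def stratum_mean(sel: np.ndarray) -> float:
        s = valid & sel
        return float(x[s].mean()) if s.any() else float("nan")

    total = stratum_mean(np.ones(x.size, dtype=bool))
    diurnal = stratum_mean(labels == "diurnal")
    nocturnal = stratum_mean(labels == "nocturnal")
    return total, diurnal, nocturnal


def evaluate_shunt_criteria(
    metrics: "PatientMetrics | Mapping[str, object]",
    low_b_pct_threshold: float = 10.0,
    amp_threshold: float = 5.0,
) -> ShuntDecision:
    """Apply the two shunt criteria to an assembled metrics row.

    Criterion A fires on any high-amplitude B-wave or plateau activity
    (pct_b_high > 0 or plateau_present).  Criterion B fires when low-
    amplitude B-waves occupy more than 10% of the (nocturnal) recording
    time AND icp_amp1 >= 5 mmHg or icp_amp2 > 5 mmHg.  If criterion B's
    wave condition holds but both amplitudes are indeterminate, the
    decision is indeterminate and flagged for manual review.
    """
    if isinstance(metrics, PatientMetrics):
        m = metrics.to_dict()
    else:
        m = dict(metrics)
    pct_high = float(m.get("pct_b_high", 0.0) or 0.0)
    plateau = bool(m.get("plateau_present", False))
    pct_low = float(m.get("pct_b_low", 0.0) or 0.0)
    amp1 = m.get("icp_amp1", float("nan"))
    amp2 = m.get("icp_amp2", float("nan"))
    amp1 = float("nan") if amp1 is None else float(amp1)
    amp2 = float("nan") if amp2 is None else float(amp2)

    if pct_high > 0 or plateau:
        return ShuntDecision(met=True, criterion=CRITERION_A)

    if pct_low > low_b_pct_threshold:
        amp_known = np.isfinite(amp1) or np.isfinite(amp2)
        if not amp_known:
            return ShuntDecision(met=None, criterion=CRITERION_INDETERMINATE)
        fired = (np.isfinite(amp1) and amp1 >= amp_threshold) or (
            np.isfinite(amp2) and amp2 > amp_threshold
        )
        if fired:
            return ShuntDecision(met=True, criterion=CRITERION_B)
    return ShuntDecision(met=False, criterion=CRITERION_NONE)


def compute_evans_index(bifrontal_mm: float, inner_skull_mm: float) -> tuple[float, bool]:
    """Evans' index: maximal bifrontal ventricular width over maximal inner
    skull diameter on the same axial slice.  Abnormal at ratio >= 0.30."""
    if bifrontal_mm <= 0 or inner_skull_mm <= 0:
        raise ValueError("both diameters must be positive")
    if bifrontal_mm > inner_skull_mm:
        raise ValueError("bifrontal distance cannot exceed the inner skull diameter")
    ratio = bifrontal_mm / inner_skull_mm
    return ratio, ratio >= EVANS_ABNORMAL_THRESHOLD


def classify_developmental_delay(
    scaled_scores: Mapping[str, float] | None = None,
    composite_scores: Mapping[str, float] | None = None,
) -> dict[str, bool]:
    """Bayley-III delay flags.

    A scaled score below 7 or a composite score below 85 flags delay on
    that scale; scales without a score are omitted from the output (absent,
    not False).
    """
    flags: dict[str, bool] = {}
    for name, score in (scaled_scores or {}).items():
        if score is not None and np.isfinite(score):
            flags[name] = bool(score < SCALED_DELAY_BELOW)
    for name, score in (composite_scores or {}).items():
        if score is not None and np.isfinite(score):
            flags[name] = bool(score < COMPOSITE_DELAY_BELOW)
    return flags
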