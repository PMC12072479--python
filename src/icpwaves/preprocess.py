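"""Slow-wave display channel and artifact masking.

Clinical ICP review uses a second, smoothed channel on which slow waves
(Lundberg B- and A-waves) stand out from cardiac and respiratory
pulsatility.  That channel is produced here by a zero-phase triangular
(Bartlett) FIR filter with unit DC gain — by default a 255-sample window,
i.e. about 1.3 s at 200 Hz.  Artifact detection turns the manual
"artifact-free period" selection of bedside review into explicit,
reproducible per-sample rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .signal_io import ArtifactMask, IcpSignal

__all__ = ["FilterConfig", "ArtifactParams", "bartlett_kernel", "smooth_bartlett", "detect_artifacts"]


@dataclass(frozen=True)
class FilterConfig:
    """Triangular smoothing-filter settings.

    window_length is in samples, must be odd so the kernel has a center tap
    (zero phase); weights are normalized to sum to one (unit DC gain).
    """

    window_length: int = 255

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError(
                f"window_length must be odd and >= 3, got {self.window_length}"
            )


def bartlett_kernel(window_length: int) -> np.ndarray:
    """Symmetric triangular weights of odd length, summing to exactly 1.

    The endpoints carry zero weight (classic Bartlett taper), so the
    effective support is ``window_length - 2`` samples.
    """
    if window_length < 3 or window_length % 2 == 0:
        raise ValueError(f"window_length must be odd and >= 3, got {window_length}")
    w = np.bartlett(window_length)
    return w / w.sum()


def smooth_bartlett(signal: IcpSignal, config: FilterConfig = FilterConfig()) -> IcpSignal:
    """Produce the smoothed slow-wave channel.

    Zero-phase: the centered symmetric kernel leaves wave timing aligned
    with the raw trace.  Edges use reflection padding so the output has the
    input's length and the unit DC gain holds up to the boundaries, avoiding
    edge transients that could mimic slow waves.
    """
    cfg = config
    if signal.n_samples < cfg.window_length:
        raise ValueError(
            f"signal has {signal.n_samples} samples but the filter needs at least "
            f"{cfg.window_length}"
        )
    kernel = bartlett_kernel(cfg.window_length)
    smoothed = ndimage.convolve1d(signal.samples, kernel, mode="reflect")
    return signal.with_samples(smoothed, channel_label="smoothed")


@dataclass(frozen=True)
class ArtifactParams:
    """Rules marking unusable samples.

    min_icp/max_icp bound the physiologically plausible range (mmHg);
    jump_mmhg is the largest credible sample-to-sample step; flat-line
    dropouts are near-zero segments with essentially no variance lasting at
    least flat_min_s.  Flagged regions are padded by pad_s on both sides
    because transducer hits corrupt neighbouring samples too.
    """

    min_icp: float = -10.0
    max_icp: float = 80.0
    jump_mmhg: float = 20.0
    flat_min_s: float = 2.0
    flat_abs_mmhg: float = 0.5
    flat_std_mmhg: float = 0.05
    pad_s: float = 1.0


def detect_artifacts(signal: IcpSignal, params: ArtifactParams = ArtifactParams()) -> ArtifactMask:
    """Flag out-of-range values, implausible jumps, dropouts and NaNs.

    Returns a mask where ``valid`` is False on flagged samples; flagged
    regions are dilated by ``pad_s`` seconds.
    """
    x = signal.samples
    fs = signal.sampling_rate
    invalid = ~np.isfinite(x)
    xf = np.where(invalid, 0.0, x)

    invalid |= (xf < params.min_icp) | (xf > params.max_icp)

    jumps = np.abs(np.diff(xf)) > params.jump_mmhg
    if jumps.any():
        idx = np.flatnonzero(jumps)
        invalid[idx] = True
        invalid[idx + 1] = True

    flat_n = max(int(round(params.flat_min_s * fs)), 2)
    if signal.n_samples >= flat_n:
        # Rolling variance via uniform filters; clip tiny negatives from rounding.
        m = ndimage.uniform_filter1d(xf, flat_n, mode="nearest")
        m2 = ndimage.uniform_filter1d(xf * xf, flat_n, mode="nearest")
        local_std = np.sqrt(np.clip(m2 - m * m, 0.0, None))
        invalid |= (local_std < params.flat_std_mmhg) & (np.abs(xf) < params.flat_abs_mmhg)

    pad_n = int(round(params.pad_s * fs))
    if pad_n > 0 and invalid.any():
        invalid = ndimage.maximum_filter1d(invalid.astype(np.uint8), 2 * pad_n + 1) > 0

    return ArtifactMask(valid=~invalid)
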