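"""Dual-indicator Ca2+ trace quantification: F/F_max and peak dF/F_max.

Fluorescence is normalized to the Ca2+-saturated indicator signal (F_max),
obtained pharmacologically at the end of each recording; with responses
kept below ~50% of F_max, fluorescence is approximately linear in [Ca2+],
so peak dF/F_max is a proxy for the peak Ca2+ change.  A linearity flag is
raised whenever a response leaves that regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Image, Mask

LINEAR_REGIME_LIMIT = 0.5  # responses should stay below 50% of F_max


@dataclass
class Trace:
    time_s: np.ndarray
    F: np.ndarray
    roi_id: str = ""
    channel: str = "cytosolic"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.time_s) != len(self.F):
            raise ValueError("time_s and F must have equal length")
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.F)


@dataclass
class NormTrace:
    f_over_fmax: np.ndarray
    f_max: float
    fmax_window: tuple[int, int]
    trace: Trace
    baseline_window: tuple[int, int] | None = None
    response_window: tuple[int, int] | None = None
    delta_peak: float | None = None
    linearity_flag: bool = False


def extract_trace(
    stack: Image,
    roi: Mask,
    bg_roi: Mask,
    frame_interval_s: float = 1.0,
    roi_id: str = "",
    channel: str = "cytosolic",
) -> Trace:
    """Per-frame ROI mean minus per-frame background mean, clipped at 0."""
    if roi.is_empty():
        raise ValueError("ROI is empty")
    if bg_roi.is_empty():
        raise ValueError("background ROI is empty")
    data = stack.data
    if data.ndim == 2:
        data = data[None]
    f = data[:, roi.data].mean(axis=1) - data[:, bg_roi.data].mean(axis=1)
    t = np.arange(len(f)) * frame_interval_s
    return Trace(time_s=t, F=np.clip(f, 0, None), roi_id=roi_id, channel=channel)


def normalize_fmax(
    trace: Trace,
    fmax_window: tuple[int, int],
    plateau_tolerance: float = 0.05,
) -> NormTrace:
    """Normalize a trace to the saturated-indicator plateau.

    F_max is the mean of the top decile of frames within ``fmax_window`` —
    robust to single-frame outliers.  The window must actually contain the
    saturation plateau: if the estimate falls below the earlier trace
    maximum by more than ``plateau_tolerance`` (relative), the window is
    rejected.
    """
    lo, hi = fmax_window
    if not (0 <= lo < hi <= len(trace)):
        raise ValueError("fmax_window outside trace")
    if hi - lo < 3:
        raise ValueError("fmax_window must span at least 3 frames")
    seg = trace.F[lo:hi]
    top = np.sort(seg)[-max(1, len(seg) // 10) :]
    f_max = float(top.mean())
    if f_max <= 0:
        raise ValueError("invalid F_max window: non-positive plateau")
    outside = np.concatenate([trace.F[:lo], trace.F[hi:]])
    if len(outside) and outside.max() > f_max * (1 + plateau_tolerance):
        raise ValueError(
            "invalid F_max window: plateau below the trace maximum elsewhere"
        )
    return NormTrace(
        f_over_fmax=trace.F / f_max, f_max=f_max, fmax_window=(lo, hi), trace=trace
    )


def peak_delta(
    norm: NormTrace,
    baseline_window: tuple[int, int],
    response_window: tuple[int, int],
    smooth_frames: int = 3,
) -> NormTrace:
    """Peak dF/F_max: max over the response window minus the baseline mean.

    Windows must be disjoint with the response after the baseline.  The
    peak is read from the response segment after a short centred moving
    average (``smooth_frames``, default 3): a raw single-frame max is
    biased upward by frame noise, while a window much longer than the
    transient rise time clips the true peak.  The linearity flag is raised
    when peak F/F_max exceeds 50% of F_max, the regime where indicator
    fluorescence stops tracking [Ca2+] linearly.
    """
    b0, b1 = baseline_window
    r0, r1 = response_window
    if not (0 <= b0 < b1 <= len(norm.f_over_fmax) and 0 <= r0 < r1 <= len(norm.f_over_fmax)):
        raise ValueError("window outside trace")
    if b1 > r0:
        raise ValueError("baseline and response windows must be disjoint, response after baseline")
    baseline = float(norm.f_over_fmax[b0:b1].mean())
    seg = norm.f_over_fmax[r0:r1]
    if smooth_frames > 1 and len(seg) >= smooth_frames:
        # smoothing stays inside the segment so the F_max step cannot leak in
        seg = np.convolve(seg, np.ones(smooth_frames) / smooth_frames, mode="valid")
    peak = float(seg.max())
    norm.baseline_window = (b0, b1)
    norm.response_window = (r0, r1)
    norm.delta_peak = peak - baseline
    norm.linearity_flag = peak > LINEAR_REGIME_LIMIT
    return norm


def baseline_drift_warning(
    trace: Trace, baseline_window: tuple[int, int], max_slope_per_s: float = 0.01
) -> bool:
    """True when the baseline drifts faster than ``max_slope_per_s`` (relative)."""
    b0, b1 = baseline_window
    seg = trace.F[b0:b1]
    if len(seg) < 3 or seg.mean() == 0:
        return False
    slope = np.polyfit(trace.time_s[b0:b1], seg / seg.mean(), 1)[0]
    return abs(slope) > max_slope_per_s


def quantify_trace_frame(
    df: pd.DataFrame,
    stim_frame: int,
    fmax_frame: int,
    cell_id: str = "",
    response_frames: int | None = None,
) -> pd.DataFrame:
    """Quantify a two-channel trace table (frame, time_s, F_cyto, F_mito).

    Windows follow the annotated event frames: baseline = all frames before
    the stimulus, response = stimulus to just before F_max saturation,
    F_max window = saturation to the end.  Returns one tidy row per channel.
    """
    rows = []
    r1 = fmax_frame if response_frames is None else min(fmax_frame, stim_frame + response_frames)
    for channel, col in (("cytosolic", "F_cyto"), ("mitochondrial", "F_mito")):
        tr = Trace(df["time_s"].to_numpy(), df[col].to_numpy(), roi_id=cell_id, channel=channel)
        norm = normalize_fmax(tr, (fmax_frame, len(tr)))
        norm = peak_delta(norm, (0, stim_frame), (stim_frame, r1))
        rows.append(
            {
                "cell": cell_id,
                "channel": channel,
                "delta_f_over_fmax": norm.delta_peak,
                "f_max": norm.f_max,
                "linearity_flag": norm.linearity_flag,
                "drift_flag": baseline_drift_warning(tr, (0, stim_frame)),
            }
        )
    return pd.DataFrame(rows)
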