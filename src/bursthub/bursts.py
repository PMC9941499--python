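"""Burst calling and burst statistics.

A trace is smoothed by lowess (locally weighted linear regression, tricube
weights, 10-frame window, no robustifying iterations); maximal runs of
smoothed frames strictly above the threshold become candidate bursts;
touching bursts are divided at valley frames where the smoothed signal
strictly decreased over the prior two frames and strictly increases over
the next two; fragments shorter than five frames are discarded as false
positives.  Burst size and total output integrate the baseline-zeroed raw
trajectory, not the smoothed one.

The burst threshold is a required analysis input (trace units after
baseline zeroing).  A documented default is k x MAD of the trace's
sub-median fluctuations, see :func:`mad_threshold`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .traces import SpotTrace


@dataclass(frozen=True)
class BurstCallConfig:
    threshold: float
    lowess_window_frames: int = 10
    min_duration_frames: int = 5

    def __post_init__(self) -> None:
        if self.lowess_window_frames < 2:
            raise ValueError("lowess window must be >= 2")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.min_duration_frames < 1:
            raise ValueError("min_duration_frames must be >= 1")


@dataclass(frozen=True)
class Burst:
    lineage_id: int
    channel: str
    start_frame: int
    end_frame: int  # inclusive
    size: float     # sum of baseline-zeroed raw trace over [start, end]

    @property
    def duration(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class NucleusSummary:
    lineage_id: int
    burst_frequency: int
    total_output: float
    ever_active: bool
    onset_frame: int | None


def mad_threshold(values: np.ndarray, k: float = 3.0) -> float:
    """k x MAD of the sub-median fluctuations of a baseline-zeroed trace."""
    values = np.asarray(values, dtype=float)
    sub = values[values <= np.median(values)]
    mad = np.median(np.abs(sub - np.median(sub)))
    return float(k * mad)


def _tricube(d: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - d ** 3, 0.0, None) ** 3


def smooth_series(values: np.ndarray, window: int = 10) -> np.ndarray:
    """Lowess smoothing of a series, evaluated at every frame.

    Each frame is fit by weighted linear regression over the ``window``
    nearest frames (a sliding window, shifted inward at the boundaries)
    with tricube distance weights.  Exact on constants and straight lines.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < window:
        warnings.warn("trace shorter than the lowess window; span clamped "
                      "to the full trace", stacklevel=2)
        window = n
    if window < 2:
        return y.copy()
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    half = (window - 1) // 2
    for t in range(n):
        lo = min(max(t - half, 0), n - window)
        xs = x[lo:lo + window]
        ys = y[lo:lo + window]
        d = np.abs(xs - t)
        dmax = d.max()
        w = _tricube(d / dmax) if dmax > 0 else np.ones_like(d)
        sw = w.sum()
        xm = (w * xs).sum() / sw
        ym = (w * ys).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        slope = (w * (xs - xm) * (ys - ym)).sum() / sxx if sxx > 0 else 0.0
        out[t] = ym + slope * (t - xm)
    return out


def smooth_trace(trace: SpotTrace, config: BurstCallConfig) -> np.ndarray:
    return smooth_series(trace.baseline_zeroed, config.lowess_window_frames)


def split_touching_bursts(start: int, end: int,
                          smoothed: np.ndarray) -> list[tuple[int, int]]:
    """Divide a supra-threshold run at interior valley frames.

    A valley is a frame t (within the run) with s[t-2] > s[t-1] > s[t] and
    s[t] < s[t+1] < s[t+2]; the run is divided there, the valley frame
    starting the later fragment.  Applied left to right, re-evaluating the
    remaining fragment.  Strict inequalities: plateaus do not split.
    """
    s = smoothed
    fragments: list[tuple[int, int]] = []
    a = start
    t = start + 2
    while t <= end - 2:
        if (s[t - 2] > s[t - 1] > s[t]) and (s[t] < s[t + 1] < s[t + 2]):
            fragments.append((a, t - 1))
            a = t
            t = a + 2
        else:
            t += 1
    fragments.append((a, end))
    return fragments


def _supra_runs(smoothed: np.ndarray, threshold: float
                ) -> list[tuple[int, int]]:
    above = smoothed > threshold
    runs = []
    start = None
    for t, flag in enumerate(above):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            runs.append((start, t - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    return runs


def call_bursts(trace: SpotTrace, config: BurstCallConfig) -> list[Burst]:
    """Call retained bursts on one trace.

    Returns disjoint, ordered bursts of duration >= min_duration_frames;
    sizes integrate the baseline-zeroed raw trace over the burst span.
    Frame numbers refer to positions within the trace's own frame vector.
    """
    smoothed = smooth_trace(trace, config)
    bz = trace.baseline_zeroed
    out: list[Burst] = []
    for run_start, run_end in _supra_runs(smoothed, config.threshold):
        for a, b in split_touching_bursts(run_start, run_end, smoothed):
            if b - a + 1 < config.min_duration_frames:
                continue
            out.append(Burst(
                lineage_id=trace.lineage_id, channel=trace.channel,
                start_frame=int(trace.frames[a]),
                end_frame=int(trace.frames[b]),
                size=float(bz[a:b + 1].sum())))
    return out


def summarize_nuclei(bursts: list[Burst],
                     traces: list[SpotTrace]) -> list[NucleusSummary]:
    """Per-nucleus burst frequency, total output, onset and activity flag."""
    by_lineage: dict[int, list[Burst]] = {}
    for b in bursts:
        by_lineage.setdefault(b.lineage_id, []).append(b)
    out = []
    for tr in traces:
        bs = sorted(by_lineage.get(tr.lineage_id, []),
                    key=lambda b: b.start_frame)
        out.append(NucleusSummary(
            lineage_id=tr.lineage_id,
            burst_frequency=len(bs),
            total_output=float(tr.baseline_zeroed.sum()),
            ever_active=bool(bs),
            onset_frame=bs[0].start_frame if bs else None))
    return out


def cumulative_active_fraction(summaries: list[NucleusSummary],
                               n_frames: int) -> np.ndarray:
    """Fraction of nuclei that experienced a burst by each frame.

    Monotone non-decreasing step function whose final value is the
    ever-active fraction.
    """
    onsets = [s.onset_frame for s in summaries if s.onset_frame is not None]
    frac = np.zeros(n_frames)
    n = len(summaries)
    if n == 0:
        return frac
    for onset in onsets:
        if onset < n_frames:
            frac[onset:] += 1.0
    return frac / n


def _active_mask(traces: list[SpotTrace], bursts: list[Burst],
                 n_frames: int) -> dict[int, np.ndarray]:
    masks = {tr.lineage_id: np.zeros(n_frames, dtype=bool) for tr in traces}
    for b in bursts:
        if b.lineage_id in masks:
            masks[b.lineage_id][b.start_frame:b.end_frame + 1] = True
    return masks


def instantaneous_activity(traces: list[SpotTrace], bursts: list[Burst],
                           n_frames: int,
                           when_active: bool = True) -> np.ndarray:
    """Per-frame mean over nuclei currently inside (or outside) a burst.

    ``bursts`` define the active set; they may come from a different channel
    than ``traces`` (e.g. MS2 intensity conditioned on concurrent PP7
    bursting).  Averages the traces' values as given (``raw``, which for
    pipeline traces is the extracted spot signal); frames with an empty
    active set are NaN.
    """
    masks = _active_mask(traces, bursts, n_frames)
    out = np.full(n_frames, np.nan)
    for t in range(n_frames):
        vals = []
        for tr in traces:
            m = masks[tr.lineage_id]
            in_burst = bool(m[t])
            if in_burst == when_active:
                idx = np.nonzero(tr.frames == t)[0]
                if idx.size:
                    vals.append(tr.raw[idx[0]])
        if vals:
            out[t] = float(np.mean(vals))
    return out


def mean_activity(traces: list[SpotTrace], n_frames: int) -> np.ndarray:
    """Per-frame mean over all analyzed nuclei; frames without data are NaN."""
    out = np.full(n_frames, np.nan)
    counts = np.zeros(n_frames)
    sums = np.zeros(n_frames)
    for tr in traces:
        sel = (tr.frames >= 0) & (tr.frames < n_frames)
        sums[tr.frames[sel]] += tr.raw[sel]
        counts[tr.frames[sel]] += 1
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return out


def compare_groups(values_a, values_b,
                   n_comparisons: int = 1) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum test with Bonferroni correction.

    Returns ``(statistic, p_value, adjusted_p)`` with the adjusted p capped
    at 1.  Exact for small tie-free samples (e.g. {1,2,3} vs {10,11,12}
    gives p = 0.1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return float(res.statistic), p, min(1.0, p * n_comparisons)


def bursts_table(bursts: list[Burst]) -> pd.DataFrame:
    return pd.DataFrame([{
        "lineage_id": b.lineage_id, "channel": b.channel,
        "start": b.start_frame, "end": b.end_frame,
        "duration": b.duration, "size": b.size,
    } for b in bursts])


def summaries_table(summaries: list[NucleusSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "lineage_id": s.lineage_id, "frequency": s.burst_frequency,
        "total_output": s.total_output,
        "onset": -1 if s.onset_frame is None else s.onset_frame,
        "ever_active": s.ever_active,
    } for s in summaries])
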