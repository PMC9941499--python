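"""Spot-intensity trace extraction from maximum-projected movies.

The per-frame spot signal of a nucleus is the integral of the 5x5 pixel
window centered on the brightest pixel inside the nucleus region, minus the
window pixel count times the median intensity over the region (local
background).  Per-trace baselines are zeroed by subtracting the trace
minimum, so adding a constant offset to a whole channel leaves the
baseline-zeroed traces unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WINDOW = 5  # spot integration window side, px


@dataclass
class SpotTrace:
    """Per-nucleus, per-channel intensity time series."""

    lineage_id: int
    channel: str
    raw: np.ndarray
    spot_yx: np.ndarray | None = None   # (T, 2) brightest-pixel coordinates
    frames: np.ndarray | None = None
    baseline_zeroed: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 1 or self.raw.size == 0:
            raise ValueError("raw trace must be a non-empty 1D array")
        if self.frames is None:
            self.frames = np.arange(self.raw.size)
        self.baseline_zeroed = self.raw - self.raw.min()

    def __len__(self) -> int:
        return self.raw.size


def extract_spot_signal(projected_frame: np.ndarray,
                        region: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Integrated 5x5 spot signal within a nucleus region.

    ``region`` is a boolean mask over the frame.  The window is centered on
    the brightest region pixel (ties broken row-major: lowest row, then
    lowest column); window pixels outside the region but inside the image
    are included.  At the image border the window is cropped and the
    background multiplier equals the actual window pixel count.  Returns
    ``(signal, (row, col))``; the signal may be negative before baseline
    zeroing.
    """
    frame = np.asarray(projected_frame, dtype=float)
    region = np.asarray(region, dtype=bool)
    if frame.shape != region.shape:
        raise ValueError("frame and region shapes differ")
    rows, cols = np.nonzero(region)
    if rows.size == 0:
        raise ValueError("empty nucleus region")
    vals = frame[rows, cols]
    best = int(np.argmax(vals))  # first max in row-major order
    r, c = int(rows[best]), int(cols[best])
    med = float(np.median(vals))
    h = WINDOW // 2
    r0, r1 = max(r - h, 0), min(r + h + 1, frame.shape[0])
    c0, c1 = max(c - h, 0), min(c + h + 1, frame.shape[1])
    window = frame[r0:r1, c0:c1]
    signal = float(window.sum() - window.size * med)
    return signal, (r, c)


def build_traces(movie, tracks, channel: str, masks) -> list[SpotTrace]:
    """Extract one baseline-zeroed SpotTrace per valid track.

    ``movie`` is a sim.ImageStack; ``masks`` the per-frame LabelMask list
    matching the tracks.  Each frame is maximum-projected over z before
    extraction.
    """
    ci = movie.channels.index(channel)
    n_frames = movie.data.shape[0]
    proj_cache: dict[int, np.ndarray] = {}

    def proj(t: int) -> np.ndarray:
        if t not in proj_cache:
            proj_cache[t] = movie.data[t, ci].max(axis=0)
        return proj_cache[t]

    frame_offset = masks[0].frame_index
    out: list[SpotTrace] = []
    for tr in tracks:
        if not tr.valid:
            continue
        raw = np.empty(len(tr.points))
        spots = np.empty((len(tr.points), 2), dtype=int)
        frames = np.empty(len(tr.points), dtype=int)
        for k, p in enumerate(tr.points):
            if not 0 <= p.frame_index < n_frames:
                raise ValueError(
                    f"track {tr.lineage_id} references frame {p.frame_index} "
                    f"outside the movie")
            mask = masks[p.frame_index - frame_offset]
            region = mask.labels == p.label
            raw[k], spots[k] = extract_spot_signal(proj(p.frame_index), region)
            frames[k] = p.frame_index
        out.append(SpotTrace(lineage_id=tr.lineage_id, channel=channel,
                             raw=raw, spot_yx=spots, frames=frames))
    return out


def traces_table(traces: list[SpotTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for k in range(len(tr)):
            rows.append({
                "lineage_id": tr.lineage_id, "channel": tr.channel,
                "frame": int(tr.frames[k]), "raw": tr.raw[k],
                "baseline_zeroed": tr.baseline_zeroed[k],
                "spot_y": int(tr.spot_yx[k, 0]) if tr.spot_yx is not None
                else -1,
                "spot_x": int(tr.spot_yx[k, 1]) if tr.spot_yx is not None
                else -1,
            })
    return pd.DataFrame(rows)
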