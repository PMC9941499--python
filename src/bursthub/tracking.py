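"""Nucleus tracking by minimal centroid displacement.

Nuclei in consecutive frames are linked greedily in ascending Euclidean
centroid distance with one-to-one matching; unmatched detections start new
lineages, and a lineage that misses a frame terminates (no gap closing).
Exclusion rules: a lineage whose region ever touches the image border, or
whose per-step displacement exceeds the nucleus length (major-axis length of
the region in the earlier frame, strict inequality), is marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .segmentation import LabelMask

EDGE_CONTACT = "edge_contact"
JUMP_EXCEEDS_LENGTH = "jump_exceeds_length"


@dataclass
class TrackPoint:
    frame_index: int
    label: int
    centroid_yx: tuple[float, float]
    major_axis_length: float
    touches_edge: bool


@dataclass
class NucleusTrack:
    lineage_id: int
    points: list[TrackPoint] = field(default_factory=list)
    valid: bool = True
    exclusion_reason: str | None = None

    @property
    def frames(self) -> list[int]:
        return [p.frame_index for p in self.points]

    def centroids(self) -> np.ndarray:
        return np.asarray([p.centroid_yx for p in self.points])

    def label_at(self, frame_index: int) -> int | None:
        for p in self.points:
            if p.frame_index == frame_index:
                return p.label
        return None


def _frame_detections(mask: LabelMask) -> list[TrackPoint]:
    ny, nx = mask.labels.shape
    dets = []
    for prop in regionprops(mask.labels):
        miny, minx, maxy, maxx = prop.bbox
        touches = miny == 0 or minx == 0 or maxy == ny or maxx == nx
        dets.append(TrackPoint(mask.frame_index, prop.label,
                               tuple(prop.centroid),
                               float(prop.axis_major_length), touches))
    return dets


def link_frames(masks: list[LabelMask]) -> list[NucleusTrack]:
    """Link detections across consecutive frames into lineages.

    Matching is greedy in ascending distance with a deterministic
    (distance, previous label, current label) tie-break and is injective per
    frame pair.  An empty frame terminates all active lineages.
    """
    if len(masks) < 2:
        raise ValueError("need >= 2 frames to track")
    shape = masks[0].labels.shape
    if any(m.labels.shape != shape for m in masks):
        raise ValueError("all masks must share the same shape")
    for i, m in enumerate(masks):
        if m.frame_index != masks[0].frame_index + i:
            raise ValueError("mask frame indices must be consecutive")

    tracks: list[NucleusTrack] = []
    prev = _frame_detections(masks[0])
    active: dict[int, NucleusTrack] = {}
    for det in prev:
        tr = NucleusTrack(lineage_id=len(tracks), points=[det])
        tracks.append(tr)
        active[det.label] = tr

    for mask in masks[1:]:
        dets = _frame_detections(mask)
        if not dets or not active:
            active = {}
            for det in dets:
                tr = NucleusTrack(lineage_id=len(tracks), points=[det])
                tracks.append(tr)
                active[det.label] = tr
            continue
        prev_pts = {lab: tr.points[-1] for lab, tr in active.items()}
        pairs = []
        for plab, ppt in prev_pts.items():
            py, px = ppt.centroid_yx
            for det in dets:
                cy, cx = det.centroid_yx
                d = float(np.hypot(cy - py, cx - px))
                pairs.append((d, plab, det.label, det))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        matched_prev: set[int] = set()
        matched_cur: set[int] = set()
        new_active: dict[int, NucleusTrack] = {}
        for d, plab, clab, det in pairs:
            if plab in matched_prev or clab in matched_cur:
                continue
            matched_prev.add(plab)
            matched_cur.add(clab)
            tr = active[plab]
            tr.points.append(det)
            new_active[clab] = tr
        for det in dets:
            if det.label not in matched_cur:
                tr = NucleusTrack(lineage_id=len(tracks), points=[det])
                tracks.append(tr)
                new_active[det.label] = tr
        active = new_active
    return tracks


def apply_exclusions(tracks: list[NucleusTrack],
                     masks: list[LabelMask] | None = None
                     ) -> list[NucleusTrack]:
    """Apply the edge-contact and jump rules to whole lineages.

    A displacement exactly equal to the nucleus length is retained (the
    exclusion uses a strict inequality).
    """
    for tr in tracks:
        if any(p.touches_edge for p in tr.points):
            tr.valid = False
            tr.exclusion_reason = EDGE_CONTACT
            continue
        for a, b in zip(tr.points, tr.points[1:]):
            dy = b.centroid_yx[0] - a.centroid_yx[0]
            dx = b.centroid_yx[1] - a.centroid_yx[1]
            if np.hypot(dy, dx) > a.major_axis_length:
                tr.valid = False
                tr.exclusion_reason = JUMP_EXCEEDS_LENGTH
                break
    return tracks


def valid_tracks(tracks: list[NucleusTrack]) -> list[NucleusTrack]:
    return [t for t in tracks if t.valid]


def tracks_table(tracks: list[NucleusTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for p in tr.points:
            rows.append({
                "lineage_id": tr.lineage_id, "frame": p.frame_index,
                "label": p.label, "y": p.centroid_yx[0],
                "x": p.centroid_yx[1], "valid": tr.valid,
                "exclusion_reason": tr.exclusion_reason or "none",
            })
    return pd.DataFrame(rows)


def count_identity_swaps(tracks: list[NucleusTrack],
                         true_positions: np.ndarray) -> int:
    """Count lineages whose nearest ground-truth nucleus ever changes.

    ``true_positions`` is the generator's (n_nuclei, T, 2) centroid array.
    Each tracked point is assigned the nearest ground-truth nucleus at its
    frame; a track whose assignment is not constant has swapped identity.
    """
    swaps = 0
    for tr in tracks:
        ids = []
        for p in tr.points:
            pos = true_positions[:, p.frame_index, :]
            d = np.hypot(pos[:, 0] - p.centroid_yx[0],
                         pos[:, 1] - p.centroid_yx[1])
            ids.append(int(np.argmin(d)))
        if len(set(ids)) > 1:
            swaps += 1
    return swaps
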