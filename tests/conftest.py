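import numpy as np
import pytest

from bursthub.segmentation import SegmentationConfig, segment_frame
from bursthub.sim import MovieSpec, TelegraphParams, simulate_movie
from bursthub.tracking import apply_exclusions, link_frames, valid_tracks
from bursthub.traces import build_traces


SMALL_SPEC = MovieSpec(n_nuclei=15, field_shape=(180, 3, 160, 160),
                       nucleus_radius_px=9.0, drift_sd_px=0.3, seed=11)
SMALL_PARAMS = TelegraphParams(k_on=0.05, k_off=0.15, seed=11)


@pytest.fixture(scope="session")
def small_movie():
    """A 15-nucleus, 180-frame movie with ground truth (rendered once)."""
    movie, truth = simulate_movie(SMALL_SPEC, SMALL_PARAMS)
    return movie, truth


@pytest.fixture(scope="session")
def small_masks(small_movie):
    movie, _ = small_movie
    cfg = SegmentationConfig()
    his = movie.channel("His2Av")
    return [segment_frame(his[t].max(axis=0), cfg, frame_index=t)
            for t in range(his.shape[0])]


@pytest.fixture(scope="session")
def small_tracks(small_masks):
    return apply_exclusions(link_frames(small_masks), small_masks)


@pytest.fixture(scope="session")
def small_traces(small_movie, small_masks, small_tracks):
    movie, _ = small_movie
    return build_traces(movie, valid_tracks(small_tracks), "MS2",
                        small_masks)


def match_tracks_to_truth(tracks, truth):
    """Map lineage id -> ground-truth nucleus index by frame-0 position."""
    mapping = {}
    for tr in tracks:
        p0 = tr.points[0]
        pos = truth.nucleus_positions[:, p0.frame_index, :]
        d = np.hypot(pos[:, 0] - p0.centroid_yx[0],
                     pos[:, 1] - p0.centroid_yx[1])
        mapping[tr.lineage_id] = int(np.argmin(d))
    return mapping
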