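"""Radial enrichment of transcription-factor signal around transcription sites.

Square single-z-plane patches of the TF channel are extracted around the
brightest spot voxel of each 3D-segmented nucleus (or around a random pixel
of the same nucleus on the same z-plane as a control).  Patch pixels are
grouped into integer radial bins (round-half-up Euclidean distance from the
center); per-site bin means are normalized by the endmost *complete* bin —
the largest bin whose pixels all lie inside the patch, i.e. the inscribed
radius — so a flat field has enrichment 1 everywhere.  Profiles report the
across-site mean and SEM per bin; condition comparisons use per-site curve
areas under a two-sided rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import compare_groups

log = logging.getLogger(__name__)

TRANSCRIPTION_SITE = "transcription_site"
RANDOM_SITE = "random_site"


@dataclass
class EnrichmentPatch:
    values: np.ndarray             # (side, side) TF intensities
    center_voxel: tuple[int, int, int]
    site_kind: str = TRANSCRIPTION_SITE
    nucleus_id: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        side = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != side:
            raise ValueError("patch must be square")
        if side % 2 == 0:
            raise ValueError("patch side must be odd")

    @property
    def side(self) -> int:
        return self.values.shape[0]


def select_top_sites(integrated_signal: np.ndarray,
                     fraction: float) -> np.ndarray:
    """Indices of nuclei at or above the (1 - fraction) signal quantile.

    With n nuclei the cutoff is the ceil(fraction * n)-th largest signal;
    ties at the cutoff are all retained, so the count may exceed that.
    """
    sig = np.asarray(integrated_signal, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if sig.size == 0:
        raise ValueError("no nuclei to select from")
    k = max(1, int(np.ceil(fraction * sig.size - 1e-12)))
    cutoff = np.sort(sig)[::-1][k - 1]
    idx = np.nonzero(sig >= cutoff)[0]
    if idx.size < 1:
        raise ValueError("selection retained no nuclei")
    return idx


def _crop_patch(plane: np.ndarray, cy: int, cx: int,
                side: int) -> np.ndarray | None:
    h = side // 2
    if cy - h < 0 or cx - h < 0 or cy + h >= plane.shape[0] \
            or cx + h >= plane.shape[1]:
        return None
    return plane[cy - h:cy + h + 1, cx - h:cx + h + 1].astype(float).copy()


def extract_patch(tf_stack: np.ndarray, spot_stack: np.ndarray,
                  nucleus_region_3d: np.ndarray, side_px: int,
                  nucleus_id: int = -1) -> EnrichmentPatch | None:
    """Patch of the TF channel around the brightest spot voxel of a nucleus.

    The global-maximum spot voxel is located within the 3D region (ties
    broken in C order) and the side_px x side_px TF patch on that single
    z-plane is returned.  Sites whose patch would leave the image are
    skipped (returns None) and logged.
    """
    if side_px % 2 == 0:
        raise ValueError("side_px must be odd")
    region = np.asarray(nucleus_region_3d, dtype=bool)
    if not region.any():
        raise ValueError("empty nucleus region")
    masked = np.where(region, spot_stack, -np.inf)
    z, y, x = np.unravel_index(int(np.argmax(masked)), masked.shape)
    patch = _crop_patch(tf_stack[z], y, x, side_px)
    if patch is None:
        log.info("nucleus %d: spot at (%d, %d, %d) too close to the image "
                 "border for a %d px patch; skipped", nucleus_id, z, y, x,
                 side_px)
        return None
    return EnrichmentPatch(patch, (int(z), int(y), int(x)),
                           TRANSCRIPTION_SITE, nucleus_id)


def sample_random_site(tf_stack: np.ndarray, nucleus_region_3d: np.ndarray,
                       z_plane: int, side_px: int,
                       rng: np.random.Generator, nucleus_id: int = -1,
                       max_tries: int = 100) -> EnrichmentPatch | None:
    """Control patch centered on a random nucleus pixel on ``z_plane``.

    The center is drawn uniformly from the nucleus's segmented pixels on the
    spot's z-plane; draws whose patch would leave the image are retried a
    bounded number of times, then the site is skipped.
    """
    region = np.asarray(nucleus_region_3d, dtype=bool)[z_plane]
    ys, xs = np.nonzero(region)
    if ys.size == 0:
        raise ValueError("nucleus region empty on the requested z-plane")
    for _ in range(max_tries):
        j = int(rng.integers(ys.size))
        patch = _crop_patch(tf_stack[z_plane], int(ys[j]), int(xs[j]),
                            side_px)
        if patch is not None:
            return EnrichmentPatch(patch, (z_plane, int(ys[j]), int(xs[j])),
                                   RANDOM_SITE, nucleus_id)
    log.info("nucleus %d: no in-bounds random site after %d tries; skipped",
             nucleus_id, max_tries)
    return None


def radial_bin_indices(side: int) -> np.ndarray:
    """Integer radial bin of each patch pixel (round-half-up distance)."""
    h = side // 2
    dy, dx = np.mgrid[-h:h + 1, -h:h + 1]
    dist = np.hypot(dy, dx)
    return np.floor(dist + 0.5).astype(int)


def endmost_complete_bin(side: int) -> int:
    """Largest bin whose pixels all fit in the patch (inscribed radius)."""
    return side // 2


def site_bin_means(patch: EnrichmentPatch) -> np.ndarray:
    """Per-bin mean TF intensity of one patch, bins 0..max."""
    bins = radial_bin_indices(patch.side)
    nb = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=patch.values.ravel(),
                       minlength=nb)
    counts = np.bincount(bins.ravel(), minlength=nb)
    return sums / counts


def radial_enrichment(patches: list[EnrichmentPatch]
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Mean relative-enrichment heatmap and radial profile over sites.

    Every site's bin means are divided by that site's endmost complete bin
    mean; the profile reports the across-site mean and SEM per bin, plus the
    bin pixel count and whether the bin is complete (inside the inscribed
    radius).  The heatmap is the pixel-wise mean across patches divided by
    its own endmost-bin mean.
    """
    if not patches:
        raise ValueError("need at least one patch")
    side = patches[0].side
    if any(p.side != side for p in patches):
        raise ValueError("patches must share a side length")
    ref_bin = endmost_complete_bin(side)
    bins = radial_bin_indices(side)
    counts = np.bincount(bins.ravel())

    per_site = []
    for p in patches:
        means = site_bin_means(p)
        ref = means[ref_bin]
        if ref <= 0:
            raise ValueError("endmost bin mean non-positive; cannot "
                             "normalize")
        per_site.append(means / ref)
    per_site = np.asarray(per_site)  # (n_sites, n_bins)

    mean_map = np.mean([p.values for p in patches], axis=0)
    ref = mean_map[bins == ref_bin].mean()
    heatmap = mean_map / ref

    n_sites = per_site.shape[0]
    mean = per_site.mean(axis=0)
    sem = per_site.std(axis=0, ddof=1) / np.sqrt(n_sites) if n_sites > 1 \
        else np.zeros_like(mean)
    profile = pd.DataFrame({
        "bin": np.arange(per_site.shape[1]),
        "mean_relative_enrichment": mean,
        "sem": sem,
        "n_pixels": counts,
        "n_sites": n_sites,
        "complete": np.arange(per_site.shape[1]) <= ref_bin,
    })
    return heatmap, profile


def site_profile_areas(patches: list[EnrichmentPatch]) -> np.ndarray:
    """Per-site curve area: sum over complete bins of (enrichment - 1)."""
    if not patches:
        raise ValueError("need at least one patch")
    ref_bin = endmost_complete_bin(patches[0].side)
    areas = []
    for p in patches:
        means = site_bin_means(p)
        norm = means / means[ref_bin]
        areas.append(float((norm[:ref_bin + 1] - 1.0).sum()))
    return np.asarray(areas)


def compare_profile_areas(patches_a: list[EnrichmentPatch],
                          patches_b: list[EnrichmentPatch]) -> float:
    """Two-sided rank-sum p-value between per-site curve areas."""
    _, p, _ = compare_groups(site_profile_areas(patches_a),
                             site_profile_areas(patches_b))
    return p


def profiles_table(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack named profiles into one CSV-ready table."""
    frames = []
    for kind, prof in profiles.items():
        prof = prof.copy()
        prof.insert(0, "kind", kind)
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)
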