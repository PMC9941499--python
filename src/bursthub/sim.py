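"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (segmentation, tracking, trace
extraction, burst calling, hub enrichment, TSS genomics) is exercised against
data produced here, so each generator records the quantities the stage is
supposed to recover: promoter states and burst intervals for traces, nucleus
positions for movies, hub amplitudes and spot voxels for 3D stacks, and
filtered read counts / orientation classes for toy genomes.

The transcription model is the two-state telegraph promoter: the promoter
switches ON/OFF as a discrete-time Markov chain, loads ``loading_rate``
nascent transcripts per ON frame, and each transcript contributes unit signal
for ``dwell_frames`` frames (a boxcar dwell).  Loading is deterministic while
ON (the rate is a mean Pol II loading, possibly fractional), which makes the
support of the noise-free trace exactly the union of ON runs extended by the
dwell time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genomics import GenomicInterval

HIS_CHANNEL = "His2Av"
MS2_CHANNEL = "MS2"
PP7_CHANNEL = "PP7"

_NUCLEAR_MARKER_LEVEL = 60.0  # His2Av disk intensity over background, a.u.


def _check_finite_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class TelegraphParams:
    """Kinetics of the two-state telegraph promoter, in per-frame units."""

    k_on: float = 0.05
    k_off: float = 0.15
    loading_rate: float = 2.0
    dwell_frames: int = 6
    intensity_per_transcript: float = 1.0
    noise_sd: float = 0.8
    n_frames: int = 180
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "loading_rate",
                     "intensity_per_transcript", "noise_sd"):
            _check_finite_nonneg(name, getattr(self, name))
        if self.dwell_frames < 1:
            raise ValueError("dwell_frames must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class MovieSpec:
    """Geometry of a synthetic nc14 movie or 3D stack.

    Defaults mirror a typical two-color confocal acquisition (512x512 px,
    18 z-slices, 180 frames); tests use smaller fields.
    """

    n_nuclei: int = 80
    field_shape: tuple[int, int, int, int] = (180, 18, 512, 512)
    nucleus_radius_px: float = 18.0
    drift_sd_px: float = 0.3
    psf_sd_px: float = 1.5
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if any(s < 1 for s in self.field_shape):
            raise ValueError("field_shape must be positive")
        for name in ("nucleus_radius_px", "drift_sd_px", "psf_sd_px",
                     "background_level"):
            _check_finite_nonneg(name, getattr(self, name))


@dataclass
class GroundTruth:
    """Known truth for a synthetic object; fields used vary by generator."""

    promoter_state: np.ndarray | None = None        # (T,) bool
    true_bursts: list[tuple[int, int]] | None = None  # inclusive frame spans
    clean_trace: np.ndarray | None = None           # (T,) noise-free signal
    nucleus_positions: np.ndarray | None = None     # (n, T, 2) y, x
    hub_amplitude: float | None = None
    # movie extras, one entry per nucleus
    states_ms2: np.ndarray | None = None            # (n, T) bool
    states_pp7: np.ndarray | None = None
    clean_ms2: np.ndarray | None = None             # (n, T)
    clean_pp7: np.ndarray | None = None
    bursts_ms2: list[list[tuple[int, int]]] | None = None
    bursts_pp7: list[list[tuple[int, int]]] | None = None
    spot_voxels: np.ndarray | None = None           # (n, 3) z, y, x
    table: pd.DataFrame | None = None               # genome fixture truth


@dataclass
class ImageStack:
    """Multi-channel T x C x Z x Y x X intensity stack with pixel metadata."""

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_um: float = 1.0

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channels.index(name)]


def true_bursts_from_clean(clean: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of frames with positive noise-free signal."""
    active = np.asarray(clean) > 0
    out: list[tuple[int, int]] = []
    start = None
    for t, a in enumerate(active):
        if a and start is None:
            start = t
        elif not a and start is not None:
            out.append((start, t - 1))
            start = None
    if start is not None:
        out.append((start, len(active) - 1))
    return out


def _simulate_states(params: TelegraphParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_frames
    total = params.k_on + params.k_off
    p_on = params.k_on / total if total > 0 else 0.0
    p_switch_on = min(params.k_on, 1.0)
    p_switch_off = min(params.k_off, 1.0)
    u = rng.random(n)
    state = np.empty(n, dtype=bool)
    state[0] = u[0] < p_on
    for t in range(1, n):
        if state[t - 1]:
            state[t] = not (u[t] < p_switch_off)
        else:
            state[t] = u[t] < p_switch_on
    return state


def simulate_trace(params: TelegraphParams,
                   rng: np.random.Generator | None = None,
                   lineage_id: int = 0,
                   channel: str = MS2_CHANNEL):
    """Simulate one promoter trace.

    Returns ``(SpotTrace, GroundTruth)``.  The observed trace is the clean
    telegraph signal plus additive Gaussian noise, clipped at zero.
    """
    from .traces import SpotTrace  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = _simulate_states(params, rng)
    initiations = params.loading_rate * state.astype(float)
    kernel = np.ones(params.dwell_frames)
    clean = np.convolve(initiations, kernel)[: params.n_frames]
    clean *= params.intensity_per_transcript
    observed = clean + rng.normal(0.0, params.noise_sd, params.n_frames)
    np.clip(observed, 0.0, None, out=observed)
    trace = SpotTrace(lineage_id=lineage_id, channel=channel, raw=observed)
    truth = GroundTruth(promoter_state=state,
                        true_bursts=true_bursts_from_clean(clean),
                        clean_trace=clean)
    return trace, truth


# ---------------------------------------------------------------------------
# movie rendering


def place_nuclei(rng: np.random.Generator, n: int, shape_yx: tuple[int, int],
                 radius: float, margin: float,
                 spacing_factor: float = 2.5,
                 max_tries_per_nucleus: int = 2000) -> np.ndarray:
    """Sequential rejection placement with center spacing >= 2.5 x radius."""
    ny, nx = shape_yx
    lo_y, hi_y = margin, ny - 1 - margin
    lo_x, hi_x = margin, nx - 1 - margin
    if hi_y <= lo_y or hi_x <= lo_x:
        raise ValueError("field too small for the requested nucleus radius")
    min_sep = spacing_factor * radius
    placed: list[tuple[float, float]] = []
    for i in range(n):
        for _ in range(max_tries_per_nucleus):
            y = rng.uniform(lo_y, hi_y)
            x = rng.uniform(lo_x, hi_x)
            if all((y - py) ** 2 + (x - px) ** 2 >= min_sep ** 2
                   for py, px in placed):
                placed.append((y, x))
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {i} of {n} without overlap; "
                "enlarge the field or reduce n_nuclei")
    return np.asarray(placed, dtype=float)


def _add_disk(img: np.ndarray, cy: float, cx: float, radius: float,
              value: float) -> None:
    ny, nx = img.shape
    y0 = max(int(math.floor(cy - radius)), 0)
    y1 = min(int(math.ceil(cy + radius)) + 1, ny)
    x0 = max(int(math.floor(cx - radius)), 0)
    x1 = min(int(math.ceil(cx + radius)) + 1, nx)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    img[y0:y1, x0:x1][mask] += value


def _add_gaussian3d(vol: np.ndarray, cz: float, cy: float, cx: float,
                    amplitude: float, sd: float) -> None:
    if amplitude == 0:
        return
    nz, ny, nx = vol.shape
    r = int(math.ceil(4 * sd))
    z0, z1 = max(int(cz) - r, 0), min(int(cz) + r + 1, nz)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, ny)
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, nx)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    vol[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-d2 / (2 * sd ** 2))


def gaussian_window_mass(sd: float, size: int = 5) -> float:
    """Sum of a unit-peak 2D Gaussian over a size x size pixel window.

    This is the factor relating the rendered spot peak amplitude to the
    integrated 5x5 spot signal recorded by the trace extractor.
    """
    h = size // 2
    dy, dx = np.mgrid[-h:h + 1, -h:h + 1]
    return float(np.exp(-(dy ** 2 + dx ** 2) / (2 * sd ** 2)).sum())


def simulate_movie(spec: MovieSpec, params: TelegraphParams,
                   params_pp7: TelegraphParams | None = None):
    """Render a two-color nc14 movie of bursting nuclei.

    Channels: His2Av nuclear marker (blurred disks), MS2 and PP7 spot
    channels (3D Gaussian spots at nucleus centers whose amplitude follows a
    telegraph trace), each over a uniform background with Gaussian noise.
    Per-nucleus random streams are split from the movie seed, so adding
    nuclei never perturbs the traces of existing ones.

    Returns ``(ImageStack, GroundTruth)``.
    """
    from scipy.ndimage import gaussian_filter

    if params_pp7 is None:
        params_pp7 = params
    T, Z, Y, X = spec.field_shape
    params = replace(params, n_frames=T)
    params_pp7 = replace(params_pp7, n_frames=T)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 + spec.n_nuclei)
    place_rng = np.random.default_rng(children[0])
    noise_rng = np.random.default_rng(children[1])

    margin = spec.nucleus_radius_px + 6.0
    pos0 = place_nuclei(place_rng, spec.n_nuclei, (Y, X),
                        spec.nucleus_radius_px, margin)

    n = spec.n_nuclei
    positions = np.empty((n, T, 2))
    clean_ms2 = np.empty((n, T))
    clean_pp7 = np.empty((n, T))
    states_ms2 = np.empty((n, T), dtype=bool)
    states_pp7 = np.empty((n, T), dtype=bool)
    for i in range(n):
        rng_i = np.random.default_rng(children[2 + i])
        # per-frame centroid jitter around the placement anchor; keeps the
        # initial spacing guarantee intact over the whole movie
        jitter = rng_i.normal(0.0, spec.drift_sd_px, (T, 2))
        jitter[0] = 0.0
        path = pos0[i] + jitter
        path[:, 0] = np.clip(path[:, 0], margin, Y - 1 - margin)
        path[:, 1] = np.clip(path[:, 1], margin, X - 1 - margin)
        positions[i] = path
        tr_ms2, gt_ms2 = simulate_trace(params, rng_i, lineage_id=i)
        tr_pp7, gt_pp7 = simulate_trace(params_pp7, rng_i, lineage_id=i,
                                        channel=PP7_CHANNEL)
        clean_ms2[i] = gt_ms2.clean_trace
        clean_pp7[i] = gt_pp7.clean_trace
        states_ms2[i] = gt_ms2.promoter_state
        states_pp7[i] = gt_pp7.promoter_state

    data = np.full((T, 3, Z, Y, X), spec.background_level, dtype=np.float32)
    zc = Z // 2
    for t in range(T):
        his2d = np.zeros((Y, X), dtype=np.float32)
        for i in range(n):
            _add_disk(his2d, positions[i, t, 0], positions[i, t, 1],
                      spec.nucleus_radius_px, _NUCLEAR_MARKER_LEVEL)
        his2d = gaussian_filter(his2d, 1.0)
        data[t, 0] += his2d[None, :, :]
        for ci, clean in ((1, clean_ms2), (2, clean_pp7)):
            if not clean[:, t].any():
                continue
            vol = data[t, ci]
            for i in range(n):
                if clean[i, t] > 0:
                    _add_gaussian3d(vol, zc, positions[i, t, 0],
                                    positions[i, t, 1], clean[i, t],
                                    spec.psf_sd_px)
    if params.noise_sd > 0:
        data += noise_rng.normal(0.0, params.noise_sd,
                                 data.shape).astype(np.float32)
        np.clip(data, 0.0, None, out=data)

    stack = ImageStack(data=data,
                       channels=(HIS_CHANNEL, MS2_CHANNEL, PP7_CHANNEL))
    truth = GroundTruth(
        nucleus_positions=positions,
        clean_ms2=clean_ms2, clean_pp7=clean_pp7,
        states_ms2=states_ms2, states_pp7=states_pp7,
        bursts_ms2=[true_bursts_from_clean(c) for c in clean_ms2],
        bursts_pp7=[true_bursts_from_clean(c) for c in clean_pp7],
    )
    return stack, truth


def simulate_hub_stack(spec: MovieSpec, hub_amplitude: float,
                       hub_sd_px: float, nuclear_level: float = 100.0,
                       noise_sd: float = 5.0, spot_amplitude: float = 1000.0):
    """Render a single-timepoint 3D TF stack with optional hubs.

    The TF channel is a uniform nuclear level inside each nucleus (a z-prism
    of the nuclear disk) plus an isotropic 3D Gaussian "hub" of amplitude
    ``hub_amplitude`` centered on the spot voxel, over camera background and
    Gaussian noise.  The spot channel marks the spot location with a bright
    diffraction-limited Gaussian.

    Returns ``(ImageStack, GroundTruth)``; ground truth records nucleus
    centers and the integer spot voxel of every nucleus.
    """
    _check_finite_nonneg("hub_amplitude", hub_amplitude)
    Z, Y, X = spec.field_shape[-3:]
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2)
    place_rng = np.random.default_rng(children[0])
    noise_rng = np.random.default_rng(children[1])
    margin = spec.nucleus_radius_px + 2.0
    pos = place_nuclei(place_rng, spec.n_nuclei, (Y, X),
                       spec.nucleus_radius_px, margin)
    zc = Z // 2
    spot_voxels = np.column_stack([
        np.full(spec.n_nuclei, zc),
        np.round(pos[:, 0]).astype(int),
        np.round(pos[:, 1]).astype(int),
    ])

    tf2d = np.zeros((Y, X), dtype=np.float32)
    for cy, cx in pos:
        _add_disk(tf2d, cy, cx, spec.nucleus_radius_px, nuclear_level)
    tf = np.broadcast_to(tf2d, (Z, Y, X)).astype(np.float32).copy()
    tf += spec.background_level
    spot = np.full((Z, Y, X), spec.background_level, dtype=np.float32)
    for vz, vy, vx in spot_voxels:
        _add_gaussian3d(tf, vz, vy, vx, hub_amplitude, hub_sd_px)
        _add_gaussian3d(spot, vz, vy, vx, spot_amplitude, spec.psf_sd_px)
    if noise_sd > 0:
        tf += noise_rng.normal(0.0, noise_sd, tf.shape).astype(np.float32)
        spot += noise_rng.normal(0.0, noise_sd, spot.shape).astype(np.float32)

    data = np.stack([tf, spot])[None]  # (1, 2, Z, Y, X)
    stack = ImageStack(data=data, channels=("TF", "spot"))
    truth = GroundTruth(nucleus_positions=pos[:, None, :],
                        hub_amplitude=hub_amplitude,
                        spot_voxels=spot_voxels)
    return stack, truth


# ---------------------------------------------------------------------------
# toy genome fixtures


def simulate_genome_fixture(n_enhancers: int, seed: int,
                            enhancer_bp: int = 1000,
                            read_bp: int = 25,
                            mean_reads: float = 8.0):
    """Emit a toy genome with known TSS-score and orientation ground truth.

    Layout: one enhancer per 20-kb block, a distal exon per block, and for
    every third enhancer an exon overlapping the enhancer 3' end so that the
    50-bp exon-margin filter is exercised on reads inside the enhancer.
    Orientation scenarios cycle through inward / outward / none / both, with
    the "none" case placing its TSS peak just outside the +/-500-bp window.

    Returns ``(enhancers, exons, reads, tf_sites, tss_peaks, GroundTruth)``
    where each collection is a list of :class:`GenomicInterval` and the
    ground-truth table records per-enhancer raw/filtered counts, TSS score,
    and orientation class.
    """
    if n_enhancers < 1:
        raise ValueError("n_enhancers must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = "toy1"
    block = 20_000
    enhancers: list[GenomicInterval] = []
    exons: list[GenomicInterval] = []
    reads: list[GenomicInterval] = []
    tf_sites: list[GenomicInterval] = []
    tss_peaks: list[GenomicInterval] = []
    rows = []
    classes = ("inward", "outward", "none", "both")
    for i in range(n_enhancers):
        base = i * block
        e_start, e_end = base + 8000, base + 8000 + enhancer_bp
        name = f"enh{i}"
        enhancers.append(GenomicInterval(chrom, e_start, e_end, name=name))
        # distal exon, far outside any margin
        exons.append(GenomicInterval(chrom, base + 2000, base + 3000,
                                     name=f"exon{i}a"))
        has_overlap_exon = i % 3 == 1
        if has_overlap_exon:
            exons.append(GenomicInterval(chrom, e_end - 100, e_end + 400,
                                         name=f"exon{i}b"))
        # clean reads: inside the enhancer, > 50 bp from any exon
        n_clean = int(rng.poisson(mean_reads))
        clean_hi = (e_end - 151 - read_bp) if has_overlap_exon \
            else (e_end - read_bp)
        for _ in range(n_clean):
            p = int(rng.integers(e_start, clean_hi))
            reads.append(GenomicInterval(chrom, p, p + read_bp, strand="+"))
        # decoy reads: overlap the expanded exon window, must be filtered
        n_decoy = int(rng.integers(0, 4))
        n_decoy_on_enh = 0
        for _ in range(n_decoy):
            if has_overlap_exon and rng.random() < 0.5:
                p = int(rng.integers(e_end - 140, e_end - 90))
                n_decoy_on_enh += 1
            else:
                p = int(rng.integers(base + 1990, base + 3040))
            reads.append(GenomicInterval(chrom, p, p + read_bp, strand="+"))
        # intergenic background read, on neither exon nor enhancer
        p = int(rng.integers(base + 12_000, base + 15_000))
        reads.append(GenomicInterval(chrom, p, p + read_bp, strand="-"))

        mid = (e_start + e_end) // 2
        tf_sites.append(GenomicInterval(chrom, mid - 50, mid + 50,
                                        name=f"site{i}"))
        cls = classes[i % 4]
        if cls in ("inward", "both"):
            tss_peaks.append(GenomicInterval(chrom, mid - 310, mid - 290,
                                             name=f"tss{i}in", strand="+"))
        if cls in ("outward", "both"):
            tss_peaks.append(GenomicInterval(chrom, mid + 290, mid + 310,
                                             name=f"tss{i}out", strand="+"))
        if cls == "none":
            # outside the +/-500-bp window: must be ignored
            tss_peaks.append(GenomicInterval(chrom, mid + 790, mid + 810,
                                             name=f"tss{i}far", strand="+"))
        rows.append({
            "name": name,
            "raw_count": n_clean + n_decoy_on_enh,
            "filtered_count": n_clean,
            "tss_score": n_clean / (enhancer_bp / 1000.0),
            "orientation_class": cls,
        })
    truth = GroundTruth(table=pd.DataFrame(rows))
    return enhancers, exons, reads, tf_sites, tss_peaks, truth


# ---------------------------------------------------------------------------
# writers


def write_ome_tiff(stack: ImageStack, path) -> None:
    import tifffile

    import warnings

    # stored TZYXC per the pipeline's external interface
    arr = np.moveaxis(stack.data, 1, -1)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=DeprecationWarning,
                                module="tifffile")
        _write_tzyxc(tifffile, path, arr, stack)


def _write_tzyxc(tifffile, path, arr, stack):
    tifffile.imwrite(
        path, arr, metadata={
            "axes": "TZYXC",
            "Channel": {"Name": list(stack.channels)},
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeY": stack.pixel_size_um,
        })


def read_ome_tiff(path, channels: Sequence[str]) -> ImageStack:
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 4:  # T Z Y X single channel
        arr = arr[..., None]
    data = np.moveaxis(arr, -1, 1)
    return ImageStack(data=data, channels=tuple(channels))


def write_ground_truth(truth: GroundTruth, csv_path, json_path,
                       params: TelegraphParams | None = None,
                       spec: MovieSpec | None = None) -> None:
    """Movie ground truth: CSV of per-nucleus-frame rows + JSON of bursts."""
    n, T, _ = truth.nucleus_positions.shape
    rows = {
        "lineage_id": np.repeat(np.arange(n), T),
        "frame": np.tile(np.arange(T), n),
        "y": truth.nucleus_positions[:, :, 0].ravel(),
        "x": truth.nucleus_positions[:, :, 1].ravel(),
        "clean_ms2": truth.clean_ms2.ravel(),
        "clean_pp7": truth.clean_pp7.ravel(),
        "state": truth.states_ms2.astype(int).ravel(),
    }
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.6g")
    payload = {
        "bursts_ms2": truth.bursts_ms2,
        "bursts_pp7": truth.bursts_pp7,
    }
    if params is not None:
        payload["telegraph_params"] = {
            k: getattr(params, k) for k in
            ("k_on", "k_off", "loading_rate", "dwell_frames",
             "intensity_per_transcript", "noise_sd", "n_frames", "seed")}
    if spec is not None:
        payload["movie_spec"] = {
            "n_nuclei": spec.n_nuclei,
            "field_shape": list(spec.field_shape),
            "nucleus_radius_px": spec.nucleus_radius_px,
            "drift_sd_px": spec.drift_sd_px,
            "psf_sd_px": spec.psf_sd_px,
            "background_level": spec.background_level,
            "seed": spec.seed,
        }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
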