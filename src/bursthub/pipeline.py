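"""Pipeline orchestration: staged runs, manifests, and figure-style outputs.

Stages run in dependency order (simulate -> segment -> track -> trace ->
bursts; hubs and tss are independent branches) over a working directory of
plain-text/TIFF intermediates.  Runs are deterministic: identical config and
inputs produce byte-identical CSV outputs (fixed float formatting), and the
manifest records every parameter, seed and output checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bursts import (BurstCallConfig, bursts_table, call_bursts,
                     cumulative_active_fraction, summaries_table,
                     summarize_nuclei)
from .genomics import (call_transcribed, classify_tss_orientation,
                       filter_exonic_reads, records_table, score_enhancers,
                       write_bed)
from .hubs import extract_patch, profiles_table, radial_enrichment, \
    sample_random_site
from .segmentation import LabelMask, SegmentationConfig, segment_frame, \
    segment_tf_stack
from .sim import (GroundTruth, ImageStack, MovieSpec, TelegraphParams,
                  simulate_genome_fixture, simulate_hub_stack,
                  simulate_movie, write_ground_truth, write_ome_tiff)
from .tracking import apply_exclusions, link_frames, tracks_table, \
    valid_tracks
from .traces import build_traces, traces_table

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"
ALL_STAGES = ("simulate", "segment", "track", "trace", "bursts", "hubs",
              "tss", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML-loadable)."""

    outdir: str = "bursthub_out"
    stages: tuple[str, ...] = ("simulate", "segment", "track", "trace",
                               "bursts")
    seed: int = 0
    n_frames: int = 180
    threshold: float | None = None
    crop: tuple[int, int, int, int] | None = None  # y0, y1, x0, x1
    movie: dict = dc_field(default_factory=dict)       # MovieSpec overrides
    telegraph: dict = dc_field(default_factory=dict)   # TelegraphParams
    segmentation: dict = dc_field(default_factory=dict)
    burst: dict = dc_field(default_factory=dict)       # BurstCallConfig extras
    hub: dict = dc_field(default_factory=dict)
    tss: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        if cfg.crop is not None:
            cfg.crop = tuple(cfg.crop)
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise StageError("config", f"unknown stages {sorted(unknown)}")
        needs_threshold = "bursts" in self.stages
        if needs_threshold and self.threshold is None:
            raise StageError("config", "burst calling needs an explicit "
                             "threshold")


def order_trajectories(summaries) -> list[int]:
    """Row order for trajectory heatmaps: ascending transcription onset.

    Never-active nuclei come last, ordered by lineage id.  MS2 and PP7
    orderings are computed from their own summaries, independently.
    """
    def key(s):
        return (s.onset_frame is None,
                s.onset_frame if s.onset_frame is not None else 0,
                s.lineage_id)

    return [s.lineage_id for s in sorted(summaries, key=key)]


def false_color_map(mask: LabelMask, total_output_by_lineage: dict[int, float],
                    label_by_lineage: dict[int, int]) -> np.ndarray:
    """Fill each nucleus region with its normalized total output.

    Pixel values are total_output / max(total_output) in [0, 1]; background
    is 0, so doubling all outputs leaves the image unchanged.  Lineages
    missing from the mask are skipped with a warning.
    """
    img = np.zeros(mask.labels.shape, dtype=float)
    if not total_output_by_lineage:
        return img
    peak = max(total_output_by_lineage.values())
    scale = 1.0 / peak if peak > 0 else 0.0
    present = set(np.unique(mask.labels))
    for lineage, total in total_output_by_lineage.items():
        lab = label_by_lineage.get(lineage)
        if lab is None or lab not in present:
            log.warning("lineage %d missing from mask frame %d; skipped",
                        lineage, mask.frame_index)
            continue
        img[mask.labels == lab] = total * scale
    return img


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _save_csv(df, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and write an output manifest.

    Returns the manifest dict.  Stage failures raise :class:`StageError`
    after writing a partial manifest with the failing stage recorded.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "n_frames": config.n_frames,
            "threshold": config.threshold,
            "crop": list(config.crop) if config.crop else None,
            "movie": config.movie, "telegraph": config.telegraph,
            "segmentation": config.segmentation, "burst": config.burst,
            "hub": config.hub, "tss": config.tss,
        },
        "outputs": {},
    }

    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage in config.stages:
                _STAGE_FUNCS[stage](config, out, state, manifest)
    except StageError:
        _write_manifest(out, manifest, partial=True)
        raise
    except Exception as exc:  # noqa: BLE001 - surface as machine-readable
        _write_manifest(out, manifest, partial=True)
        raise StageError("unknown", str(exc)) from exc
    _write_manifest(out, manifest, partial=False)
    return manifest


def _write_manifest(out: Path, manifest: dict, partial: bool) -> None:
    manifest["partial"] = partial
    for f in sorted(out.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _stage_simulate(config, out, state, manifest):
    spec = MovieSpec(seed=config.seed,
                     **{**{"field_shape": (config.n_frames, 6, 256, 256),
                           "n_nuclei": 20, "nucleus_radius_px": 10.0},
                        **config.movie})
    params = TelegraphParams(seed=config.seed, n_frames=config.n_frames,
                             **config.telegraph)
    movie, truth = simulate_movie(spec, params)
    if config.crop is not None:
        y0, y1, x0, x1 = config.crop
        movie = ImageStack(movie.data[..., y0:y1, x0:x1], movie.channels,
                           movie.pixel_size_um)
        truth.nucleus_positions = truth.nucleus_positions - \
            np.array([y0, x0])[None, None, :]
    write_ome_tiff(movie, out / "movie.ome.tif")
    write_ground_truth(truth, out / "ground_truth.csv",
                       out / "ground_truth.json", params=params, spec=spec)
    state["movie"], state["truth"] = movie, truth
    state["spec"], state["params"] = spec, params


def _require(state, key, stage):
    if key not in state:
        raise StageError(stage, f"missing upstream product {key!r}; run the "
                         "producing stage first")
    return state[key]


def _stage_segment(config, out, state, manifest):
    import tifffile

    movie: ImageStack = _require(state, "movie", "segment")
    seg_cfg = SegmentationConfig(**config.segmentation)
    his = movie.channel("His2Av")
    masks = [segment_frame(his[t].max(axis=0), seg_cfg, frame_index=t)
             for t in range(his.shape[0])]
    tifffile.imwrite(out / "masks.tif",
                     np.stack([m.labels.astype(np.uint16) for m in masks]))
    state["masks"] = masks


def _stage_track(config, out, state, manifest):
    masks = _require(state, "masks", "track")
    tracks = apply_exclusions(link_frames(masks), masks)
    _save_csv(tracks_table(tracks), out / "tracks.csv")
    state["tracks"] = tracks


def _stage_trace(config, out, state, manifest):
    movie = _require(state, "movie", "trace")
    tracks = valid_tracks(_require(state, "tracks", "trace"))
    masks = state["masks"]
    all_traces = []
    for channel in ("MS2", "PP7"):
        if channel in movie.channels:
            all_traces.extend(build_traces(movie, tracks, channel, masks))
    if not all_traces:
        raise StageError("trace", "no requested channel present in movie")
    _save_csv(traces_table(all_traces), out / "traces.csv")
    state["traces"] = all_traces


def _stage_bursts(config, out, state, manifest):
    traces = _require(state, "traces", "bursts")
    cfg = BurstCallConfig(threshold=config.threshold, **config.burst)
    all_bursts = []
    all_summaries = []
    for channel in ("MS2", "PP7"):
        chan_traces = [t for t in traces if t.channel == channel]
        if not chan_traces:
            continue
        bursts = [b for tr in chan_traces for b in call_bursts(tr, cfg)]
        summaries = summarize_nuclei(bursts, chan_traces)
        all_bursts.extend(bursts)
        all_summaries.append((channel, summaries))
    _save_csv(bursts_table(all_bursts), out / "bursts.csv")
    import pandas as pd

    stacked = []
    for channel, summaries in all_summaries:
        df = summaries_table(summaries)
        df.insert(0, "channel", channel)
        stacked.append(df)
    _save_csv(pd.concat(stacked, ignore_index=True), out / "summaries.csv")
    n_frames = config.n_frames
    frac = {channel: cumulative_active_fraction(s, n_frames)
            for channel, s in all_summaries}
    _save_csv(pd.DataFrame({"frame": np.arange(n_frames),
                            **{f"active_fraction_{c.lower()}": v
                               for c, v in frac.items()}}),
              out / "active_fraction.csv")
    state["bursts"] = all_bursts
    state["summaries"] = dict(all_summaries)
    state["burst_config"] = cfg


def _stage_hubs(config, out, state, manifest):
    # default patch side fits inside the radius-7 nuclei that survive the
    # [50, 200] px TF area filter
    hub_cfg = {"n_nuclei": 25, "field_shape": (1, 12, 256, 256),
               "nucleus_radius_px": 7.0, "hub_amplitude": 100.0,
               "hub_sd_px": 3.0, "side_px": 13, **config.hub}
    spec = MovieSpec(
        n_nuclei=hub_cfg["n_nuclei"], field_shape=hub_cfg["field_shape"],
        nucleus_radius_px=hub_cfg["nucleus_radius_px"], seed=config.seed)
    stack, truth = simulate_hub_stack(spec, hub_cfg["hub_amplitude"],
                                      hub_cfg["hub_sd_px"])
    tf = stack.channel("TF")[0]
    spot = stack.channel("spot")[0]
    seg_cfg = SegmentationConfig(**config.segmentation)
    labels3d = segment_tf_stack(tf, seg_cfg)
    rng = np.random.default_rng(config.seed + 1)
    site_patches, rand_patches = [], []
    for lab in range(1, labels3d.max() + 1):
        region = labels3d == lab
        p = extract_patch(tf, spot, region, hub_cfg["side_px"],
                          nucleus_id=lab)
        if p is None:
            continue
        site_patches.append(p)
        r = sample_random_site(tf, region, p.center_voxel[0],
                               hub_cfg["side_px"], rng, nucleus_id=lab)
        if r is not None:
            rand_patches.append(r)
    if not site_patches:
        raise StageError("hubs", "no usable transcription sites")
    _, prof_site = radial_enrichment(site_patches)
    profiles = {"transcription_site": prof_site}
    if rand_patches:
        _, prof_rand = radial_enrichment(rand_patches)
        profiles["random_site"] = prof_rand
    _save_csv(profiles_table(profiles), out / "hub_profiles.csv")
    state["hub_profiles"] = profiles


def _stage_tss(config, out, state, manifest):
    tss_cfg = {"n_enhancers": 20, "threshold_score": 1.0, **config.tss}
    enhancers, exons, reads, tf_sites, tss_peaks, truth = \
        simulate_genome_fixture(tss_cfg["n_enhancers"], seed=config.seed)
    for name, ivs in (("enhancers", enhancers), ("exons", exons),
                      ("reads", reads), ("tf_sites", tf_sites),
                      ("tss_peaks", tss_peaks)):
        write_bed(ivs, out / f"{name}.bed")
    filtered = filter_exonic_reads(reads, exons)
    records = score_enhancers(filtered, enhancers, raw_reads=reads)
    records, curve = call_transcribed(records, tss_cfg["threshold_score"])
    classes = classify_tss_orientation(enhancers, tf_sites, tss_peaks)
    for rec in records:
        rec.orientation_class = classes.get(rec.enhancer.name, "none")
    table = records_table(records)
    table.to_csv(out / "tss_records.tsv", sep="\t", index=False,
                 float_format=FLOAT_FMT)
    _save_csv(curve, out / "tss_cumulative.csv")
    state["tss_records"] = records


def _stage_report(config, out, state, manifest):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traces = state.get("traces")
    summaries = state.get("summaries")
    if not traces or not summaries:
        raise StageError("report", "report needs trace and burst products")
    n_frames = config.n_frames
    for channel, chan_summaries in summaries.items():
        chan_traces = {t.lineage_id: t for t in traces
                       if t.channel == channel}
        order = [i for i in order_trajectories(chan_summaries)
                 if i in chan_traces]
        heat = np.zeros((len(order), n_frames))
        for row, lineage in enumerate(order):
            tr = chan_traces[lineage]
            sel = tr.frames < n_frames
            heat[row, tr.frames[sel]] = tr.baseline_zeroed[sel]
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(heat, aspect="auto", interpolation="nearest",
                       cmap="viridis")
        ax.set_xlabel("frame")
        ax.set_ylabel("nucleus (ordered by onset)")
        fig.colorbar(im, ax=ax, label="baseline-zeroed intensity (a.u.)")
        fig.savefig(out / f"trajectories_{channel.lower()}.png", dpi=120)
        plt.close(fig)

        totals = [s.total_output for s in chan_summaries]
        fig, ax = plt.subplots(figsize=(3, 4))
        ax.boxplot(totals)
        ax.set_ylabel(f"total {channel} output (a.u.)")
        fig.savefig(out / f"total_output_{channel.lower()}.png", dpi=120)
        plt.close(fig)

    masks = state.get("masks")
    if masks:
        frame50 = min(50, len(masks) - 1)
        mask = masks[frame50]
        tracks = valid_tracks(state.get("tracks", []))
        label_by_lineage = {}
        for tr in tracks:
            lab = tr.label_at(frame50)
            if lab is not None:
                label_by_lineage[tr.lineage_id] = lab
        for channel, chan_summaries in summaries.items():
            totals = {s.lineage_id: s.total_output for s in chan_summaries}
            img = false_color_map(mask, totals, label_by_lineage)
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.imshow(img, cmap="inferno")
            ax.set_axis_off()
            fig.savefig(out / f"false_color_{channel.lower()}.png", dpi=120)
            plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "track": _stage_track,
    "trace": _stage_trace,
    "bursts": _stage_bursts,
    "hubs": _stage_hubs,
    "tss": _stage_tss,
    "report": _stage_report,
}
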