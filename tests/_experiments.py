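"""Shared experiment drivers for the acceptance checks.

Used by both the pytest acceptance suite and scripts/acceptance.py so the
two always measure the same quantities the same way.  Problem sizes are
desk-scale (small fields, tens of nuclei); kinetic parameters are the
generators' defaults.
"""

from __future__ import annotations

import numpy as np

from bursthub.bursts import BurstCallConfig, call_bursts
from bursthub.hubs import (EnrichmentPatch, compare_profile_areas,
                           endmost_complete_bin, extract_patch,
                           radial_enrichment, sample_random_site,
                           site_profile_areas)
from bursthub.segmentation import SegmentationConfig, segment_frame, \
    segment_tf_stack
from bursthub.sim import (MovieSpec, TelegraphParams, gaussian_window_mass,
                          simulate_hub_stack, simulate_movie, simulate_trace)
from bursthub.tracking import (apply_exclusions, count_identity_swaps,
                               link_frames, valid_tracks)
from bursthub.traces import SpotTrace, build_traces

from tests._reference import ref_call_bursts

# study-condition constants (chosen once; see docs/methods.md)
RECOVERY_SPEC = dict(n_nuclei=20, field_shape=(180, 3, 192, 192),
                     nucleus_radius_px=9.0, drift_sd_px=0.3)
K_ON_GRID = (0.02, 0.05, 0.1)
K_OFF = 0.15
THRESHOLD_FRACTION = 0.2  # of the steady-state ON plateau, extracted units

HUB_SPEC = dict(n_nuclei=25, field_shape=(1, 9, 384, 384),
                nucleus_radius_px=17.0)
HUB_SD = 3.0
HUB_NUCLEAR = 100.0
HUB_NOISE = 5.0
HUB_SIDE = 29


def burst_caller_agreement(n_traces: int, seed: int,
                           n_frames: int = 180) -> float:
    """Fraction of random traces whose burst intervals match the oracle."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    matches = 0
    for _ in range(n_traces):
        k_on = rng.uniform(0.01, 0.2)
        k_off = rng.uniform(0.05, 0.4)
        params = TelegraphParams(
            k_on=k_on, k_off=k_off, loading_rate=rng.uniform(1.0, 3.0),
            dwell_frames=int(rng.integers(2, 9)),
            noise_sd=rng.uniform(0.3, 1.5), n_frames=n_frames)
        trace, _ = simulate_trace(params, rng)
        threshold = rng.uniform(0.5, 0.5 * params.loading_rate
                                * params.dwell_frames)
        cfg = BurstCallConfig(threshold=threshold)
        got = [(b.start_frame, b.end_frame)
               for b in call_bursts(trace, cfg)]
        if got == ref_call_bursts(trace.raw, threshold):
            matches += 1
    return matches / n_traces


def extraction_threshold(params: TelegraphParams, spec: MovieSpec) -> float:
    """Burst threshold in extracted-signal units: a fixed fraction of the
    steady-state ON plateau times the 5x5 Gaussian window mass."""
    plateau = (params.loading_rate * params.dwell_frames
               * params.intensity_per_transcript)
    return THRESHOLD_FRACTION * plateau * gaussian_window_mass(spec.psf_sd_px)


def run_recovery_movie(k_on: float, seed: int):
    """Simulate/segment/track/extract/call one movie; return per-nucleus
    recovered and ground-truth burst counts and per-burst sizes, plus the
    identity-swap count."""
    spec = MovieSpec(seed=seed, **RECOVERY_SPEC)
    params = TelegraphParams(k_on=k_on, k_off=K_OFF, seed=seed)
    movie, truth = simulate_movie(spec, params)
    cfg = SegmentationConfig()
    his = movie.channel("His2Av")
    masks = [segment_frame(his[t].max(axis=0), cfg, frame_index=t)
             for t in range(his.shape[0])]
    tracks = apply_exclusions(link_frames(masks), masks)
    vt = valid_tracks(tracks)
    swaps = count_identity_swaps(vt, truth.nucleus_positions)
    traces = build_traces(movie, vt, "MS2", masks)
    bc = BurstCallConfig(threshold=extraction_threshold(params, spec))
    rec_counts, rec_sizes = [], []
    gt_counts = []
    for tr in traces:
        bursts = call_bursts(tr, bc)
        rec_counts.append(len(bursts))
        rec_sizes.extend(b.size for b in bursts)
        # ground-truth partner by frame-0 position
        p0 = next(t for t in vt if t.lineage_id == tr.lineage_id).points[0]
        pos = truth.nucleus_positions[:, 0, :]
        g = int(np.argmin(np.hypot(pos[:, 0] - p0.centroid_yx[0],
                                   pos[:, 1] - p0.centroid_yx[1])))
        gt_counts.append(len(truth.bursts_ms2[g]))
    return rec_counts, rec_sizes, gt_counts, swaps


def recovery_experiment(seed: int, seeds_per_condition: int = 3):
    """Parameter-recovery sweep over the k_on grid.

    Returns dict k_on -> (median recovered frequency, median ground-truth
    frequency, median recovered burst size) and the total swap count.
    """
    out = {}
    total_swaps = 0
    for i, k_on in enumerate(K_ON_GRID):
        rec_counts, rec_sizes, gt_counts = [], [], []
        for j in range(seeds_per_condition):
            rc, rs, gc, swaps = run_recovery_movie(
                k_on, seed=seed + 1000 * i + j)
            rec_counts.extend(rc)
            rec_sizes.extend(rs)
            gt_counts.extend(gc)
            total_swaps += swaps
        out[k_on] = (float(np.median(rec_counts)),
                     float(np.median(gt_counts)),
                     float(np.median(rec_sizes)))
    return out, total_swaps


def _hub_stack(amplitude: float, seed: int, nuclear=HUB_NUCLEAR):
    spec = MovieSpec(seed=seed, **HUB_SPEC)
    return simulate_hub_stack(spec, amplitude, HUB_SD,
                              nuclear_level=nuclear, noise_sd=HUB_NOISE)


def hub_patches_segmented(amplitude: float, seed: int, n_sites: int = 50):
    """True-site patches through the full segmentation path, pooling stacks
    until ``n_sites`` patches are collected."""
    cfg = SegmentationConfig(tf_min_area_px=600, tf_max_area_px=1300)
    patches = []
    k = 0
    while len(patches) < n_sites and k < 8:
        stack, truth = _hub_stack(amplitude, seed + 71 * k)
        tf = stack.channel("TF")[0]
        spot = stack.channel("spot")[0]
        labels3d = segment_tf_stack(tf, cfg)
        for lab in range(1, labels3d.max() + 1):
            p = extract_patch(tf, spot, labels3d == lab, HUB_SIDE,
                              nucleus_id=lab)
            if p is not None:
                patches.append(p)
        k += 1
    return patches[:n_sites]


def hub_patches_at_truth(stack, truth):
    """Patches cropped at the ground-truth spot voxels (fast path used for
    the repeated power simulations)."""
    tf = stack.channel("TF")[0]
    h = HUB_SIDE // 2
    patches = []
    for i, (vz, vy, vx) in enumerate(truth.spot_voxels):
        if vy - h < 0 or vx - h < 0 or vy + h >= tf.shape[1] \
                or vx + h >= tf.shape[2]:
            continue
        patches.append(EnrichmentPatch(
            tf[vz, vy - h:vy + h + 1, vx - h:vx + h + 1],
            (int(vz), int(vy), int(vx)), nucleus_id=i))
    return patches


def hub_central_errors(seed: int, ratios=(1.25, 1.5, 2.0),
                       n_sites: int = 50) -> dict[float, float]:
    """Relative error of the central-bin enrichment vs the closed form."""
    ref = endmost_complete_bin(HUB_SIDE)
    errors = {}
    for i, ratio in enumerate(ratios):
        amplitude = (ratio - 1.0) * HUB_NUCLEAR
        patches = hub_patches_segmented(amplitude, seed + 17 * i,
                                        n_sites=n_sites)
        _, prof = radial_enrichment(patches)
        enr0 = prof["mean_relative_enrichment"][0]
        expected = (HUB_NUCLEAR + amplitude) / (
            HUB_NUCLEAR + amplitude * np.exp(-ref ** 2 / (2 * HUB_SD ** 2)))
        errors[ratio] = abs(enr0 - expected) / expected
    return errors


def hub_null_deviation(seed: int, n_sites: int = 50) -> float:
    """Max |enrichment - 1| in SEM units for the hubless condition."""
    patches = hub_patches_segmented(0.0, seed, n_sites=n_sites)
    _, prof = radial_enrichment(patches)
    ref = endmost_complete_bin(HUB_SIDE)
    sel = prof.index[1:ref]  # skip exact-1 reference bin; bin 0 is 1 px
    dev = np.abs(prof["mean_relative_enrichment"][sel] - 1.0)
    sem = np.maximum(prof["sem"][sel], 1e-9)
    return float((dev / sem).max())


def random_site_null_deviation(seed: int, n_sites: int = 200) -> float:
    """Random-site null on a homogeneous TF field, in SEM units."""
    spec = MovieSpec(seed=seed, background_level=HUB_NUCLEAR, **HUB_SPEC)
    stack, truth = simulate_hub_stack(spec, 0.0, HUB_SD, nuclear_level=0.0,
                                      noise_sd=HUB_NOISE)
    tf = stack.channel("TF")[0]
    rng = np.random.default_rng(seed + 5)
    yy, xx = np.mgrid[: tf.shape[1], : tf.shape[2]]
    patches = []
    while len(patches) < n_sites:
        for vz, vy, vx in truth.spot_voxels:
            disk = (yy - vy) ** 2 + (xx - vx) ** 2 <= \
                HUB_SPEC["nucleus_radius_px"] ** 2
            region = np.broadcast_to(disk, tf.shape)
            p = sample_random_site(tf, region, int(vz), HUB_SIDE, rng)
            if p is not None:
                patches.append(p)
    patches = patches[:n_sites]
    _, prof = radial_enrichment(patches)
    ref = endmost_complete_bin(HUB_SIDE)
    sel = prof.index[:ref]
    dev = np.abs(prof["mean_relative_enrichment"][sel] - 1.0)
    sem = np.maximum(prof["sem"][sel], 1e-9)
    return float((dev / sem).max())


def hub_power(seed: int, n_reps: int = 100, alpha: float = 0.01) -> float:
    """Fraction of repetitions where ratio-2.0 vs ratio-1.0 rejects."""
    rejections = 0
    for r in range(n_reps):
        stack_a, truth_a = _hub_stack(HUB_NUCLEAR, seed + 2 * r)
        stack_b, truth_b = _hub_stack(0.0, seed + 2 * r + 1)
        pa = hub_patches_at_truth(stack_a, truth_a)
        pb = hub_patches_at_truth(stack_b, truth_b)
        # two stacks of 25 nuclei per arm
        stack_a2, truth_a2 = _hub_stack(HUB_NUCLEAR, seed + 7000 + 2 * r)
        stack_b2, truth_b2 = _hub_stack(0.0, seed + 7000 + 2 * r + 1)
        pa += hub_patches_at_truth(stack_a2, truth_a2)
        pb += hub_patches_at_truth(stack_b2, truth_b2)
        if compare_profile_areas(pa[:50], pb[:50]) < alpha:
            rejections += 1
    return rejections / n_reps


def genomics_oracle_agreement(n_annotations: int, seed: int) -> float:
    """Fraction of random toy annotations where filtering, counting and
    classification match the quadratic oracle exactly (including reads at
    the expanded exon boundaries offset by -2..+2 bp)."""
    from bursthub.genomics import (GenomicInterval, classify_tss_orientation,
                                   filter_exonic_reads, score_enhancers)
    from tests._reference import (ref_classify, ref_count_reads,
                                  ref_filter_exonic)

    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_annotations):
        enhancers = [GenomicInterval("c", int(s),
                                     int(s) + int(rng.integers(200, 2000)),
                                     name=f"e{i}")
                     for i, s in enumerate(rng.integers(0, 80_000, 8))]
        exons = [GenomicInterval("c", int(s),
                                 int(s) + int(rng.integers(100, 800)))
                 for s in rng.integers(0, 80_000, 12)]
        reads = [GenomicInterval("c", int(s), int(s) + 25)
                 for s in rng.integers(0, 80_000, 120)]
        # boundary probes around every expanded exon edge
        for ex in exons[:4]:
            for off in (-2, -1, 0, 1, 2):
                lo = ex.start - 50 - 25 + off
                if lo >= 0:
                    reads.append(GenomicInterval("c", lo, lo + 25))
                reads.append(GenomicInterval("c", ex.end + 50 + off,
                                             ex.end + 75 + off))
        sites = [GenomicInterval("c", int(s), int(s) + 100, name=f"s{i}")
                 for i, s in enumerate(rng.integers(0, 80_000, 10))]
        peaks = [GenomicInterval("c", int(s), int(s) + 20,
                                 strand="+" if rng.random() < 0.5 else "-")
                 for s in rng.integers(0, 80_000, 25)]
        good = True
        filt = filter_exonic_reads(reads, exons)
        good &= filt == ref_filter_exonic(reads, exons)
        recs = score_enhancers(filt, enhancers, raw_reads=reads)
        for rec in recs:
            good &= rec.filtered_count == ref_count_reads(rec.enhancer, filt)
            good &= rec.raw_count == ref_count_reads(rec.enhancer, reads)
        classes = classify_tss_orientation(enhancers, sites, peaks)
        for enh in enhancers:
            good &= classes[enh.name] == ref_classify(enh, sites, peaks)
        ok += bool(good)
    return ok / n_annotations
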