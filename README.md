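# bursthub

Quantitative analysis of **simultaneous gene and non-coding enhancer
transcription** in live *Drosophila* embryos.  Two-color MS2/PP7 live
imaging renders nascent transcription of a reporter gene (MS2 stem-loops
bound by MCP-GFP) and of the non-coding RNA produced at its enhancer (PP7
stem-loops bound by PCP-mCherry) as diffraction-limited nuclear spots.
`bursthub` turns such movies into per-nucleus burst statistics, quantifies
the radial enrichment of transcription-factor "hubs" around transcription
sites in 3D super-resolution stacks, and scores enhancer transcription-start
sites (TSS) from stranded CAGE/RAMPAGE-style reads — with a first-class
synthetic-data generator so the whole pipeline is testable against known
ground truth without any external data.

Who it is for: quantitative biologists analyzing nc14-style live-imaging
experiments (or benchmarking burst-calling procedures) who want a tested,
scriptable reimplementation of this analysis chain.

## The analysis chain

1. **Segmentation** (`bursthub.segmentation`) — per-frame z maximum
   projection of the nuclear-marker channel; median filter → 5/25 px
   difference-of-Gaussians bandpass → Otsu threshold → distance-transform
   watershed, with regions bounded by the Voronoi partition of the markers.
   A TF-channel variant applies an inclusive [50, 200] px area filter and
   extends regions into 3D z-prisms.
2. **Tracking** (`bursthub.tracking`) — lineages linked by minimal centroid
   displacement (greedy, one-to-one); a lineage is excluded if its region
   ever touches the image border or jumps farther than the nucleus length.
3. **Trace extraction** (`bursthub.traces`) — per frame, the spot signal is
   the integral of the 5×5 px window centered on the brightest pixel in the
   nucleus minus 25× the median nuclear intensity; traces are baseline-
   zeroed by subtracting their minimum.
4. **Burst calling** (`bursthub.bursts`) — lowess smoothing (local linear
   regression, tricube weights, 10-frame window), maximal supra-threshold
   runs, valley splitting of touching bursts (strict two-frame decrease then
   increase), and a ≥ 5-frame duration filter.  Statistics per nucleus:
   burst frequency, burst size ∫(baseline-zeroed raw) over each burst,
   total output ∫ over all frames, onset, cumulative active fraction,
   instantaneous and mean activities.  Group comparisons use the two-sided
   Wilcoxon rank-sum test with Bonferroni correction.
5. **Hub enrichment** (`bursthub.hubs`) — 29×29 (or 41×41) px TF-channel
   patches on the z-plane of the brightest spot voxel of each 3D-segmented
   nucleus, with random-site controls; pixels binned by integer radial
   distance, per-site bins normalized by the endmost complete bin; profiles
   report mean ± SEM across sites and conditions are compared by per-site
   curve areas (rank-sum).
6. **TSS genomics** (`bursthub.genomics`) — reads within 50 bp of any exon
   are removed; the TSS score of an enhancer is its filtered read count per
   kb; enhancers are classified *inward* / *outward* / *both* / *none* by
   whether stranded TSS peaks within ±500 bp of an overlapping TF-binding
   site transcribe toward or away from the site.
7. **Synthetic data** (`bursthub.sim`) — two-state telegraph promoter
   (ON/OFF switching at k_on/k_off per frame, deterministic loading while
   ON, boxcar transcript dwell) rendered as spot movies over drifting
   nuclear fields; 3D stacks with injectable Gaussian TF hubs; toy genomes
   with known TSS scores and orientation classes.

## Worked example

Simulate a small two-color movie, run the imaging chain, and call bursts:

```python
import numpy as np
from bursthub.sim import MovieSpec, TelegraphParams, simulate_movie
from bursthub.segmentation import SegmentationConfig, segment_frame
from bursthub.tracking import link_frames, apply_exclusions, valid_tracks
from bursthub.traces import build_traces
from bursthub.bursts import BurstCallConfig, call_bursts, summarize_nuclei

spec = MovieSpec(n_nuclei=15, field_shape=(180, 3, 160, 160),
                 nucleus_radius_px=9, seed=11)
params = TelegraphParams(k_on=0.05, k_off=0.15, seed=11)
movie, truth = simulate_movie(spec, params)

his = movie.channel("His2Av")
masks = [segment_frame(his[t].max(axis=0), SegmentationConfig(),
                       frame_index=t) for t in range(180)]
tracks = valid_tracks(apply_exclusions(link_frames(masks), masks))
traces = build_traces(movie, tracks, "MS2", masks)

# threshold in extracted units: 20% of the steady-state ON plateau
# (loading_rate x dwell x intensity, times the 5x5 Gaussian window mass)
cfg = BurstCallConfig(threshold=28.0)
bursts = [b for tr in traces for b in call_bursts(tr, cfg)]
summaries = summarize_nuclei(bursts, traces)
freq = [s.burst_frequency for s in summaries]
print(f"{len(tracks)} lineages, median burst frequency "
      f"{np.median(freq):.0f}, ground-truth median "
      f"{np.median([len(b) for b in truth.bursts_ms2]):.0f}")
```

This prints

```
15 lineages, median burst frequency 5, ground-truth median 5
```

— 15 tracked lineages whose recovered per-nucleus burst count matches the
generator's ground truth at the cohort median.  Burst sizes and total
outputs are in arbitrary intensity·frame units, as in any uncalibrated
fluorescence experiment.

The same chain is available from the shell:

```sh
bursthub run config.yaml --seed 11 --threshold 28
bursthub tss --out out_tss --seed 3      # genomics branch only
```

Each run writes CSV/TSV tables, label-mask and OME-TIFF images, and a
`manifest.json` recording every parameter, seed and output checksum; runs
with identical configs are byte-identical.

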