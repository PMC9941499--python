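# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `bursthub`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Telegraph model and synthetic traces

The generator's transcription model is the two-state telegraph promoter:
per frame, an OFF promoter switches ON with probability `k_on` and an ON
promoter switches OFF with probability `k_off` (rates are per-frame
probabilities; the initial state is drawn from the stationary distribution
`p_ON = k_on / (k_on + k_off)`).  While ON the promoter loads
`loading_rate` nascent transcripts per frame — deterministically, so the
rate is a mean Pol II loading and may be fractional — and each transcript
contributes `intensity_per_transcript` units of signal for `dwell_frames`
frames (boxcar dwell).  The noise-free trace is therefore the convolution
of the ON indicator with a boxcar, and its support is exactly the union of
ON runs extended by the dwell time; *true bursts* are defined as the
maximal runs of positive noise-free signal.  Observed traces add Gaussian
noise (`noise_sd`) clipped at zero.

Deterministic loading was chosen over Poisson loading so that the
degenerate cases (never-ON, never-OFF) and the clean-trace support are
exact statements rather than almost-sure ones, and so that spot-extraction
accuracy can be checked against a closed-form Gaussian window mass.  The
cost is that the generator underestimates initiation shot noise; the
additive Gaussian term stands in for all intensity noise.

Default kinetics (`k_on = 0.05`, `k_off = 0.15` per frame, `dwell = 6`
frames, `loading = 2` per frame, `noise_sd = 0.8`) describe a moderately
bursty promoter at a ~17 s frame interval: mean ON period ~6.7 frames
(\~2 min), ON fraction 0.25, bursts of a few minutes — typical magnitudes
for developmental promoters in nc14-style recordings.  They are documented
defaults of the generator, not measurements of any embryo data set.

## Synthetic movies, hub stacks and toy genomes

Movies are T×C×Z×Y×X stacks with three channels: a nuclear marker rendered
as blurred disks, and MS2/PP7 spot channels rendered as isotropic 3D
Gaussians (SD `psf_sd_px`) whose peak amplitude follows each nucleus's
clean telegraph trace, over a uniform background with Gaussian noise.
Nuclei are placed by rejection sampling with center spacing ≥ 2.5× the
nucleus radius and *jittered* per frame around their placement anchor
(`drift_sd_px` is the per-frame centroid jitter SD).  Anchored jitter
rather than a random walk keeps the spacing guarantee valid over the whole
movie; nc14 nuclei do not interpenetrate, and a free random walk at
desk-scale fields eventually merges neighbors, which is a rendering
artifact rather than a tracking scenario of interest.  Random streams are
split per nucleus from the movie seed, so enlarging a field never perturbs
the traces of existing nuclei.  Non-goals of the renderer: photobleaching,
nuclear divisions, z-drift, realistic PSFs, initiation shot noise.

Hub stacks are single-timepoint Z×Y×X fields: a uniform nuclear TF level
inside each nucleus plus an isotropic 3D Gaussian "hub" of amplitude `A`
and SD `σ` centered on the integer spot voxel, plus noise; the spot channel
marks the spot.  On the spot's z-plane the expected radial profile is
`(L + A·exp(−r²/2σ²)) / (L + A·exp(−R²/2σ²))` after endmost-bin
normalization at radius `R`, which is the closed form the recovery tests
check (10% tolerance on the central bin, 50 sites).

One geometric caveat matters at desk scale: the closed form and the flat
null both presuppose that the analysis patch lies inside the nucleus.  The
29×29 px patch of the real protocol is small relative to a real nucleus,
but not relative to a synthetic nucleus a few tens of pixels across.
True-site patches are therefore validated on nuclei that cover the patch
(radius 17 px for side 29), and the random-site null calibration is run on
a spatially homogeneous TF field — the regime the flat-null statement is
about.  With dark extranuclear background and small nuclei, random patches
clip the nucleus rim and the control shows residual central enrichment;
that regime is exercised separately with the weaker (and correct)
requirement that the random control stays far below the true-site
enrichment.

Toy genomes place one 1-kb enhancer per 20-kb block with a distal exon,
an exon overlapping every third enhancer's 3′ end (to exercise the 50-bp
margin filter on enhancer reads), reads inside and near exons, a central
TF-binding site, and stranded TSS peaks engineered to realize each
orientation class — including a peak just outside the ±500-bp window for
the "none" class.  Ground truth (filtered counts, scores, classes) is
recorded by construction.

## Segmentation

Per-frame chain on the z maximum projection: median filter (radius 1 px
default; unstated in the original protocol) → difference-of-Gaussians
bandpass with σ = cut/2.355 for the 5/25 px size cuts (the conventional
FWHM reading of a size-cut bandpass) → Otsu threshold → hole filling and
removal of specks below the low cut → distance transform → peak markers
with minimum separation `high_cut/2` → watershed on the negated distance
transform → final regions bounded by the Voronoi partition of the markers
(every foreground pixel assigned to its nearest marker).  For near-circular
nuclei the watershed ridge and the Voronoi bisector coincide; the explicit
Voronoi bound makes the partition watertight and deterministic.  A
near-constant frame yields an empty mask with a logged warning.  Mask
hand-editing in the original protocol is replaced by deterministic,
unattended operation; concave blobs can in principle yield non-4-connected
Voronoi∩foreground regions (not observed on disk-like nuclei).

The TF-stack variant segments the z maximum projection, keeps regions with
area in the inclusive band [50, 200] px (both bounds inclusive; "between"
is ambiguous), and extends each region across all z-slices as a prism —
the simplest consistent reading of a 3D voxel region built from a 2D mask.

## Tracking

Greedy one-to-one linking in ascending centroid distance with a
(distance, previous label, current label) tie-break; unmatched detections
start new lineages; no gap closing.  Exclusions apply to whole lineages:
border contact in any frame, or a per-step displacement strictly greater
than the nucleus length, taken as the region's major-axis length in the
earlier frame (displacement exactly equal to the length is retained).

## Trace extraction

The spot signal is `Σ(5×5 window centered on the brightest region pixel)
− n_window × median(region)`.  Argmax ties break row-major (lowest row,
then column); window pixels outside the region but inside the image are
included; at the image border the window is cropped and the background
multiplier is the actual pixel count, so a uniform region scores exactly
zero in every geometry.  The signal may be negative before per-trace
baseline zeroing (subtraction of the trace minimum, making the minimum
exactly 0).  Adding a constant to a whole channel cancels in the
median-background and baseline steps.  Intensities remain in native
camera units.

## Burst calling

Traces are smoothed by lowess: locally weighted linear regression with
tricube weights over the 10 nearest frames (a sliding window, shifted
inward at the boundaries), zero robustifying iterations.  The local linear
fit reproduces constants and straight lines exactly; traces shorter than
the window clamp the span with a warning.  Maximal runs with smoothed
signal strictly above the threshold are candidates; runs are divided at
valley frames where the smoothed series strictly decreased over the prior
two frames and strictly increases over the next two (plateaus do not
split; the valley frame starts the later fragment; the rule is applied
left-to-right and re-evaluated on the remainder).  Fragments shorter than
5 frames are discarded, including fragments created by splitting.  Burst
end is the last supra-threshold frame (inclusive).  Sizes and total
outputs integrate the baseline-zeroed *raw* trace, never the smoothed one.

The threshold is a required analysis input in trace units.  A documented
per-trace default of `k × MAD` of the trace's sub-median fluctuations is
provided (`mad_threshold`, `k = 3`); note that because the threshold is
applied to the *smoothed* series, whose noise floor is several-fold lower
than the raw one, a raw-MAD-referenced cut should be validated (and `k`
raised) for wide smoothing windows — at `k = 3` it sits close to the
smoothed noise floor and over-calls on heavily smoothed data.  The
validation experiments instead pass an explicit threshold of 20% of the
known steady-state ON plateau in extracted units
(`loading_rate × dwell_frames × intensity` times the 5×5 Gaussian window
mass), which is well above the smoothed noise floor for the rendering
noise used.

Burst frequency is the count of retained bursts per nucleus; the
cumulative active fraction is the running fraction of nuclei whose first
retained burst has started.  Instantaneous activity averages trace values
over the nuclei currently inside (or, for conditioned comparisons, outside)
a retained burst — the conditioning bursts may come from the other channel,
which is how MS2 activity is stratified by concurrent PP7 bursting.  Group
comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney U) test via
scipy, exact for small tie-free samples, with Bonferroni multiplication
capped at 1.

Burst-count recovery against the generator is definition-sensitive: the
generator's true bursts merge ON runs separated by less than the dwell
time (the rendered signal never reaches zero there), while the
valley-splitting caller can resolve exactly such sub-dwell gaps.  At high
switching rates the caller therefore counts somewhat more bursts than the
clean-trace-run definition; the recovery experiments compare cohort
medians, where the two definitions agree to within the stated tolerance.

## Hub radial enrichment

Sites are the brightest spot voxel in each 3D-segmented nucleus (top-X%
selection by integrated spot signal keeps all ties at the cutoff); patches
are read on that single z-plane and skipped, not padded, when they would
leave the image (padding would bias edge bins).  Pixels are binned by
round-half-up Euclidean distance from the center ("a pixel increment");
bin 0 is the center pixel alone.  Each site's bin means are divided by
that site's endmost *complete* bin (the inscribed radius, side//2), so the
reference bin is exactly 1 with zero SEM; bins beyond it (patch corners)
are reported but flagged incomplete.  Profiles are mean ± SEM across
sites (not across pixels).  Random-site controls draw a uniform pixel of
the same nucleus on the same z-plane, with one documented seed per run.
Condition comparisons reduce each site to the area `Σ(enrichment − 1)`
over complete bins and apply the rank-sum test.

## Pipeline and outputs

Stages (simulate → segment → track → trace → bursts; hubs and tss as
independent branches; report for figures) run from a YAML config or CLI
flags.  All CSV outputs use fixed `%.6g` float formatting, so identical
configs produce byte-identical files; `manifest.json` records parameters,
seeds, package version and SHA-256 checksums of every output.  Trajectory
heatmaps order nuclei by transcription onset (never-active last, by
lineage id; channels ordered independently); false-color maps fill each
nucleus region with its total output normalized to the cohort maximum at
the 50th-frame mask.

## Genomic conventions

All coordinates are 0-based half-open (BED).  A read lies "on" an
enhancer if they overlap by ≥ 1 bp.  Exon filtering removes reads
overlapping exons expanded by 50 bp on each side (an exact half-open abut
is not an overlap) and is idempotent.  TSS scores are reads per kb of
enhancer.  The ±500-bp orientation window is anchored on the TF-site
interval midpoint (integer division); a TSS peak is *inward* if it
overlaps the site or if transcription proceeds toward it (plus strand left
of the midpoint, minus strand right of it); enhancers aggregate their
sites' votes into inward / outward / both / none, with "both" reported as
its own class.  The transcribed-enhancer threshold is a config input
(score ≥ threshold; with threshold 0 the comparison is strict so
zero-score enhancers are never called transcribed).  Unstranded TSS peaks
are skipped with a warning.

## Problem sizes

End-to-end experiments run at desk scale, chosen as the smallest fields
that keep ≥ 15–20 analyzable nuclei and the full 180-frame window:
192×192 px, 3 z-slices, 20 nuclei of radius 9 px for recovery movies;
384×384 px, 9 z-slices, 25 nuclei of radius 17 px for hub stacks (nuclei
sized to cover the 29×29 patch).  The generator's full-scale defaults
(512×512, 18 z, 80 nuclei) remain available.

## Known limitations

- The renderer's noise model is additive Gaussian; no Poisson shot noise,
  bleaching or z-drift, so real-data SNR regimes are not represented.
- Segmentation assumes near-circular, non-dividing nuclei; no
  learning-based fallback and no mitotic-figure handling.
- Sub-pixel spot localization, 3D spot fitting and chromatic registration
  are out of scope; frame intervals are assumed uniform.
- The hub analysis is 2D-radial on a single z-plane; hubs are not counted
  or tracked over time.
- The genomics module consumes already-positioned BED records; alignment
  and peak calling are upstream of the package.
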