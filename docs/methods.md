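# Methods

## Scope and model

`nmjquant` quantifies single-plane, multi-channel fluorescence micrographs
of NMJ coculture experiments. Every image is a `CalibratedImage`: a 2D grid
of non-negative intensities in arbitrary units plus a pixel size in µm.
Coordinates are 0-based `(row, col)` with the origin at the top-left; one
pixel covers `pixel_size_um²` µm². Reading never rescales intensities, and
integer data stay integer until a filtering operation needs floating point.
Acquisition pixel size is never assumed: the caller supplies it (TIFF
resolution tags are honored only as a fallback), because every µm²- and
mm²-denominated quantity depends on it.

## Nucleus detection and segmentation

Detection is a scale-space Laplacian-of-Gaussian blob detector
(`min_sigma_px`–`max_sigma_px`, default 2–6 px, ten scales, 50% overlap
suppression) with an absolute response threshold. It is deterministic and
parameter-transparent; it deliberately replaces learned detectors, since the
downstream classification rules only need center points of well-separated
DAPI nuclei. Segmentation is a seeded watershed on the inverted
Gaussian-smoothed DAPI image, restricted to foreground above a threshold
(Otsu on the smoothed image unless an explicit value is given — explicit
values always win, as every threshold in this pipeline is by design
user-defined). Each seed on foreground yields exactly one mask.

Region features use one moment convention everywhere: second central
moments over pixel-center coordinates with **no** +1/12 per-pixel variance
term, so a single-pixel object has major axis 0 and eccentricity 0. Objects
are 4-connected throughout, consistent with the topology of the 3×3 diamond
structuring element used by the elongation stage. The test suite checks the
moments against an independent per-pixel covariance oracle at 1e-9 relative
tolerance.

## Marker positivity

Both rules use strict inequality (score > threshold), applied uniformly so
that a threshold equal to the background calls nothing positive. The point
rule smooths with σ = 0.5 px (reflective boundaries) and takes the window
maximum over 3×3 px centered at each detected nucleus; border windows are
clipped, not discarded, to avoid biasing edge-dense fields. With window 1
and σ = 0 the rule degenerates to per-pixel thresholding (tested). The
nuclear-mean rule averages the marker channel over each segmented nuclear
mask. Thresholds have no defaults — they are the analysis' chief free
parameter, and the pipeline logs every one together with its provenance
(user / Otsu).

## Elongation index

Parameters and defaults: smoothing σ = 8 px; user-defined segmentation
threshold; 8 erosions + 8 dilations with the 3×3 diamond; minimum area
960 px²; minimum eccentricity 0.75; minimum major axis 120 px; denominator
= number of marker-positive cells in the same field, supplied by the caller
so the statistic's two halves stay independently testable.

Numerical choices:

* outside-image pixels are background for both erosion and dilation, which
  keeps the opening anti-extensive exactly; wide objects touching the
  border therefore contribute boundary slivers to the residual, and the
  synthetic generator keeps bodies ≥ 20 px from the frame edge;
* the XOR of raw and opened segmentation is computed as the set difference
  after asserting containment — identical result, and the assertion guards
  the implementation;
* all three filters are strict "smaller than" deletions, so objects at
  exactly 960 px² / 0.75 / 120 px survive;
* the index is reported per image; aggregation across replicates (mean ±
  SD) happens in the reporting layer, and per-image values are always
  exported so either per-image or pooled aggregation can be computed.

Iterated diamond erosion/dilation is verified bit-exactly against an
exhaustive neighborhood-sweep oracle on random grids, and the analytic
8×150 px rod case (residual = the rod, major axis 173.2 px, eccentricity
0.9986) against the covariance oracle.

## AChR clusters and myotubes

Clusters are 4-connected components of the thresholded α-bungarotoxin
channel with a minimum-area filter (default 4 px²), the automatable
surrogate for interactive speck rejection; an image blocklist replaces
manual exclusion of detached-myotube fields. Myotube area for count
normalization comes from a percentile contrast stretch (default 1–99%)
mapped to [0, 1], thresholded (default 0.5), with total area in mm². The
secondary-channel rule is always explicit: `mean_gt` (mean intensity in the
cluster mask > threshold) or `overlap_frac` (fraction of cluster pixels on
a binarized secondary mask ≥ threshold, suggested 0.25). The overlap rule
is an automated analogue of manual colocalization counting, not equivalent
to it.

Myotube records carry area in µm², percent coverage of the analyzed image's
own area (recorded in output, since the denominator choice matters), and a
size class split strictly at 200,000 µm² — exactly 200,000 is "small", a
documented convention for a boundary the measurement itself leaves open.
Connected components are treated as individual myotubes in automated mode
(no declumping); manually outlined masks can be substituted. Density-curve
data are exported raw with log10-transformed areas; the KDE helper requires
an explicit bandwidth and refuses degenerate (all-equal) inputs.

## Synthetic data

The generator produces the three field types the pipeline consumes, each
with exact ground truth and a single seeded RNG stream (identical spec ⇒
bit-identical images):

* **nuclei fields** — isotropic Gaussian blobs (σ = radius/2, default
  radius 6 px), centers ≥ 2 radii apart by rejection sampling (bounded
  retries, capacity error on failure); the marker channel renders blobs
  only at the `round(fraction · n)` nuclei flagged positive;
* **cell-body fields** — capsules (rectangle + semicircular caps, default
  150×8 px) at random orientations, or discs of equal area; bodies are
  placed by mask-collision sampling with ≥ 20 px separation so σ = 8
  smoothing cannot merge neighbors, and ≥ 20 px from the border;
* **coculture fields** — a myotube mask from a quantile-thresholded
  low-frequency Gaussian random field covering the requested fraction of
  the frame; non-overlapping uniform-intensity discs placed entirely on the
  mask; a rapsyn channel co-positive at a seeded fraction of clusters.

Noise is additive Gaussian with σ = peak/SNR on a constant background
offset of 3σ, clipped at zero. The offset keeps clipping below 0.14% so the
noise σ is directly measurable on blank regions (the generator's stated SNR
contract); without it, clipping at a zero background would truncate the
noise to a half-normal and bias any σ estimate by ~40%. Poisson shot noise,
PSF convolution beyond the Gaussian blobs, photobleaching, autofocus and
the z-dimension are deliberately not modelled. Consequently, passing tests
demonstrate correctness of the measurement pipeline on well-posed inputs —
separated nuclei, known SNR, planted geometry — not robustness to real
microscopy artifacts (uneven illumination, touching nuclei, debris), which
remain the user's responsibility to assess.

Default field conditions: 512×512 px at 0.5 µm/px, peak signal 1000 au at
SNR 10, 200 nuclei with 60% marker-positive, 10 cell bodies per morphology
field, 25 receptor clusters (60% rapsyn-positive) on a 40% myotube mask.
These sizes keep every validation run to seconds per field while leaving
the planted effects (bipolar vs. round morphology, positive fractions)
unambiguous.

## Reporting

Summaries are mean ± sample SD (n−1); a single replicate reports SD 0 with
an explicit degeneracy flag. Group order is lexicographic and CSV floats
are written in shortest round-trip form, so identical configurations
reproduce outputs byte-for-byte. Hypothesis testing (ANOVA, t-tests, KS,
mixed models) is intentionally delegated: tables are exported in long
(condition, replicate, metric, value, units) form for standard statistical
software.

## Known limitations

* Thresholds dominate every absolute quantity; the package ships no
  defaults for them and instead logs provenance. Published percentages
  obtained with unrecorded thresholds cannot be recomputed, only the
  direction and structure of effects can be checked.
* Border-touching wide objects inflate the elongation residual (see
  above); crop or pad real fields accordingly.
* The watershed does not declump heavily touching nuclei, and myotube
  components are not separated into individual cells.
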