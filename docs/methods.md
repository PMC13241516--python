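# Methods

## Image model

The generator renders a single 2-D equatorial plane per scene — the plane
in which these emulsion droplets are imaged in practice — so all analysis
is 2-D; there is no z-stack or point-spread-function model beyond a 1-px
Gaussian optical blur. Two channels share one geometry:

- **Reporter channel.** Background level plus a uniform fill per droplet,
  `fill = intensity_base + intensity_diameter_slope · diameter + jitter`
  (jitter ~ N(0, 500 a.u.)). The linear coupling is the simplest model
  producing the positive intensity–diameter correlation observed in real
  droplets of this kind; only the sign of the correlation is an empirical
  constraint, the linear form is a modelling choice.
- **Marker channel.** Background, a dim fill inside every droplet
  (3000 a.u.), and bright condensate masks (30 000 a.u.).

Both channels receive Poisson-scaled shot noise (`rng.poisson(s·I)/s`,
s = 0.05) and additive Gaussian read noise (sd 100 a.u.), then clip to the
16-bit range. Intensities are stored 16-bit; fixed thresholds quoted on
the conventional 8-bit display scale are rescaled by 257 = 65535/255.

### Droplets

Diameters are log-normal. The field measurement this emulates reports a
median of 25.3 µm with a wide right-skewed spread, but not the
distribution's shape; log-normal was chosen because droplet diameters are
strictly positive and right-skewed. Defaults `diam_log_mu = 3.2308`
(e^µ = 25.30 µm median) and `diam_log_sigma = 0.45`. Placement is
rejection sampling, largest first, with a 2 µm inter-droplet gap and full
containment in the field; an infeasible packing raises a "scene too
crowded" error naming the achieved count. One scene holds 25 droplets in
a 512×512 field at 0.65 µm/px (~11% area fraction), so cohort statistics
are built from many scenes rather than one crowded field.

Rejection of over-large droplets slightly truncates the upper tail in
principle; at the default field size droplets up to ~100 µm fit, so the
effect on the median is negligible (measured detected medians across seeds
fall within ±4% of 25.3 µm).

### Condensates

Each droplet independently receives condensates with probability 0.8 (a
stressed condition where most droplets respond; condensate formation under
stress is droplet-autonomous), and a selected droplet gets
`1 + Poisson(0.5)` of them. Shapes are radial-perturbation polygons,
`r(θ) = r₀(1 + Σ_{m=2..6} a_m cos(mθ + φ_m))` with `a_m ~ U(0, 0.6)/√m`,
rasterized and reduced to their largest connected component. The target
perimeter is drawn uniformly from 15–34 µm; since the perturbation
lengthens the outline by a measured factor of ~1.34 at this amplitude, r₀
is divided by 1.34 so realized Crofton perimeters track the target
interval (measured 5–95% range ≈ 15–35 µm). The amplitude was set so the
median ground-truth circularity falls in 0.4–0.8 (measured ≈ 0.59),
i.e. clearly less circular than in-cell stress granules, without
degenerating into filaments.

Placement enforces, by exact pixel checks on the rasterized mask, that
every condensate lies strictly inside its parent disc and that siblings
stay ≥ 2 px apart (so ground-truth objects remain separable). A condensate
that cannot be placed is shrunk stepwise (×0.85 every 15 attempts) and, if
still infeasible after 60 attempts, skipped with a logged warning — small
droplets (radius ≲ 8 µm) therefore sometimes end up empty, which mirrors
the physical size constraint.

Ground-truth area and perimeter are measured on the rasterized mask itself
(pixel count; 4-direction Crofton), so generator truth and pipeline
measurements share one geometry and oracle tests compare like with like.

## Segmentation

**Droplets:** Gaussian pre-filter (σ = 2 px), threshold, hole filling,
8-connected labelling, removal of components under 50 µm² and (by
default) of border-touching components, since truncated droplets bias
area fractions. The threshold defaults to Otsu — the workflow this
reimplements used a per-experiment manual threshold, which is not
reproducible; a fixed value can be supplied to recover that behaviour.

**Condensates:** median filter (disk radius 2 px) as an edge-preserving
denoiser — a stand-in chosen because the original pipeline's learned
denoiser is proprietary — then rolling-ball background subtraction and a
fixed threshold of 60 (8-bit-equivalent; rescaled ×257 for 16-bit data).
A fixed threshold keeps conditions comparable; whether the original
software applied its threshold before or after display scaling is not
recoverable, so the 8-bit-equivalent convention is declared and
configurable (`threshold_scale="raw"`). Minimum size 5 px; no hole
filling (condensates may be thin or crescent-shaped).

**Rolling ball.** Implemented as the exact grayscale opening by a flat
disk of the given radius (default 50 px — much wider than any condensate,
narrower than a large droplet), subtracted from the image. The disk is
decomposed into its horizontal segments, so erosion/dilation reduce to one
1-D sliding min/max per row offset — exact, and fast enough for 50 px
radii where a naive neighbourhood scan is not. Out-of-bounds pixels are
ignored (identity padding), matching a brute-force in-bounds scan, which
the tests verify directly against such an oracle. A constant image maps to
zero; the residual is non-negative and invariant to constant offsets.

**Assignment.** Each condensate's parent is the droplet label under its
unweighted centroid pixel; a centroid on background falls back to the
droplet with the largest pixel overlap; no overlap at all yields the
ORPHAN sentinel (−1). One parent per child, always.

## Morphometry

Area = pixel count × pixel_size²; perimeter = 4-direction Crofton
estimator (≤ 2% error on discs of radius ≥ 20 px — naive pixel-edge
counting overestimates a disc by ~27% and was ruled out because
circularity is meaningless without a convergent perimeter);
circularity = `4π·A/P²`, clipped at 1 because discretization can push
rasterized near-circles marginally above it. Objects are classed by
perimeter: focus (≤ 15 µm, pre-existing seed granules), condensate
(15–34 µm), large (> 34 µm). Foci are included in condensate statistics by
default — no exclusion rule is established for the published readouts —
and can be excluded with `exclude_foci`.

Per droplet, the condensate-area fraction is Σ child areas / droplet
area, clipped to [0, 1]; orphans are excluded from fractions and counted
separately. The replicate summary reports percent-positive (NaN, not 0,
for an empty replicate), median and mean ± SD of the fraction (in %), and
perimeter/circularity histograms over user-supplied, left-closed bins
whose outer edges are widened to conserve object counts.

## FRAP

Normalization divides the bleach-region signal by a non-bleached reference
region of the same droplet (cancelling gain and multiplicative drift) and
scales the pre-bleach mean to 100%. Recovery is a single exponential —
the minimal standard model whose half-time is the conventional summary —
fitted by least squares on post-bleach frames only, with time re-zeroed at
the first post-bleach frame. Initialization is deterministic from the
data (I₀ = first post-bleach value, P = mean of the last 10% of frames,
k = ln2 / time-to-half-range), with up to five deterministic perturbed
restarts on non-convergence; k is bounded positive and flagged when it
lands at the bound. Mobile fraction = (P − I₀)/(100 − I₀), clipped to
[0, 1]. No photobleaching-decay correction is applied beyond the
reference normalization, and no diffusion-coupled (Soumpasis) or
double-exponential models are offered. The bleach duration is an
acquisition parameter, not inferred from the trace.

Under the default acquisition emulation (0.5 s sampling over 180 s, noise
2% of plateau) the fitter recovers k and t½ with ≤ 5% median relative
error over 100 traces; on noiseless input the residual sum of squares is
≤ 10⁻¹⁰ of the total.

## Statistics

Line-profile colocalisation is the sample Pearson R of the two channel
series; a constant channel raises an error rather than returning NaN.
Set-overlap enrichment is the upper-tail hypergeometric probability
P(X ≥ k), accumulated in log space so gene-scale universes cannot
underflow (the result also carries log₁₀ p exactly; p itself is floored
at the smallest positive double). The test is one-sided (enrichment only)
because that is how set overlaps are interrogated here. The universe must
be supplied explicitly; when omitted it defaults, with a logged warning,
to the union of the two sets — a deliberately conservative choice, since a
silently large background would fabricate significance. BH adjustment is
the standard step-up (via statsmodels), tested against the hand-applied
rule.

## What the generator does and does not establish

Passing the end-to-end tests shows the pipeline recovers known geometry
and kinetics from images whose noise, blur, size distribution and
intensity structure resemble the real acquisitions. It does not establish
performance on real micrographs with out-of-focus light, touching or
coalescing droplets, uneven illumination, or condensates at threshold
intensity: touching droplets are not split (a watershed is deliberately
out of scope; the generator guarantees separation, and real touching
droplets should be flagged), and detection near the fixed threshold is
sensitive to the denoiser. Headline biological percentages from any real
experiment depend on its own optics and thresholds and are not
reproduced by simulation.

## Problem sizes and determinism

Cohort statistics use 40 condensate-free scenes (1000 droplets) for the
size readout and 9 full scenes (~225 droplets) for the area-fraction
recovery — enough for stable medians and rank correlations while a full
test run stays around a minute. All randomness derives from a single seed
per scene (`SceneConfig.rng_seed`, consumed in sampling, injection and
rendering order); fixed seeds give bit-identical images, and the run
manifest written by `run_quantify` records everything needed to reproduce
a run.
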