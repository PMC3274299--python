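# Methods

`benthoscan` implements two automated protocols for fixed-camera benthic
imagery — counting of galatheid squat lobsters (*Munida quadrispina*) and
estimation of white bacterial-mat (*Beggiatoa* spp.) coverage — plus a
synthetic scene generator that provides ground truth for validating both.
This note records the models, the parameter choices, the numerical
decisions, and what the synthetic experiments do and do not demonstrate.

## Animal-counting protocol

The front end converts a raw RGB frame into candidate objects in four
steps, all operating on 8-bit channels:

1. **Median filtering** — a 7×7 window applied three times per channel.
   Removes impulse noise (suspended particles, specular glints) and thin
   structures such as appendages while preserving body edges.
2. **White top-hat** — each channel minus its morphological opening with a
   flat disc of diameter 25 px. Structures the disc cannot fit inside
   (animal bodies) survive at their contrast over the local background;
   the smooth illumination field and broad sediment features are removed.
   The element shape is configurable (`disc`/`square`); the disc is the
   default because animals appear at arbitrary orientations. The protocol
   presumes the target is *smaller than the element*: a body wider than
   25 px is hollowed by the opening and may split.
3. **Chromatic distance** — the per-pixel distance between the R and G
   channels, |R − G|, computed in widened integer arithmetic. Squat
   lobsters are redder than the sediment, so this single chromatic axis
   carries the detection signal.
4. **Percentile segmentation and object extraction** — the distance map is
   binarized strictly above its own 95th percentile (the next-higher order
   statistic of the sorted values), labelled with 8-connectivity, and
   components outside the pixel-area gate [200, 150000] are discarded as
   contingent noise. Each surviving object carries area, centroid, outer
   contour and mean RGB over the original image.

Note a structural property of percentile segmentation: 5 % of pixels are
*always* above threshold. When animals occupy less than that, the
remainder comes from the background, and the area gate plus the classifier
— not the threshold — carry the burden of rejecting it. This is why the
classifier stage exists at all.

### Shape features

An object outline (marching-squares boundary of the padded object mask,
closed, longest loop) is resampled to 128 points equally spaced by arc
length and read as the complex sequence `z_k = col_k + i·row_k`. Its DFT
is normalized into an invariant descriptor: drop the DC term
(translation), divide by |Z₁| (scale), take magnitudes (rotation and
starting point). The 128-value vector packs harmonics +1..+64 then
−1..−64; a 128-point transform has only 127 non-DC bins, so the shared
Nyquist magnitude appears in both halves. The 60 lowest-frequency
magnitudes (±1..±30) are the named reporting descriptors. Start-point
invariance is exact for circular shifts of the 128 samples; re-deriving
the samples from a shifted raw vertex list moves them by a fractional arc
offset and is only approximately invariant. Arc-length resampling is
exactly idempotent only when the sampled polygon has equal chords (a
circle); on cornered polygons a second pass drifts by the arc-vs-chord
difference, a small fraction of the perimeter.

### Keypoint features

Scale-space keypoints are difference-of-Gaussian extrema with 128-bin
gradient-orientation descriptors (4×4 spatial grid × 8 orientations),
detected by `skimage.feature.SIFT` on the channel-mean grey conversion of
the top-hat image. The operating point is 9 octaves, 3 levels per octave,
peak-selection threshold 3 (expressed on the 0–255 intensity scale and
rescaled to the detector's normalized units), and a non-edge
principal-curvature threshold of 7. Octaves beyond what the image size
supports are skipped. Counting rule: features classified as animal are
grouped by single-linkage clustering with a 500 px linking radius; each
cluster with more than six features counts as one animal. Complete
linkage is available as a configuration alternative.

### Classifiers

**PLSDA.** Class membership ("belonging" / "not belonging") is encoded as
two complementary 1/0 dummy columns; the feature block is mean-centred and
latent vectors are extracted sequentially by NIPALS, each maximizing the
residual covariance with the dummy block; prediction is by argmax of the
predicted dummy pair. Because the two dummy columns are complementary,
the centred response block has rank one, the NIPALS inner loop converges
immediately, and at full rank the regression coefficients coincide with
the least-squares fit of the dummies (verified to 1e−8 relative).
Defaults: 10 latent vectors for the 131-column RGBv+FD table, 18 for the
128-bin keypoint descriptors. Calibration is reported as RMSEC (root mean
square of dummy residuals), RMSECV (leave-one-out below 500 rows, seeded
10-fold above — the fold scheme is a package choice), per-class
sensitivity/specificity, and percent correct.

**Euclidean-distance class model.** The belonging class is summarized by
its mean RGB vector and mean FD vector; an object belongs when *both* its
RGB distance and its FD distance to those centroids fall within
independent thresholds. The calibration rule — thresholds at the 95th
percentile of within-class training distances — is a package choice
(exposed in config), as no calibration rule is fixed by the protocol.

**Kennard–Stone split.** Calibration/test partition (70/30) by the
deterministic maximin rule: seed with the most distant pair, then
repeatedly add the row maximizing its minimum distance to the selected
set. Ties break to the lowest row index, making the split reproducible
and order-invariant up to relabelling.

## Mat-coverage protocol

Within a fixed ROI: (1) the background is modelled by convolving the frame
with a normalized Gaussian kernel; (2) the background is subtracted from
the original, negative residuals are clamped to zero (mats are brighter
than their background), and the three channel residuals are summed; (3)
the in-ROI values are contrast-clipped — below the 10 % quantile and above
the 99 % quantile values collapse to those quantiles — and affinely
rescaled to 0–255; (4) a fixed threshold of 150 (strict) binarizes the
map and 8-connected components smaller than 1000 px (the area factor) are
eliminated; (5) Percent Coverage = 100 × mat pixels / ROI pixels, and the
box-counting Fractal Dimension is the slope of ln(occupied boxes) against
ln(1/box size).

The published kernel rule sets the kernel side and sigma to "10 % of the
image"; read as a length this package uses 10 % of the shorter side
(side rounded up to odd), both overridable in config. Because the side
equals the sigma, the truncated kernel is nearly a box average: the
background model has an effective window of about a tenth of the frame,
and any structure that is *dense at that scale* is absorbed into the
background. The protocol therefore presumes mats that are locally sparse
— thin filaments — rather than solid sheets; solid high-coverage patches
are invisible to it by construction (we verified this quantitatively
during design: solid synthetic mats are recovered with errors of tens of
points at any patch scale, filamentous ones within a few points).

For the fractal dimension the mask is resized by nearest neighbour to the
next power-of-two square (preserving occupancy), box sizes descend the
quadrant ladder S, S/2, …, 2, and occupancy counts are assertion-checked
to be monotone. The alternative fixed ladder (2,3,4,6,8,12,16,32,64) used
by older manual-processing software is available for comparison runs.
Limits: a filled square measures 2.00, a one-pixel line 1.00, a level-5
Sierpinski carpet ln 8/ln 3 within the stated tolerances.

## Synthetic scenes: what they emulate

The generator models the three nuisance factors that dominate real
cabled-observatory frames — uneven illumination, variable sediment
texture, turbidity — and plants targets with exactly controllable ground
truth. Default study conditions (chosen once, on physical grounds):

| parameter | default | rationale |
|---|---|---|
| scene size | 384×384 px | enough room for several animals at realistic scale; keeps a 70-scene experiment tractable |
| base sediment RGB | (120, 110, 95) | warm grey-brown mud, small intrinsic R−G (~10) |
| illumination amplitude | 0.40 of range (animal scenes), 0.15 (mat scenes) | platform lights rake animal-survey frames; mat surveys are flash-dominated with the ROI in the evenly lit frame region |
| sediment texture | Gaussian-smoothed noise, σ=4 px, 10 grey levels | band-limited speckle |
| turbidity | additive blurred haze, common to all channels | chromatically neutral by construction, as scatter is |
| sensor noise | σ=2 per channel | 8-bit camera noise floor |
| chromatic sediment patches | 4 per frame, tint 15–35 | stained sediment/detritus; supplies the non-target candidate objects a classifier must reject |
| animal area | uniform in [400, 1100] px² | bodies whose minor axis stays below the 25 px top-hat element, the protocol's own design premise |
| animal chroma offset | 60 (R raised, G lowered symmetrically about the local background over the body; appendages darken in B only) | keeps the detection signal independent of local illumination, as real pigment contrast is |
| mat morphology | contour-band filament web (\|smoothed noise\| below a quantile), strand scale 1.5 px, density ≥ 0.40 inside a 50 px envelope | *Beggiatoa* mats are lacy filament networks; the band web stays connected (so the 1000 px area factor does not shred it) while staying locally sparse (so the background model does not absorb it) |
| mat brightness | saturated white (252) | reflective filaments under flash |

Realized mat coverage tracks the target exactly up to quantile
discretization (well within ±0.02). Planted-animal masks are pairwise
disjoint with a 10 px dilation margin.

What passing the synthetic experiments shows: the pipeline arithmetic is
correct end to end, the stated parameters interlock (median window vs
appendage width, top-hat element vs body width, area factor vs filament
connectivity), and recovery is accurate *when the scene matches the
protocol's assumptions*. What it does not show: performance on real
imagery — real sediment is not Gaussian noise, real animals are not
ellipses with strokes, real mats are not level sets of a smoothed field,
and real confounders (fish, shadows, ripples) are absent by design.

## Problem sizes

The standard experiments train the RGBv+FD PLSDA on objects from 50
scenes and evaluate counting on 20 held-out scenes of 3 animals each;
detection localization is scored over the 50 training scenes; mat
recovery over targets 10–70 % × 20 seeds. These sizes give roughly ±8
points of binomial uncertainty on the held-out exact-count rate.

## Known limitations

- The percentile threshold guarantees 5 % of pixels segment regardless of
  content; an animal-free frame still yields candidate objects and the
  counting result then rests entirely on the classifier.
- Bodies wider than the top-hat element fragment; closely spaced animals
  can merge. Both inflate or deflate counts by one in a few percent of
  scenes under default conditions.
- The mat protocol under-measures solid (non-filamentous) mats severely;
  this is a property of the published design, not of the implementation.
- The ED class model's calibration rule and the PLSDA cross-validation
  fold scheme are package choices where the protocol is silent.
- Inter-frame correspondence ("tracking" across the hourly series) is out
  of scope; feature grouping is within-image only.
- The keypoint (SIFT) counting branch is implemented and verified at the
  component level, but its end-to-end accuracy cannot be demonstrated on
  the synthetic scenes: generated animals are smooth ellipses without the
  carapace texture that makes real animal keypoints distinctive, so their
  gradient descriptors do not separate from sediment keypoints. End-to-end
  validation of that branch requires imagery with textured targets; the
  RGBv+FD branch is the one validated end to end here.
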