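# Methods

## Scope and model

`actinet` extracts the filamentous-actin network from single-channel
fluorescence micrographs (2D images or confocal z-stacks) and reduces it
to seventeen quantitative measures of network architecture.  The method
is purely image-based: no model of actin dynamics is fitted.  Its core
assumptions are

* filaments appear as bright, curvilinear, roughly tubular structures on
  a darker background;
* a single-pixel-wide centreline ("skeleton") is an adequate summary of
  the network in a 2D projection;
* for z-stacks, the network topology is resolvable in the 2D
  maximum-intensity projection, and the stack is only informative about
  the *z position* of structures (confocal z-resolution is far coarser
  than the lateral pixel size), estimated per pixel from the brightest
  plane.

## Extraction pipeline

1. **Top-hat background subtraction.** The grayscale opening with a
   spherical (non-flat ball) structuring element of radius 15 px is
   subtracted from the image.  The radius should be 2–3 times the width
   of the thickest filament; features narrower than the element survive,
   smooth background and uneven illumination do not.  A flat disc is
   available as a configuration fallback (`tophat_flat`), which makes the
   operation intensity-scale invariant (the ball's height is expressed in
   intensity units and therefore interacts with the image's dynamic
   range).
2. **Tubular enhancement.** A multi-scale Hessian vesselness filter
   (Frangi formulation for bright ridges, default sensitivity constants,
   `gamma` set per scale to half the maximal Hessian norm) is applied at
   filament thicknesses 4–14 px in steps of 2.  Each thickness t is
   probed with Gaussian-derivative scale σ = t/6, so the ±3σ support of
   the smoothing kernel spans the probed thickness.  The response is the
   maximum over scales.  Responses below 1e−6 of the per-image peak are
   zeroed: the filter's far-field eigenvalue response never underflows to
   exactly zero in float arithmetic, but any realistic acquisition bit
   depth quantises such values away, and a percentile threshold on a
   sparse image would otherwise latch onto numerical dust.
3. **Percentile threshold.** Pixels strictly above the 90th percentile of
   the *in-ROI* response distribution are kept.  Restricting the
   percentile to the ROI makes the parameter transferable across crop
   sizes; this is the single most sensitive parameter of the pipeline
   (useful range roughly 87–92).
4. **Small-object removal.** 8-connected components of fewer than 20
   pixels are deleted (the 20-px component itself is kept).  The critical
   value depends on imaging conditions and should be re-examined per
   dataset.
5. **Skeletonisation.** Topology-preserving thinning to a one-pixel-wide
   skeleton: perimeter pixels are removed until further removal would
   change the number of components or holes (Euler number).
6. **Rotation normalisation.** The frame is rotated so the ROI's
   second-moment major axis (fitted-ellipse orientation) is horizontal.
   Because rotating a discrete skeleton degrades it and rotating before
   thresholding loses other information, both orders are run: path A
   thins first and rotates the skeleton with nearest-neighbour
   interpolation; path B rotates the filtered intensity image bilinearly
   and thins in the rotated frame.  The pixel-wise OR of both results is
   re-thinned.  An isotropic ROI (equal principal moments) leaves the
   frame unrotated with a warning.

Everything uses 8-connectivity (components, thinning, neighbour counts,
path tracing); 4-connectivity would sever diagonal steps of a 1-px line.
Extraction is fully deterministic.

## Filament labelling

Junction pixels (skeleton pixels with ≥3 skeleton neighbours; adjacent
qualifying pixels merged into one junction, represented by the member
nearest the cluster centroid) are temporarily removed.  The remaining
fragments are flood-fill labelled, then re-joined at each junction by
greedy pairing: the pair of incident fragments whose outgoing directions
are most nearly opposite is merged first, then the next straightest pair
among the remaining arms, while at least two unpaired arms remain.
Leftover arms are branches.  A plain crossing therefore reconnects into
two through-filaments; a T-junction into a main filament plus a branch.
Local direction at a junction is the unit vector from the
junction-adjacent fragment end to the pixel five path-steps along —
matching the ~5-px curvature sampling scale.  Ties between equally
straight pairs go to the larger combined length (deterministic).
Poorly-resolved crossings that thinning renders as 'h' or 'x-wing'
shapes are accepted behaviour, not corrected.

Merged filament paths pass through the junction representative pixel, so
each filament is traversable endpoint-to-endpoint; in the label image
the junction pixels remain background and are recorded separately, so
skeleton pixels partition exactly into filament pixels plus junction
pixels.  Cyclic filaments are broken at an arbitrary pixel with a
warning.

## The seventeen measures

Per cell: ROI size (px); cell orientation (rad); skeleton density
(skeleton px / ROI px, with a per-volume variant dividing additionally
by stack depth × z-spacing); structure sizes (8-connected component
pixel counts); branch ratio (junctions / filaments); branch-point
density (junctions / ROI px, alternative normalisation by the summed
length of branched filaments available but off by default); average
filament length (mean of 3D lengths).

Per filament: width (mean perpendicular run length through the
pre-thinning binary, tangent estimated from ±2 path steps, rays capped
at 30 px so neighbouring structures cannot inflate the local width);
2D length ((N + (√2−1)·D) × pixel size for N path pixels and D diagonal
steps, so a diagonal step costs √2 in total); 3D length (2D length /
cos θ_z); 2D angle (endpoint displacement versus the horizontal,
(−π/2, π/2], y-up sign convention, vertical = +π/2); z angle (endpoint z
displacement from the brightest-plane estimate versus in-plane endpoint
separation, capped at 85° before the cosine division because the coarse
z estimate makes near-vertical angles explosive; capped filaments are
flagged); deviation (mean perpendicular distance of path pixels to the
endpoint chord, in nm); mean intensity (computed, excluded from the
seventeen).

Curvature: for each interior path pixel, flanking points are chosen as
close to λ = 475 nm away *along the path* as possible (endpoints used
when nearer), and the Menger curvature (inverse circumradius, signed by
turn orientation) of the triple is evaluated in physical units.  The
signed filament curvature is |mean κ| — opposite bends cancel — and the
unsigned curvature is mean |κ|.  λ = 475 nm (five pixels at 95 nm/px) is
large enough that single-pixel jitter does not dominate and small enough
to stay local.  For gently curved filaments (radius ≫ λ) the unsigned
mean still carries a jitter floor; the signed mean does not (jitter
cancels), which is why the two are reported separately.  Paths shorter
than three pixels have undefined curvature and are omitted.

Branch angles measure the deviation a myosin motor travelling along the
main filament would turn through to take the branch: the angle between
the branch's outgoing direction at the junction and the *nearer* of the
main filament's two outgoing directions.  The 3D variant lifts the
junction and the ±5-step window points to 3D with the brightest-plane z
estimate and evaluates the angle from pairwise distances (law of
cosines) in the plane spanned by the two centre-lines; a flat network
reproduces the 2D values exactly.  Junctions whose arms were fully
consumed by pairing (plain crossings) have no branches and contribute no
angle.

## Synthetic ground-truth generator

Scenes emulate the acquisition: each filament is a quadratic spline
through two uniform random endpoints (re-sampled until ≥25 % of the
field apart) and their midpoint displaced perpendicular to the chord by
a uniform offset of up to 25 % of the chord length.  Filaments are
rasterised at their physical thickness (5 nm F-actin default; 15/25 nm
for intermediate-filament/microtubule calibres) on a 19× supersampled
grid (5 nm effective pixels at the default 95 nm/px, 200×200 px field),
blurred with a Gaussian PSF (σ = 0.21 λ_em/NA ≈ 79.2 nm for NA 1.35 and
509 nm emission), and block-averaged (exact 19×19 means) back to the
acquisition grid.  Brightness is emission per unit length applied
*before* the blur (rasterised pixel values scaled by supersample/width),
so a wider PSF dilutes the realised intensity exactly as a lower-NA lens
would, and all thicknesses emit identically.  The blur and block-mean
are separable, so the per-axis passes are interleaved — bitwise the same
result as blurring the full fine grid, at a fraction of the cost.

Noise is salt-and-pepper: a 5 % fraction of acquisition-grid pixels
receives an impulse with amplitude uniform in (0, noise_max], and the
impulse field is blurred with the same PSF before being added.  The
realised SNR of each scene is recorded as (mean intensity on
ground-truth pixels − mean background)/SD(background), where background
excludes a 1-px dilation of the truth so PSF-spread signal does not
leak into the noise statistics.  Because the amplitude–SNR map is
non-linear, a calibration helper finds the noise_max for a requested
mean SNR by Monte-Carlo bisection; for a fixed seed the impulse pattern
is independent of the amplitude and the noise scales linearly with it,
so each scene is rendered once and candidate amplitudes are evaluated
with vector arithmetic.

Ground truth is the set of acquisition-grid pixels containing at least
one centreline point.  Scenes are pure functions of (parameters, seed);
datasets derive per-scene seeds from a master seed and write a manifest.

What the generator does *not* emulate: photon (Poisson) statistics and
camera gain, out-of-focus light and 3D scene geometry, spatially
correlated background (organelles, autofluorescence), photobleaching,
and filament bundling (all filaments are single and equally bright).
Passing validation on these scenes therefore demonstrates robustness to
impulse-type noise, density, threshold and optical resolution — not
performance on every real-data artefact.

## Validation metrics

A predicted skeleton pixel is a true positive when a ground-truth pixel
lies within Chebyshev distance 1 (the 8-neighbourhood; Euclidean ≤ √2
coincides on the integer grid), otherwise a false positive; truth pixels
with no prediction within tolerance are false negatives.  Matching is
set-based, not one-to-one.  Sensitivity = TP/(TP+FN), precision =
TP/(TP+FP); empty truth or empty prediction leave the respective metric
undefined (NaN with a warning).  Sweeps report per-image rows plus
per-condition mean, SD and quartiles; failed images are recorded with
NaN metrics rather than dropped.

## Problem sizes

The validation protocol is 100 images per condition.  The test suite
runs the same experiments at 10–25 images per condition (50 for the
thickness comparison, which feeds a rank test), which stabilises the
condition means to within a couple of percentage points;
`scripts/acceptance.py` runs the SNR experiment at the full 100 images
per condition.  Noise calibration uses 8 scenes per candidate amplitude
with a ≤0.1 % relative bisection tolerance.

## Numerical choices and degenerate inputs

* Strictly-greater comparison at the threshold; a constant in-ROI
  distribution yields an empty binary with a warning.
* Percentile over in-ROI pixels only.
* Orientation ties (isotropic ROI) resolve to 0 with a warning.
* z ties resolve to the lowest plane index.
* Empty skeletons, empty networks and junctions with fewer than two
  incident fragments are warnings, not errors; downstream measures
  return zeros/empty lists.
* Intensity-image rotation is bilinear, binary rotation is
  nearest-neighbour; the OR of the two skeleton paths is re-thinned.

## Known limitations

* True 3D over/under-crossings are not resolved; z is estimated only at
  skeleton pixels from the brightest plane.
* No gap closing across broken filaments; adaptive/local thresholds are
  deliberately excluded (tested and rejected during the original
  algorithm's development; Otsu-style selection left to future work).
* The unsigned curvature of nearly straight filaments is dominated by
  discretisation jitter (see above) and should be compared between
  conditions, not read as an absolute curvature.
* The synthetic noise parameterisation (impulse density, grid placement,
  SNR definition) is a modelling choice; realised SNR values are
  recorded per scene precisely so that alternative definitions can be
  swapped in and compared.
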