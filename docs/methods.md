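# Methods

This note documents the models, conventions, numerical choices and known
limitations of `fiberorient`.  It is written for users deciding whether the
pipeline's assumptions fit their data and for maintainers changing defaults.

## Coordinate and angle conventions

All images are 2D arrays indexed `[row, col]`; coordinates are 0-based pixel
centers with x along columns and y along rows (y increases downward).  Every
axis angle in the package — fiber axes, spheroid major axes, radial
directions — is expressed in degrees in [0, 180), measured from +x toward
+y.  Axes are undirected, so all angle comparisons are taken modulo 180°
and reduced to the acute difference in [0, 90°].  Region axes come from the
central second moments of the pixel set (equivalent-ellipse semantics
identical to `skimage.measure.regionprops`, with axis lengths
4·√eigenvalue); a fast `bincount`-based implementation computes them for
tens of thousands of components at once and is unit-tested against
`regionprops`.

## Fiber extraction

The chain is: (1) subtract a disk-mean filtered copy (radius 10 px) from
the reflection image; (2) square the residual and flag pixels whose squared
intensity exceeds the local mean by more than 0.5 local standard deviations,
where "local" is a circular neighborhood of radius 5 px (population-
normalized SD; a square window is available via
`ExtractionParams.neighborhood`); (3) remove pixels with no 8-connected
neighbor, then close with a 3×3 square; (4) keep 8-connected components
with more than 20 pixels and eccentricity ≥ 0.9.

Numerical choices worth knowing:

* **Border policy** is reflective padding for all local filters, to avoid
  spurious edge fibers on stitched images.
* **Negative clipping** (`clip_negative`, default on): reflection intensity
  is non-negative and integer-image subtraction saturates at zero, so the
  negative halo that disk-mean subtraction leaves around bright structures
  is clipped before squaring.  Without it the halo is squared into
  arc-shaped false "fibers" around every real one.
* **Amplitude floor**: pixels below 10⁻⁸ of the dynamic range are treated
  as exact background.  An adaptive threshold otherwise chases FFT round-off
  in genuinely empty regions and floods the mask.
* Convolutions run through FFT (`scipy.signal.fftconvolve`); float32 input
  stays float32, which halves the cost on stitched wells.  Equality with
  brute-force per-pixel implementations is asserted in the test suite.

On noiseless rendered single fibers the recovered axis angle is accurate to
≈0.2° across 0–170°.  On images with additive i.i.d. Gaussian noise the
local threshold flags ≈19 % of pure-noise pixels; the cleanup and the
size/eccentricity gates remove most but not all resulting clusters, so pure
noise yields a nonzero false-fiber rate.  Real reflection backgrounds are
spatially structured rather than i.i.d., and the original workflow was
operated on such data; treat absolute fiber counts in very dim regions with
caution.

## Radial orientation model

Per fiber, the orientation parameter is cos²θ with θ the acute angle
between the fiber axis and the radial vector from the tumor-spheroid center
to the fiber centroid.  It is invariant to 180° axis flips and to rotation
of the scene about the tumor center; its expectation under uniformly random
orientation is exactly 0.5.

Distances are measured from the spheroid *edge*: Euclidean centroid
distance minus the spheroid radius (from DIC morphometry, or overridden
manually).  Fibers inside the spheroid (negative distance) are excluded.
Bins are half-open [lo, hi), width 67 µm by default (100 px at 0.67 µm/px),
anchored at the edge.

`RadialOrientationModel.fit()` performs bounded least squares
(`scipy.optimize.curve_fit`, trust-region reflective) of
`y = 0.5 + (Y0 − 0.5)·exp(−x/L0)` to the bin means whose centers exceed the
fit window (default 100 µm).  Bounds: Y0 ∈ [0, 1], L0 ∈ (0, 10·max
distance].  The fit is multi-start (three deterministic initializations of
L0 at span/6, span/2 and span; Y0 from the mean of the first three usable
bins) and keeps the lowest residual: with a single start, one noisy
near-edge bin can park the solver in a degenerate steep-decay basin.  Bins
are unweighted by default; 1/SE weighting is available (`weighted=True`)
but deliberately not the default — on short decay lengths it underweights
exactly the few informative near-edge bins.  Fewer than three usable bins
or non-convergence returns an explicit `FitFailure` value rather than
raising.

Uncertainties are 95 % confidence half-widths from the fit covariance with
a Student-t quantile (dof = bins − 2).  The confidence band of the curve
uses the delta method; `integrated_orientation = (Y0 − 0.5)·L0` carries a
delta-method SE as well.  The *orientation extent* is the largest distance,
capped at the far edge of the last populated bin (no extrapolation), at
which the band's lower bound exceeds 0.5; the crossing is located on a
4096-point grid and refined by bisection.  On a flat (random) profile the
fitted amplitude is statistically zero, L0 is unidentifiable (it will often
sit at a bound), and the integrated orientation should be interpreted only
together with its SE.

Group statistics follow the field's convention for these data: two-sided
Mann-Whitney U for comparing orientation distributions, unpaired two-sided
t-test (pooled variance) for comparing integrated orientations;
"oriented collagen" is classified as exceeding the reference mean + 1 SD
(sample SD, ddof = 1).

## Spheroid morphometry and nuclei counting

DIC images are divided by a large-radius median-filtered copy (default
radius 50 px) to remove illumination; the median uses an 8-bit quantized
sliding-histogram rank filter, since the background field needs no more
depth and brute-force medians are prohibitive at this kernel size.  The
core is the connected component nearest the image center after blurring
(σ = 4 px) and thresholding at mean − 2 SD.  The migration zone is captured
by Canny edges (σ = 2 px) dilated by 15 px, united with the core,
hole-filled, then eroded by the same 15 px: the dilation bridges the sparse
texture of migrating cells and the matched erosion returns the boundary to
the outermost detected cells, so the measured radius is not inflated by the
structuring element (a rim-less spheroid segments to its core).  "Radius"
is the equivalent-circle radius `pixel_size·√(area/π)` of the combined
mask.  Blur σ, median radius, Canny σ and dilation radius are configurable
and echoed into the output metadata.

Nuclei: z-planes are sum-projected, blurred (σ = 2 px), thresholded at
mean + 2 SD, components below 9 px discarded, and touching objects split by
a watershed on the distance transform seeded at local maxima ≥ 5 px apart.
On synthetic blobs of σ = 3 px the count is exact for center separations
≥ 4σ and still splits a 3σ pair.  The mean + 2 SD threshold presumes signal
is present; a signal-free but noisy acquisition will produce spurious
foreground, so the blank fixture is noiseless by construction.

## Endothelial scoring

Direction = (90° − α)/90° with α the acute angle between the mask's major
axis and the vector from the mask centroid to the tumor center; elongation
= major/minor axis ratio; orientation = direction × elongation.  Direction
is reported for all masks but flagged `low_confidence` when elongation
< 1.05, where the major axis is numerically ill-defined.  The association
between collagen orientation at the injection site and these scores is
summarized by the Pearson product-moment coefficient with a linear fit.

## Synthetic scenes: what they emulate and what they do not

The generative law for fiber orientation is a mixture: a fiber at edge
distance d is exactly radial (plus optional Gaussian wobble) with
probability `w0·exp(−d/λ)`, else uniform on [0, 180).  Its expectation is
exactly the analysis' fitted form with Y0 = 0.5 + 0.5·w0 and L0 = λ, which
is what makes closed-form recovery checks possible.  Centroids are uniform
over the image excluding the tumor disk; lengths are Gaussian (clipped);
each scene uses a single seeded `default_rng` stream, so identical seeds
give bit-identical fibers and images.

Fibers render as constant-intensity rectangles of width 2 px (~1.3 µm at
the default 0.67 µm/px — the scale at which collagen fiber bundles image in
reflection confocal), optionally blurred and with additive Gaussian noise.
Hairline anti-aliased rendering was rejected: its intensity varies along
oblique lines, which fragments the squared-intensity threshold and corrupts
moment-based angles.

Dense scenes can be rendered as a shallow z-series
(`render_reflection_stack`): each fiber is assigned to one of n planes and
extraction runs per plane, pooling the detections.  This mirrors how a
confocal acquisition sections a 3D gel — tens of thousands of fibers
projected into a single 2D plane would overlap into unresolvable clumps
that no real acquisition produces, and at such densities merged components
systematically shrink the measured cos² amplitude.

The phantoms emulate geometry and first-order contrast, not microscopy
physics: no PSF anisotropy, no depth attenuation, no speckle statistics, no
fiber curvature (the detector's eccentricity gate assumes near-straight
segments), and no mechanical coupling between fibers.  Passing tests
demonstrate that the *analysis chain* is correct and recovers known ground
truth; they do not certify detector performance on real reflection
backgrounds.  Fiber density and length for 1 mg/mL rat-tail collagen are
plausible placeholders (defaults: 30 ± 8 px length), not calibrated values.

## Verification problem sizes

The parameter-recovery check runs the full render → extract → bin → fit
chain over w0 ∈ {0.2, 0.5, 0.8} × λ ∈ {200, 500, 1000} µm with 2×10⁴
fibers per scene and 5 seeds per cell, comparing the median recovered
(Y0, L0) to truth within 10 %.  Scene geometry is matched to the
estimand: fields of 2.8–5.6 mm at 2 µm/px, 6–10 z-slices, and a spheroid
radius of 700 µm for λ = 200 (short decays concentrate their information in
the first few bins, so the near-edge annuli must hold enough fibers) versus
500 µm otherwise (long decays instead need ≥3λ of radial range).  Scenes
are noiseless: the check targets geometric recovery, not denoising.  The
spheroid radii are at the 48-hour scale because profiles are measured from
the final spheroid edge; very small spheroids additionally crowd converging
radial fibers into arc-like merges at the rim.

## Known limitations

* The exact confidence procedure of the original GraphPad-based fit is not
  public; the delta-method band (with a bootstrap-free t quantile) is this
  package's choice, so extent values are comparable within the package, not
  necessarily to other implementations.
* `segment_core` assumes the spheroid is the darkest central object;
  strongly vignetted or off-center acquisitions need the manual center
  override.
* The fiber detector reports merged crossing fibers as single components or
  drops them via the eccentricity gate; at high areal density this biases
  orientation amplitudes toward 0.5.  Keep per-plane fiber coverage low
  (sparse gels or z-resolved acquisition) when absolute Y0 matters.
* 3D fiber reconstruction, gel mechanics, and soluble-factor modelling are
  out of scope.
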