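# Methods

## Model and procedure

A particle ("blob") in a height image is defined through two properties of
the discrete scale-space representation `L(x, y; t)`:

1. its center and size are the location and scale of a strict local
   maximum of the scale-normalized Hessian determinant
   `det H_norm L = t²(Lxx Lyy − Lxy²)` over the three-dimensional
   (x, y, t) domain, and
2. its spatial support at that scale is the connected set of pixels where
   `det H_norm L` stays positive, i.e. where the smoothed surface is
   locally convex (the Gaussian curvature `K = det H L/(1+Lx²+Ly²)²` has
   the same sign as `det H L`, so convexity can be read from the detector
   directly).

Because both ingredients are built from second derivatives, the detected
particles are exactly invariant under constant and planar additions to the
image and nearly invariant under smooth large-scale backgrounds — the
usual flattening/background-subtraction preprocessing of AFM images is
unnecessary. The normalized Laplacian `t(Lxx+Lyy)` is used only to read
off a blob's sign (negative at bright-blob centers).

The pipeline is: scale space → detector volumes → strict 3×3×3 maxima →
sign classification → candidate minimum-scale cull → support regions →
overlap resolution → Taylor center refinement → strength/scale culling →
boundary tracing → measurement. It is deterministic for a given image and
configuration.

## Closed-form oracles

For a planted Gaussian bump `A·exp(−r²/(2t₀))` (the canonical blob model),
smoothing at scale `t` yields a bump of scale `t₀+t` with center amplitude
`A·t₀/(t₀+t)`; the center detector response is

    det H_norm L(0; t) = A² t₀² t² / (t₀ + t)⁴,

maximal exactly at `t = t₀` with peak value `A²/16`, and the positive-
curvature support at the selected scale is the disk `r < √(2t₀)`. These
closed forms anchor the test suite: scale selection, region radius,
contour perimeter (`2π√(2t₀)`) and the measured relative height
(`A(1−1/e)`, since the boundary sits where the bump height is `A/e`) are
all checked against them end to end.

## Numerical choices

* **Kernel.** Smoothing uses the discrete Gaussian analog
  `T(n; t) = e⁻ᵗ Iₙ(t)` (modified Bessel weights), which satisfies the
  semigroup property exactly on the integer grid; a sampled-and-
  renormalized continuous Gaussian is available as an option. Kernels are
  truncated once the discarded tail mass falls below `tol` (default
  1e-10, making two-stage vs one-stage smoothing agree to ~1e-10) and
  renormalized to unit sum. Borders are mirror-padded, which preserves
  constants and the image sum.
* **Scale grid.** `t` is sampled as `t_min·2^(k/layers_per_octave)` with
  defaults `t_min = 0.5 px²`, `t_max = (min(rows, cols)/8)² px²`, 4 layers
  per octave. The ratio is held exactly constant; the grid stops at the
  last sample ≤ `t_max`. Scales are kept in pixel² internally and
  reported in physical units (`t·pixel_size²`) alongside.
* **Derivatives.** Plain 3-point central differences on the smoothed
  layers (one-sided at borders), in pixel units. Blob strengths therefore
  carry the squared height unit (nm² for nm heights); with heights in
  meters they would be ~1e-19, the order of magnitude practitioners
  usually quote. Absolute strengths depend on this unit convention and
  are not comparable across conventions.
* **Untrusted border band.** Derivative values within `ceil(3√t)` px of
  the image edge are influenced by padding and one-sided stencils; seeds
  there are discarded and contours of regions reaching into the band are
  flagged.
* **Maxima.** Strict inequality against all available neighbors of the
  3×3×3 stencil; exact plateaus yield no seed (ties are measure-zero on
  real data and would otherwise duplicate particles).
* **Refinement.** The SIFT-style quadratic step `offset = −H⁻¹∇` of the
  detector, re-seated to the adjacent voxel while any component exceeds
  0.5, at most 5 iterations; the scale offset is applied geometrically
  (`t̂ = t_k·ratio^δ`) because the grid is geometric. Singular local
  models or border seeds fall back to the seed coordinates, flagged
  unconverged.
* **Boundaries.** `subpixel_factor = 1` returns the exact pixel-boundary
  (staircase) polygon of the support footprint, whose shoelace area
  equals the pixel-count area identically. Factors ≥ 2 trace the zero
  level set of the detector, marching-squares style, on a grid refined by
  that factor under bilinear or bicubic interpolation. Bicubic tracing is
  markedly more accurate on smooth boundaries (0.07 % vs ~1–3 % perimeter
  error on planted bumps at factor 20) because bilinear interpolation
  biases zero crossings between grid points; vertex spacing is bounded by
  the fine-grid cell diagonal `√2/factor`. Holes (negative islands) are
  kept as interior contours and subtracted from the area.
* **Overlap resolution.** Greedy by descending strength with
  deterministic tie-breaks (ascending scale, row, column indices);
  acceptance requires pixel-disjoint support in the image plane. Overlap
  is decided on pixel-resolution regions, not subpixel contours, which
  are a reporting refinement.
* **Minimum scale as a candidate filter.** The minimum-scale cull is
  applied to candidate seeds *before* overlap resolution. Its purpose is
  to remove few-pixel noise blobs, and a noise spike must not be allowed
  to displace a real particle in the strength contest before being culled
  itself. The post-hoc `filter_min_scale`/`filter_min_strength`
  operations never recompute anything: a blob surviving any cull is
  bit-identical to its unculled self.
* **Automatic strength threshold.** Otsu's method on a 256-bin histogram
  of log10 strengths (strengths span decades; a linear histogram
  collapses), returning the inter-class-variance-optimal bin edge mapped
  back to linear scale. An exact 1D two-cluster split scan (k-means,
  k = 2, solved globally on the sorted values) is the alternative. The
  pipeline applies no automatic cull when all strengths lie within one
  decade: distinct significance classes differ by orders of magnitude,
  and a homogeneous population (e.g. a clean calibration image where
  every detection is a real particle) must not be split.

## The synthetic generator

The generator emulates what the detector needs from AFM data and no more:
isolated Gaussian protrusions of known subpixel center, amplitude and
scale on a flat background; hexagonal lattices of three-bump clusters
with the dimensions of the bacteriorhodopsin purple membrane (6.25 nm
lattice constant, monomer width σ = 0.5 nm, intra-trimer separation
1.6 nm at 0.25 nm/px), which merge into single coarse-scale units while
staying individually resolvable at fine scales; and the standard
perturbation battery — constant offset, fault-line step, corner-to-corner
tilt, per-scanline parabolic bow, per-scanline random offsets, per-pixel
Gaussian noise — at the magnitudes customary for robustness studies
(2 nm for the deterministic defects, σ = 1 nm for the stochastic ones).

It does **not** model tip convolution, structured membrane backgrounds,
height-dependent noise, or drift. Passing tests on these fixtures
demonstrate the algorithm's geometric and numerical correctness and its
artifact invariances; they do not certify accuracy on real data, where
tip geometry and background structure dominate the error budget.

Problem sizes used by the test suite and the acceptance script — 256×256
images with 4–20 planted bumps, 192×192 trimer lattices (56 trimers), 100
random volumes/samples for the brute-force cross-checks — are large
enough that every planted structure sits well inside the trusted region
at its own scale.

## Known limitations

* Scanline noise at σ = 1 nm on 3 nm particles destroys or displaces a
  few percent of detector maxima (row offsets locally cancel the bump's
  cross-scan curvature) and occasionally grows a sprawling noise region
  that wins an overlap contest against a genuine particle. Across random
  layouts the per-image recall under the battery protocol (minimum
  candidate scale 4 px², strength threshold 0) averages ~89 %
  (range 75–95 %) for scanline noise and ~98 % for per-pixel Gaussian
  noise of the same σ.
* The relative height and provisional volume are referenced to the mean
  raw height along the particle's own boundary. This is an explicit
  stand-in for a proper local background estimate under the particle: for
  a Gaussian bump it reports `A(1−1/e)` rather than the full amplitude,
  and on sloped or structured backgrounds the baseline inherits that
  structure. Outputs carry the `provisional` label for this reason.
* Nested and overlapping blobs are reported only through the strength
  contest (the stronger of two overlapping blobs survives); substructure
  analysis beyond the scale-space signature diagnostic is out of scope.
* Anisotropic pixel grids are rejected (>1 % difference between the two
  pixel sizes) rather than supported.
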