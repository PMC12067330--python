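# Methods

`gridcal` calibrates the distortion of a lens-coupled camera from a single
image of a grid target and corrects images and tomographic sinogram stacks
with it.  This note records the models, the algorithmic choices, the
defaults, and the limits of what the synthetic test bench demonstrates.

## Distortion model

Two independent components are calibrated:

**Radial distortion** is modeled by a polynomial in the radius from the
distortion center (x_c, y_c):

    backward:  r_d = r_u (k_0 + k_1 r_u + k_2 r_u^2 + ... + k_n r_u^n)
    forward:   r_u = r_d (k'_0 + k'_1 r_d + ... + k'_n r_d^n)

with (x_d, y_d) = center + (x_u − x_c, y_u − y_c)·r_d/r_u.  "Backward" maps
undistorted → distorted coordinates and is the direction used to resample
images (the four neighbours of a mapped position are known pixels);
"forward" is its inverse and is applied to reference points.  Odd and even
powers are both present — restricting to even terms (as some computer-vision
parameterizations do) costs accuracy.  Conversion between the directions
samples one model on a radius grid and fits the other by least squares.

**Perspective distortion** (target / lens / sensor planes not parallel) is
an eight-coefficient projective map

    x' = (c1 x + c2 y + c3)/(c7 x + c8 y + 1),   y' = (c4 x + c5 y + c6)/(…).

The composition convention is `distorted = P(R(undistorted))`: the radial
map acts first (about its center), the homography last.  Calibration undoes
them in reverse order — perspective first, then radial — so the radial fit
always sees a perspective-free grid.

Coordinates are (x = column, y = row) with the origin at the top-left pixel
center, everywhere.

## Calibration workflow

1. **Point extraction.**  Dot patterns: the background is flattened by
   dividing by a smoothed background estimate (Gaussian low-pass, re-run
   once with the detected foreground masked out via normalized convolution —
   without the masking the background dips around every dot and biases the
   centroids by ~0.05 px); Otsu or rank-threshold binarization; per-component
   center of mass, intensity-weighted by default (~2× more precise than the
   binary centroid on rendered targets; binary available via
   `centroid_method="binary"`).  Components touching the image border are
   discarded (clipped dots have biased centroids).  Defect filters: size
   vs. median, best-fit-ellipse axis ratio, and a 4-nearest-neighbour
   spacing test for misplaced dots (only valid for weak distortion — under
   strong distortion use the post-grouping residual filter instead).
   Line patterns: intensity profiles cast perpendicular to the nominal line
   direction; every local extremum is validated by a Gaussian-plus-offset
   fit (acceptance: relative RMS residual below `quality_threshold`, sane
   width, amplitude above 30% of the global contrast — the amplitude floor
   rejects the shallow ghost extrema a profile picks up where it runs along
   a perpendicular line).  Chessboards: square boundaries are step edges of
   the intensity profile; a sliding linear fit turns each edge into a peak
   of the slope signal, localized by the same Gaussian criterion.  A
   gradient-magnitude conversion to a line image is also provided, but the
   corner response of the gradient image makes profile casting unreliable,
   so the edge route is the default.

2. **Grouping into lines.**  Each grid line is represented by a parabola
   (horizontal: y = a x² + b x + c over x; vertical with x and y swapped).
   The slope-guided method chains points in order of the independent
   coordinate; each chain keeps a running local slope (initialized from the
   estimated grid rotation) and claims the point whose predicted ordinate is
   within `tolerance_ratio · nominal_distance`; chains never span gaps
   beyond `max_missing + 1` spacings.  The per-chain adaptive slope is what
   lets the method survive the line-to-line slope variation perspective
   introduces — a single global projection provably mixes neighbouring
   lines once the slope spread times the image width exceeds half a
   spacing.  For strongly curved (fisheye) grids the middle-out method
   groups a central slab first (where distortion is minimal), fits each
   group, and advances outward slab by slab, claiming points within
   `residual_tolerance` of each group's running fit (a straight line below
   five points, a parabola after); ties go to the smallest residual.  The
   seed slab is widened automatically until the line count stabilizes.
   After grouping, points farther than `residual_threshold` (2 px) from
   their parabola are dropped and the parabola refit once — this is the
   distortion-strength-agnostic defect filter.

3. **Distortion center.**  With the origin anywhere, the curvature
   coefficient a changes sign at the center.  The coarse estimate
   interpolates b and c of the sign-straddling parabola pair to the a = 0
   crossing for each orientation and intersects the two resulting axis
   lines.  (Plain averaging of the pair — the textbook description — is
   biased by up to half a spacing whenever the center is not midway
   between lines.)  Two vanishing-point estimators cover centers outside
   the grid: all intersections of opposite-curvature parabola pairs
   (barrel), or of the flattest parabola with all others (general; for
   non-crossing pincushion pairs the closest-approach abscissa — the real
   part of the complex root pair — is used).  Both are exact on radially
   symmetric grids but carry an O(g·x*²) projective bias under tilt and a
   vertex bias that grows with the center offset, so the pipeline uses
   them only as fallbacks when the coarse method finds no sign change.

4. **Perspective correction.**  An initial homography is built from four
   point correspondences: the pairwise intersections of the averaged
   positive-a and negative-a lines of each orientation (distorted quad)
   against their regularized counterparts (common rotation, exact
   perpendicularity, intercepts rescaled to the mean spacing or a
   user-supplied px-per-line scale).  Center estimation and correction are
   iterated two or three times.  Because the averaged lines come from
   curved parabolas, this estimate retains a small projective bias; it is
   then refined in two stages that exploit the radial model itself:
   - *Line-flattening iteration*: fit the radial polynomial, radially
     unwarp the grouped points (lines become straight up to the residual
     perspective), and solve — one linear equation per point — the
     incremental homography that flattens every point onto its ideal
     equidistant lattice line.  Not monotone (the center re-estimate is
     noisy), so the best state by its own straightness objective is kept.
   - *Levenberg–Marquardt polish*: the incremental homography coefficients
     are optimized directly against the residual vector "signed distance of
     every radially-corrected point to its group's straight line", refitting
     the polynomial for each candidate.  Uniform scale is excluded from the
     parameterization (the polynomial absorbs it exactly); a redundant
     center-shift parameter, algebraically folded back into the homography,
     is kept deliberately — it preconditions the damped solve, which
     otherwise stalls in a shallow local minimum.  The polish alternates
     with the model-corrected center estimate (below) until the center
     stops moving, and a final pass with translation frozen restores
     straightness without disturbing the center.

   The coefficient-ratio correction (rescale one orientation's a and c by
   the cross-orientation mean intercept-spacing ratio, harmonize b at the
   intersection of the b-vs-c trend lines) is implemented as a global
   anisotropic rescale of the point cloud and available via
   `perspective_correction="coeffs"`; it is adequate for anisotropic
   sampling and very mild tilt.  Detection of perspective (differing
   a-vs-c slopes between orientations, drifting b) is reported as a
   diagnostic flag, but the default pipeline always runs the homography
   route: it converges to the identity on perspective-free grids, whereas
   a tilt just below any detection threshold already biases the radial fit
   beyond the pipeline's accuracy.

5. **Center refinement on the corrected grid.**  The two-line a = 0
   interpolation is unbiased but noise-limited (the curvature step between
   adjacent lines is small); a linear fit of a(c) over ±3 lines averages
   the noise but is biased by higher-order curvature.  That bias is fully
   determined by the fitted model: ideal lines generated from it at the
   same intercepts reproduce the same windowed-root offset, which is
   subtracted.  This model-corrected estimate is the center used for the
   final fit and, mapped back through the inverse homography (which
   cancels the translation ambiguity of the corrected frame exactly), the
   center reported in image coordinates.

6. **Radial coefficients.**  With the origin at the center and perspective
   removed, each undistorted grid line is axis-parallel at intercept c_i^u,
   reconstructed by arithmetic extrapolation from the lines nearest the
   center: anchor i_0 = argmin |c|, spacing Δc = mean |Δc| over the
   `n_near` (default 6) nearest lines, c_i^u = c_{i0} + (i − i_0)·Δc.  Every
   point then yields one linear equation through its scale factor
   f = y_d/c_i^u (horizontal; x_d/c_j^u vertical): backward f = Σ k_m r_u^m
   with r_u = r_d/f; forward 1/f = Σ k'_m r_d^m.  Both orientations are
   stacked into a single least-squares system (one model per image), radii
   normalized by their maximum for conditioning; lines with |c^u| < 1 px
   are excluded (f degenerates).  Δc can be refined by a ±2% grid search
   minimizing the summed squared straightness residuals; one orientation
   at a time, because a common rescale of both spacings is absorbed
   exactly by the polynomial.  The refined tables are kept only when the
   worst-point residual also improves.

7. **Correction and evaluation.**  Images are resampled through the
   backward models (bilinear by default, out-of-frame samples clamped to
   the edge per the backward-mapping convention; a fill constant is
   optional).  Perspective and radial corrections compose into a single
   resampling pass.  Sinogram generation reads only the band of source
   rows the backward map touches for the requested output row, so a
   single slice never requires correcting the whole projection stack.
   Straightness is quantified as the perpendicular distance of each point
   to its group's total-least-squares line, reported against the distance
   from the center (vertical-offset distance would differ at second
   order).

## Defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `poly_order` | 4 | – | captures order-1..3 generating profiles with margin |
| `n_near` | 6 | lines | spacing estimate from the low-distortion core |
| `refine_steps` / `refine_fraction` | 15 / 0.02 | – | ±2% spacing search, sum-of-squares cost |
| `grouping_tolerance` | 0.3 | × spacing | claims points with half-spacing margin |
| `max_missing` | 4 | dots | bridges defect runs without merging lines |
| `residual_threshold` | 2.0 | px | post-grouping outlier cut |
| `normalization_size` | 51 | px | > dot diameter; masked re-estimate makes the result insensitive to the exact value |
| `quality_threshold` | 0.2 | – | Gaussian-validation residual bound |
| `centroid_method` | weighted | – | ~2× lower centroid noise than binary |
| `center_iterations` | 3 | – | quad/center alternation converges in 2–3 |

## Synthetic test bench

The generator produces dot, line and chessboard targets warped by a known
polynomial + homography ground truth, with anti-aliased rendering (4×
supersampled discs and lines; the chessboard is pulled back analytically
per pixel at 8× supersampling — coarser supersampling leaves AA
quantization that measurably biases edge localization), uneven background,
additive Gaussian noise, and a seeded defect simulator (removed, displaced,
enlarged dots) that returns a ledger of what it perturbed.  Test
homographies are built to fix the distortion center (tilt about the
optical axis), so the ground-truth center is well-defined in the observed
image.

What it emulates: geometry, contrast, noise and the dominant defect types
of real targets.  What it does not: scintillator blur, vignetting, X-ray
scatter, target non-flatness, lens models outside the polynomial family.
Passing the bench therefore demonstrates the correctness and the
statistical behaviour of the algorithms under the stated conditions, not
detector-specific performance.

Problem sizes used by the test suite and the acceptance script: rendered
2000×2000 px, 31×31-line dot targets (spacing 60 px, dot radius 10 px,
noise σ = 0.01) for parameter recovery — 50 grids in the suite, 12 in the
acceptance script; 25×25-line point grids at 2000 px for the fisheye
scenarios; 96×96×40 stacks for the sinogram path.

## Numerical choices and degenerate inputs

- All least-squares solves go through column-scaled `lstsq`; the radial
  system reports its condition estimate and rejects past 1e10.
- Quadratic intersection of near-identical parabolas (|Δa| < 1e−8) is
  skipped; near-parallel vanishing lines (< 1e−4 rad) raise instead of
  returning a wild intersection.
- r = 0 is an exact fixed point of every radial map; the identity
  polynomial short-circuits to a bit-exact copy.
- Points whose scale factor f ≤ 0.2 are excluded from the radial system.
- Middle-out tie-breaking: smallest absolute residual, which is
  deterministic and order-independent.
- All stochastic generator operations take an explicit seed or Generator.

## Known limitations

- The reconstructed undistorted space carries an arbitrary global scale
  (the absolute scale of the target is unknowable from one image unless
  the physical line spacing is supplied) and, when
  the center does not fall on a grid line, a small anchor offset; recovered
  radial profiles therefore match the generating profile to ~0.1 px over a
  900 px radius after the best single rescale — not arbitrarily closely —
  while line straightness (what correction quality actually depends on) is
  unaffected.
- The vanishing-point center estimators degrade under tilt and large
  center offsets (see step 3); the pipeline relies on them only for
  centers outside the grid span.
- Output images keep the input shape; fisheye correction therefore crops
  (no canvas expansion).
- Lines absent from the central slab cannot be seeded by the middle-out
  grouping.
- The misplaced-dot nearest-neighbour filter only catches gross
  misplacement (all four neighbour distances off); sub-half-spacing
  displacements are caught by the post-grouping residual filter instead.
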