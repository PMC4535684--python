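# Methods

## The measurement model

A metaphase cell contributes one two-channel 2D image (DAPI-like
counterstain plus probe channel) containing exactly two probe signals — one
per homolog. The per-cell statistic is the normalized inter-homolog
difference of background-corrected integrated intensities,
`d = |I_A − I_B| / (I_A + I_B)`. Because `d` is a ratio of linear
functionals of the image, it is invariant to exposure, gain and any other
overall intensity scale, and to the exact fraction of spot mass the contour
captures *as long as that fraction is the same for both homologs* — which it
is here, since both contours equilibrate at the same image-independent
radius of the edge-map ridge (see below).

## Segmentation

**Edge map.** Gradient magnitude of the Gaussian-smoothed probe image,
normalized to [0, 1]; optionally binarized at a fraction of its maximum
(`binarize_fraction`, default 0 = gray-scale; 0.1 is a reasonable binary
setting). The gray-scale map is the default because it yields a smooth GVF
source with a well-defined ridge.

**GVF.** The edge-map gradient `(f_x, f_y)` is diffused by iterating
`u ← u + γ [ μ ∇²u − (u − f_x)(f_x² + f_y²) ]` (and `v` analogously) with
replicate-edge boundaries. Defaults: `μ = 0.1`, at most 500 iterations,
convergence when the RMS of the Euler-equation residual
`μ∇²u − (u − f_x)(f_x² + f_y²)` drops below `1e−4`. Declaring convergence on
the residual (rather than on the raw update) makes the stated tolerance mean
the same thing for any time step. The default step
`γ = 1 / (4μ + max(f_x² + f_y²))` is strictly inside the explicit-scheme
stability region; a user-supplied step that diverges raises
`FloatingPointError` rather than returning garbage.

**Snake.** 64 vertices, semi-implicit iteration: the circulant
tension/rigidity system `(I + γ(αK₂ + βK₄))` is solved exactly each step
with the external force `κ·(u, v)` sampled bilinearly; vertices are
re-sampled to uniform arc length every iteration; convergence at mean vertex
displacement < 0.02 px, at most 500 iterations (non-convergence returns the
last contour flagged, self-intersection raises and excludes the cell).
Defaults `α = β = 0.1`, `γ = 1`, `κ = 2`, initial circle radius 3× the spot
sigma around each detected peak.

**Where the contour sits.** For a Gaussian spot of width σ smoothed with
σ_s, the edge-map ridge — the snake's equilibrium — lies at radius
`sqrt(σ² + σ_s²)`. Choosing `σ_s = σ·sqrt(2 ln 20 − 1) ≈ 2.19 σ` puts that
ridge exactly at the radius enclosing 95 % of the spot's mass; the snake's
tension then settles a few percent inside the ridge, so the pipeline default
is `σ_s = 2.3 σ`, which places the converged contour at 0.90–0.97 of the
95 %-mass area across the tested amplitude and noise range. The contour
therefore delineates the photometrically meaningful spot boundary, not the
steepest-gradient core. The standalone `compute_edge_map` keeps a plain
2 px default; only the pipeline couples smoothing to the expected spot size.

**Peak detection.** Local maxima of the σ-smoothed image above
`median + 6 × 1.4826 × MAD`, ranked by height (lexicographic (row, col)
tie-break), kept greedily at a minimum mutual distance (6 σ default), with a
2 σ border margin excluded because replicate-edge smoothing under-averages
the frame border. Fewer peaks than expected means failed hybridization and
excludes the cell.

## Quantification

Pixel membership is center-in-polygon (no partial-pixel weighting; the error
is bounded by the perimeter and cancels between homologs). Background is
local: the median of an annulus (width 5 px) outside the 2 px-dilated
contour, with the partner spot's dilated mask excluded; an empty annulus is
an error. Background-corrected pixels are clipped at zero before summation
so noise cannot drive an integral negative. Both intensities zero means
failed hybridization (cell excluded); `weaker_homolog` is `none` only when
`d` is zero to machine tolerance.

## DA statistics

- Per-cell threshold on `d`: **0.3**, inclusive. The DA regime of the
  statistic (medians ≈ 0.5–1 at DA loci) and the treated/equal regime
  (≈ 0.1–0.3) are well separated there; configurable.
- Locus call: flagged fraction ≥ 2/3 (inclusive), AND two-proportion z-test
  against a 0.5 null proportion with an equal-size pseudo-cohort giving
  p < α = 0.05, AND directional consistency (one homolog weaker in > 75 %
  of flagged cells; otherwise "mixed", no call). Cohorts under 10 cells are
  marked underpowered and the call is withheld. The null arm of the
  single-locus test is a design choice — the published criterion names the
  test but not its second proportion; the pre/post use is unambiguous.
- Pre/post: two-proportion z on the flagged counts, signed so reduction is
  negative; significant at z < −2.0. Group means of per-cell `d` are
  reported as Δμ and compared by a two-tailed Welch t-test (unequal
  variances, Satterthwaite df). No multiple-testing correction by default
  (per-locus α); a Bonferroni divisor is available.
- The generic tests (Welch t, one-way ANOVA, Pearson r) are implemented as
  explicit textbook formulas with p-values from `scipy.stats` distributions
  and are cross-checked against scipy/statsmodels in the test suite.
  Degenerate inputs are defined, not NaN: zero-variance equal-mean samples
  give t = 0, p = 1 (F = 0, p = 1); a degenerate two-proportion pool
  (pooled p ∈ {0, 1}) gives z = 0 and is flagged.

## 3D-SIM volumetrics

Geometry is always explicit: 17 sections at 0.13 μm axially (the
reconstruction this models), 0.04 μm in-plane by default (a typical SIM
reconstruction scale; in-plane size is not part of the depth arithmetic).
Segmentation is a global threshold (Otsu by default; a
background + 3√background alternative) followed by the 26-connected
component containing a seed voxel. Depth = number of sections containing
mask voxels × z-step (a contiguous-run mode exists; the default counts all
sections, the two agree for the unimodal axial profiles modeled here).
Volume = voxel count × pixel² × z-step, exact to float rounding. Pair
comparisons report raw (μm, μm³) and normalized (|a−b|/(a+b)) differences;
group-level tests are delegated to the statistics module.

## The synthetic generator

Spots are Gaussians — isotropic in-plane, separable axially — on a constant
photon background with Poisson noise (optional additive read noise). A
Gaussian is analytically integrable (`∫∫ = 2πAσ²`), which anchors the
quantification tests; it does not model SIM reconstruction artifacts,
chromatic shift, overlapping chromosomes or non-uniform background, so
passing tests demonstrate correctness of the measurement chain, not
robustness to every real-microscope pathology. The counterstain channel
(filled ellipse pair) is plumbing for format realism and is never
quantified.

Cohort defaults are the study conditions the generator emulates: 50 cells
per locus (observed cohorts ranged 20–100, mean ≈ 43), DA cells in 85 % of
an untreated DA-locus cohort with true `d ~ U(0.4, 0.9)` and a fixed weaker
homolog, null/treated cells with `d ~ U(0, 0.2)` and a random weaker side —
bracketing the two observed regimes of the statistic. The summed pair
amplitude is 400 photons at peak over a background of 10 photons/pixel
(peak SNR ≈ 6–60 across `d`, integrated SNR far higher); spot σ = 2 px. No
acquisition noise statistics were published for this assay; Poisson shot
noise at these levels is the conventional assumption. 3D truth (axial span,
voxel count) is defined by the generator's own fixed rule — noise-free spot
signal above `3√background` — so truth is meaningful independently of the
analysis module's thresholding.

## Determinism and QC

Every stochastic step takes an explicit integer seed (no wall-clock
seeding); per-cell seeds are derived from the cohort seed, so identical
configuration yields bit-identical images, tables and reports. Every
excluded cell appears exactly once in the QC log with a reason code
(`peak_detection`, `degenerate_contour`, `background`, `quantification`,
`peak_assignment`); locus statistics use the surviving cells.

## Problem sizes

Default frames are 96×128 px (2D) and 17×64×96 voxels (3D); simulation-based
test suites use 200 replicates (noise statistics, pairing property,
type-I/power checks use 500–2000 draws of the closed-form statistic). These
sizes make the full test suite and the acceptance script run in seconds to a
few minutes on one CPU while keeping Monte-Carlo standard errors well inside
the asserted bounds.

## Known limitations

- Exactly two probe signals per cell; touching-spot splitting, multi-probe
  scenes and counterstain (chromosome) segmentation are out of scope.
- The per-cell DA threshold (0.3) is a package default informed by the two
  regimes of the statistic, not a published constant.
- "Intensity ratio" box-plot summaries and the normalized difference are
  treated as the same quantity; the method defines only one statistic.
- Whether published normalized mean pair differences in volume/depth are raw
  or normalized is ambiguous in the source material; both are emitted.
- No photometric calibration, flat-fielding or deconvolution.
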