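# Methods

This note documents the model implemented by `oecontour`, the numerical
choices behind it, and what the synthetic validation does and does not
establish.

## Model

The segmentation engine is the two-phase Chan–Vese active contour: a
level-set function φ (positive inside the contour) evolves by

    ∂φ/∂t = δ_ε(φ) [ μ(x) · div(∇φ / |∇φ|) − λ(x) · ((I − c₁)² − (I − c₂)²) ],

with c₁, c₂ the smoothed-Heaviside region means, refreshed every step.
Where the classic model uses two scalars (μ, λ) — empirically fine-tuned
to μ = 0.006·255², λ = 1 on the [0, 255] intensity scale — this package
replaces them with pixel-wise maps derived from the image's regional edge
structure, computed **once** before evolution:

1. **Grid tiling.** The image is cut into square tiles. The automatic
   rule picks the tile side as min(height, width)/8, floored to an even
   integer and clamped at 8: 32 for 256², 40 for 320². A tile of that
   size is large enough to hold a meaningful edge region yet small enough
   to stay locally homogeneous.

2. **Directional decomposition.** Each tile passes through a
   critically-sampled 4-band directional filter bank (the two-level fan
   tree of the contourlet family, realized by its equivalent frequency
   wedge responses under periodic tile extension, with the two quincunx
   stages' combined diagonal-2 decimation applied at once). A tile of
   side s yields four subbands of side s/2 — coefficient count preserved.
   The four wedges are centered on the principal orientations
   (0°, 45°, 90°, 135°), so a grating at any of those angles excites a
   single band. The windows share an isotropic radial high-pass
   (raised-sine below 3 cycles/tile, DC bin zeroed): a constant, or the
   broad plateaus flanking a step edge, carry no orientation, and removing
   them is what makes a coherent edge *sparse* in its band. This is the
   role the Laplacian detail stage plays in the full contourlet transform,
   folded into the band filters so the critical-sampling geometry is
   untouched. Orientation selectivity is unaffected because the taper is
   isotropic. The bank is analysis-only; no reconstruction is needed.

3. **Orientation entropy.** Each subband is scored by the Shannon entropy
   of its normalized coefficient magnitudes, and the four scores are
   summed into the tile's OE. The default probability estimator
   soft-thresholds |coefficients| at

       T = max( 3 × median|c| over all bands,  0.25 × tile peak |c| ),

   then L1-normalizes per band (a band left empty scores zero). The first
   floor tracks the image's noise level: without it, per-band
   normalization is scale-invariant inside each tile, and a featureless
   noise tile — noise being the most spatially spread signal there is —
   scores near the maximum, inverting the intended ordering. The second
   floor is a local-saliency gate: the sidelobes of one strong edge
   otherwise read as spatial spread. Both floors scale linearly with
   intensity, so OE is invariant under positive rescaling of the image,
   and the bound 0 ≤ OE_jk ≤ log₂(M·N) survives thresholding (a partial
   distribution with mass q ≤ 1 obeys −Σ p log p ≤ log(M·N)). The plain
   unthresholded estimator is available as `normalization="band"` for
   diagnostics. With the default estimator, multi-oriented clutter scores
   highest, a coherent boundary scores through its one compact band, and
   flat regions score near zero — the ordering the parameter maps rely
   on, asserted by the test suite on dedicated fixtures and across the
   phantom study grid.

4. **Parameter maps.** The tile OE grid is rescaled linearly to
   [eps, 1] (all-equal grids map to 1), broadcast piecewise-constant to
   pixels as the data-fidelity map `w_df`, and inverted element-wise for
   the regularization map `w_reg = 1/w_df` — the reciprocal coupling
   balances the two forces: where data are unreliable clues (high-OE
   clutter already excluded, low-OE structure), regularization takes
   over. In the solver, `w_reg` is anchored to the classic model's
   magnitude as μ(x) = w_reg(x)·0.006·255² and λ(x) = w_df(x), so unit
   maps reproduce the fine-tuned scalar model exactly (a tested
   invariant). `eps` defaults to 0.01: it bounds the reciprocal pair's
   dynamic range at 100:1. Much wider ranges make the curvature term
   stiffer than a single evolution step can resolve — the semi-implicit
   update becomes insensitive to the time step in those tiles, and the
   monotone line search (below) stalls prematurely.

The structure-tensor module (smoothed gradient outer products, closed-form
eigenvalues λ₁ ≥ λ₂ with the + sign on λ₁, coherence
(λ₁−λ₂)/(λ₁+λ₂), quiver export) is diagnostic: it visualizes the
structured/unstructured dichotomy that motivates OE, but the segmentation
path uses OE only.

## Numerics

- **Discretization.** The curvature term uses the neighbor-weighted
  semi-implicit scheme of the original Chan–Vese numerical treatment
  (coefficients μ/√(η² + |∇φ|²) on the four neighbors, center treated
  implicitly), which remains stable for the large effective μ the maps
  produce; the data term is explicit. Defaults: dt = 0.1, smoothed
  Heaviside/delta width ε = 1 intensity unit of φ, gradient guard
  η² = 1e-8. An explicit Euler scheme is available for comparison at
  small weights (`scheme="explicit"`).
- **Monotone energy control.** Each iteration the step is accepted only
  if the discrete weighted energy (length term Σ μ δ_ε(φ)|∇φ| plus
  fidelity term) does not increase; otherwise dt is halved up to six
  times. If no step size decreases the energy, the iteration counts as a
  stall, and five consecutive stalls terminate the run. This makes the
  energy trace non-increasing by construction (within 1e-9 relative)
  and gives a well-defined convergence point.
- **Stopping.** Evolution stops when the zero-crossing set changes by
  fewer than `tol` pixels (default 2) for five consecutive iterations,
  when the contour vanishes, or at `max_iter` (default 300). Pixels with
  φ = 0 exactly count as outside.
- **Initialization.** A circle, φ = radius − distance (an exact signed
  distance). The automatic choice centers it at the intensity centroid
  with radius min(side)/4 — "near the target" for a single dominant
  object. A one-signed φ in the first five iterations raises a
  degenerate-initialization error.
- **Reinitialization** (signed-distance rebuild via Euclidean distance
  transform) is available (`reinit_every`) but off by default: it is a
  non-energetic operation that jumps the diffuse-Heaviside energy, and
  the semi-implicit scheme does not need it on the tested conditions.
  When enabled, the energy trace is re-based at each rebuild.
- **Degenerate inputs.** Zero-mass subbands map to the uniform
  distribution in the public per-band estimator (and to zero entropy
  under the thresholded default); an all-equal OE grid yields unit maps;
  empty Heaviside sides fall back to the global mean intensity.

## Synthetic phantoms

`make_phantom` renders one smooth-boundary target (disk, ellipse, or
harmonic-perturbed blob; intensity 150) on a background (intensity 100)
littered with short anti-aliased strokes at random orientations, plus
additive Gaussian noise, clipped to [0, 255]; the paired ground truth is
the set of pixels inside the ideal boundary. Defaults: 256 × 256 images
(the grid rule then gives the 32-px tiles and 16-px subbands quoted
above), target radius 0.23 × side with ±3 % center jitter, stroke
contrast ±30 grey levels, length 5–11 px, half-width 0.7 px, 6–12 strokes
per filled 16-px background cell. Strokes are masked off the target so
ground truth stays exact. `phantom_suite` spans the full cross of clutter
densities {0.2, 0.5, 0.8} × noise σ {2, 5, 10} × three shapes — 27
phantoms, seeded and reproducible.

Two generator choices matter and are deliberate. Clutter is made of
*strokes*, not plain noise, because noise has no oriented edges and would
not exercise the directional bank. Stroke contrast is background-like
(±30, i.e. clutter stays on the background side of the inside/outside
decision threshold) because clutter that mimics the target intensity
defeats any region-statistics model — it would test a failure mode the
model class shares with its baseline, not the parameterization.

What passing the phantom study shows: on images satisfying the model's
premise (two intensity populations; structured target boundary;
unstructured, intensity-distinguishable clutter), the entropy-derived
maps match hand-tuned quality without tuning, converge in no more median
iterations, and the printed detuned exemplar degrades — the sensitivity
the self-parameterization removes. What it does not show: performance
under modality-specific physics (ultrasound speckle, mammographic
texture), intensity inhomogeneity, multi-object scenes, or weak/broken
boundaries; none of these are simulated.

## Known limitations

- The method inherits the two-phase piecewise-constant assumption of its
  host model; it re-weights forces but cannot segment what the energy
  cannot represent.
- OE is computed on a fixed grid; a boundary crossing a tile corner
  contributes little entropy, and the maps are blocky at tile resolution
  (an optional Gaussian smoothing of `w_df` exists, off by default).
- The filter bank is analysis-only and uses smooth angular wedge windows;
  it is not a perfect-reconstruction contourlet implementation.
- The threshold constants of the default OE estimator (3 × median,
  0.25 × peak) were calibrated on the phantom family at the 256²/32-px
  geometry; strongly different noise statistics may warrant retuning.
- Iteration counts depend on the stopping rule; wall-clock speed claims
  are hardware-bound and deliberately not made — the suite measures
  iterations under identical initializations instead.
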