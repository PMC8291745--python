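# Methods

This note documents the models, numerical choices and limitations behind
`histalign`: a two-step (affine + greedy diffeomorphic) registration
pipeline for differently stained 2D histology sections, evaluated with
landmark-based error statistics on synthetic slide pairs.

## Stain model and registration channel

Stains mix additively in optical density:
`od = -log10(I / I0)` per RGB channel, and a pixel's OD triplet is
`conc_row @ M`, where the rows of `M` are the unit-normalized OD triplets
of FastRed, FastBlue and DAB.  Unmixing is `conc_row = od_row @ M^-1`,
with `M^-1` recomputed from `M` at full precision.  Intensities are floored
at 1/255 of the background before the log (standard practice; the model is
undefined at zero), and the background level is fixed at the dtype maximum
rather than estimated per slide.

Slides whose label indicates DAB content (ESR, ERBB2) are registered on the
FastBlue channel, which retains tissue structure while discarding the
brown DAB background.  The channel is re-rendered as a single-stain
pseudo-intensity `10^-conc` rather than used as a raw concentration: raw
concentrations are bright-on-dark while luminance images are dark-on-bright,
and the polarity flip makes perfectly aligned cross-stain pairs
*anti*-correlate under NCC (measured NCC ≈ −0.7).  All other labels use
Rec. 601 luminance; the choice of scalar channel for non-DAB stains is a
convention of this package, not a published rule.  Channels are rescaled to
[0, 1].

## Preprocessing geometry

Full-resolution slides are smoothed with a Gaussian of σ = (1/f)/2 pixels
and downsampled by `f` (default 1/25).  σ is half the resampling stride —
the Nyquist reading of the smoothing rule; a literal σ = f/2 = 0.02 px
would be a no-op.  Downsampling is local-mean (area) style: a uniform
filter over one output-pixel footprint followed by sampling on the strided
grid `x_full = x_work / f`.  The strided convention makes the landmark
mapping exactly `p_work = p_full · f + pad_offset`, with no half-pixel
bias, and the area step conserves integrated intensity to well under 1%.

Pairs are padded to a common size (per-side maximum, tissue centered), then
each side grows by 2·4·(2r+1) pixels — four similarity-kernel diameters per
edge — so tissue stays clear of the boundary after the affine step.
Padding is filled with Gaussian noise matched to the pooled mean/std of the
four corner patches of the unpadded image (patch side = one kernel
diameter), clipped to the image's intensity range.  Matched noise removes
the spurious NCC wall that a constant (e.g. white) fill creates along the
pad boundary; the package ships a demonstration (`fig5_pad_demo`) showing
the boundary-strip |NCC| dropping from ~1.0 (white fill) to ~0.57 (noise
fill) while windows that never touch the pad are bit-identical.

## Similarity metric

Windowed NCC with radius `floor(width/S)`, `S = 40`, computed with five
integral images (I, J, I², J², I·J) so cost is independent of the radius.
Windows are clipped at the image boundary; every pixel owns a window.
The registration minimizes the masked mean of `1 − NCC`.

Two policies matter in practice:

* **Featureless windows.**  Windows whose intensity std is below 0.01 (on
  the [0, 1] channel scale) in either image contribute NCC = 0.  Without
  this floor, near-flat background windows correlate at ±1 through residual
  illumination gradients; because background dominates the slide area,
  those coin-flip correlations create false affine optima (on the recovery
  suite this single policy moved the median landmark error from ~1.0 to
  ~0.6 px).
* **Gradient.**  The gradient of the masked mean dissimilarity with respect
  to a per-pixel displacement is computed exactly: the adjoint of the
  window statistics (itself a set of box sums) times the spatial gradient
  of the warped moving image.  It matches central finite differences to
  within ~2%.

Per pyramid level the radius is `floor(radius/stride)` (at least 1), so
windows cover a constant physical extent.

## Affine stage

Initialization is a brute-force search over 4500 random rigid transforms —
angle ~ Normal(0, 180°), per-axis translation ~ Normal(0, 10% of width) —
evaluated at the 4× pyramid level with the identity included as a
candidate, argmin kept (first occurrence on ties; deterministic given the
seed).  Refinement minimizes the masked dissimilarity over the six affine
coefficients with L-BFGS-B, coarse-to-fine (4×, 2×, 1×), warm-starting each
level.  Two numerical details are load-bearing:

* the linear coefficients are rescaled so a unit parameter step moves an
  edge pixel about one pixel (the raw 6-coefficient problem is so badly
  conditioned that the optimizer stalls several pixels from the optimum);
* gradients use 3-point finite differences (the objective is piecewise
  smooth in the parameters because of bilinear interpolation; one-sided
  differences are too noisy).

Transforms act about the image center in the pull-back convention
`output(x) = moving(A(x − c) + c + t)`.  Each level, and the stage as a
whole, falls back to its starting transform if the optimizer fails to
improve the metric, so the stage never returns something worse than its
initialization.

## Greedy diffeomorphic stage

The update equations are: smooth the negative metric gradient with an
isotropic Gaussian σ_s, scale it to a bounded step ψ = Id + v, compose the
running field φ ← φ∘ψ, and smooth the composed displacement with σ_t.
Defaults σ_s = 6 px, σ_t = 5 px, iterations (100, 50, 10) on the (4×, 2×,
1×) pyramid.  Larger σ_s gives smoother updates; larger σ_t gives less
total deformation.  Design choices made where the scheme is underspecified:

* **σ units across levels.**  σ_s and σ_t are stated in working-resolution
  pixels and held fixed in physical scale, i.e. divided by the level stride
  at coarser levels.  Keeping them fixed in level voxels instead smooths
  coarse levels so aggressively that almost no deformation survives there
  (measured: 40% vs 75% landmark-error reduction on the recovery suite).
* **Step size.**  The smoothed update field is scaled so that its 95th
  percentile magnitude (within the mask) equals `step_cap` (default 1 px)
  and any longer vector is clipped to `step_cap`, so the largest update
  never exceeds the cap.  Normalizing by the maximum instead lets a handful
  of high-contrast pixels set the global scale and starves typical tissue
  pixels (measured: 62% vs 86% error reduction).  With the cap at 1 px and
  σ_s = 6, every ψ, and hence the composed field, keeps a positive Jacobian
  determinant on the entire test suite (minimum ≈ 0.5).
* **Stage separation.**  The affine result is not folded into the field:
  the moving image is resampled through A once and the field lives in that
  frame; the total map is x ↦ A(φ(x)).  This keeps the landmark chain
  simple and mirrors the two-matrix output of the pipeline.
* Fields are composed with bilinear interpolation and clamp-to-edge
  sampling; between levels the field is resampled on the exact strided
  grid (level-k pixel x sits at level-p coordinate x·k/p) with
  displacements rescaled by the stride ratio.
* No explicit regularization penalty is added to the objective; all
  regularity comes from σ_s/σ_t smoothing, as the update equations
  prescribe.
* If the finished field scores worse than the post-affine start at full
  resolution, the identity field is returned with a warning — the stage
  never degrades the metric.

The Jacobian determinant of φ(x) = x + u(x) uses central differences
(one-sided at the boundary) and is attached to every run as a diagnostic.

## Landmark evaluation

Full-resolution landmarks map to working space by `p·f + offset`; the
fixed image's landmarks are pushed through φ then A (the same pull-back
map that resamples the moving image, evaluated pointwise) and back to the
moving image's full-resolution frame.  TRE is the Euclidean distance to
the moving image's landmarks, rTRE divides by the moving (target) image
diagonal, robustness is the fraction of landmarks whose rTRE strictly
decreased (ties count as not improved).  Aggregates over pairs follow the
challenge conventions: average and median of the per-pair median rTRE,
average/median of per-pair average rTRE, average/median robustness.

## Synthetic study conditions

The generator (`histalign.synthetic`) emulates the conditions the pipeline
is designed for, with all values chosen for realism and then frozen:

* **Tissue.**  1250×1250 px slides (preprocessed at f = 1/5 to ~250 px
  working side, inside the 200–700 px band the pipeline targets): a union
  of random elliptical lobes squashed through a steep sigmoid (sections
  have crisp cut boundaries), carrying band-limited texture at two scales.
* **Stains.**  Density maps are rendered to RGB through the forward OD
  model with distinct recipes (an H&E-like FastBlue/FastRed mix; a
  DAB-brown mix), on a bright (0.92–0.98) background with mild illumination
  noise.
* **Section individuality.**  Each section adds its own fine-scale
  component (different cells in adjacent sections).  Its amplitude, 0.03 of
  the density range, is calibrated so perfectly aligned registration
  channels still correlate at NCC ≈ 0.85 — adjacent real sections remain
  strongly correlated at the working scale.
* **Warps.**  Rigid, affine, sinusoidal and Gaussian-bump ground-truth
  maps with analytic forward evaluation and exact (or fixed-point-iterated,
  tol 1e-12) inversion; generation rejects any warp whose Jacobian is not
  strictly positive.  The sinusoidal fixture composes the smooth warp
  (8 working px amplitude, 80 working px wavelength) with a modest rigid
  mounting offset, because consecutive sections are mounted independently
  and never start aligned.
* **Landmarks.**  Placed on corner-salient structures (Shi–Tomasi maxima)
  inside well-supported tissue, mimicking how annotators pick uniquely
  identifiable points; random flat-tissue points would not be annotatable
  in practice.

What the generator does **not** emulate: nuclei-scale morphology, tears,
folds, missing tissue, stain artifacts, scanner aberrations.  Passing the
synthetic suite therefore demonstrates the geometric and numerical
correctness of the pipeline — capture range, convergence, diffeomorphism
preservation, metric/evaluation arithmetic — not robustness to real-slide
artifacts.

## Known limitations

* Accuracy at the tissue periphery is aperture-limited: along a smooth
  tissue boundary only the edge-normal motion component is observable, so
  tangential errors of a few pixels can survive there.  Interior,
  textured regions converge to ~1 px at working resolution.
* The σ_s × σ_t grid search on the clean synthetic suite is minimized at
  the smallest σ_t in the swept box, not at an interior cell: with exact
  ground-truth correspondence and no section artifacts, less total-field
  smoothing is monotonically better.  An interior optimum emerges only
  from real-data artifacts (non-corresponding structure, tears) that the
  generator deliberately does not model; the sweep harness itself is fully
  functional and tested.
* Registration quality is resolution-bounded by the working scale; the
  full-resolution warp is produced by rescaling the working-resolution
  field, never by re-optimizing at full scale.
* The problem sizes used in the test suite (800–1250 px synthetic slides,
  20-pair affine suite, 3-pair diffeomorphic suite) were chosen so the
  whole suite exercises every claim at desk scale.
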