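# histalign

Accurate alignment of differently stained, consecutively cut 2D histology
slides.  Adjacent sections of one tissue block are stained with different
dyes (H&E, ESR, ERBB2, ...), digitized independently, and end up arbitrarily
rotated, shifted and smoothly deformed relative to each other.  Registering
them restores pixel-level correspondence so that structure seen in one stain
can be read in the context of the others — a prerequisite for multi-marker
tissue analysis and 3D reconstruction from serial sections.

`histalign` is a library plus a command-line tool implementing a two-step
diffeomorphic registration pipeline with a landmark-based evaluation
framework, exercisable entirely on synthetic slide pairs.

## Method

Given a fixed image $I_i$ and a moving image $I_j$:

1. **Stain color deconvolution.**  DAB-containing slides (ESR/ERBB2) are
   unmixed in optical density, $\mathrm{OD}_c = -\log_{10}(I_c/I_{0,c})$,
   through the inverse of the unit-row stain matrix $M$ (rows FastRed,
   FastBlue, DAB); registration uses the FastBlue channel re-rendered as a
   pseudo-intensity.  Other slides use Rec. 601 luminance.
2. **Preprocessing.**  Gaussian smoothing at the Nyquist scale of the
   resampling stride, downsampling by a factor $f$ (default $1/25$), padding
   of the pair to a common size with the tissue centered plus four
   similarity-kernel diameters per edge, and filling the padding with
   Gaussian noise matched to the four corner patches, which suppresses
   spurious NCC responses along the pad boundary.
3. **Similarity.**  Windowed normalized cross-correlation with adaptive
   radius $\lfloor \mathrm{width}(I_i)/S \rfloor$ ($S = 40$), computed with
   integral-image sum tables; the registration minimizes the masked mean of
   $1 - \mathrm{NCC}$.
4. **Affine stage.**  A brute-force search over 4500 random rigid transforms
   (angle $\sim \mathcal N(0, 180^\circ)$, translation
   $\sim \mathcal N(0, 0.1\,w)$ per axis) at the coarsest pyramid level
   seeds an L-BFGS minimization over the 6 affine coefficients, run
   coarse-to-fine over a 4×/2×/1× pyramid.
5. **Greedy diffeomorphic stage.**  Iterated updates
   $\psi^\gamma = \mathrm{Id} + \varepsilon^\gamma\,[G_{\sigma_s} * D_\varphi\mu]$,
   $\varphi^{\gamma+1} = G_{\sigma_t} * (\varphi^\gamma \circ \psi^\gamma)$
   with $\sigma_s = 6$, $\sigma_t = 5$ px and $N = \{100, 50, 10\}$
   iterations per pyramid level; small smoothed steps composed into the
   field keep the Jacobian determinant positive, so the result is a
   diffeomorphism.
6. **Evaluation.**  Landmarks are mapped through the preprocessing geometry
   and the estimated pull-back chain; accuracy is measured as
   $\mathrm{rTRE} = \mathrm{TRE}/\sqrt{w^2 + h^2}$ and robustness as the
   fraction of landmarks whose rTRE strictly decreased.

## Worked example

Generate a synthetic pair of differently stained sections related by a known
rigid offset plus a sinusoidal deformation (8 px amplitude at working
resolution), register, and score the landmarks:

```python
from histalign import (SynthConfig, make_tissue_pair,
                       RunConfig, register_pair, evaluate_result)

cfg = SynthConfig(seed=0)
fixed, moving, gt, fixed_lm, moving_lm = make_tissue_pair(cfg)
run = RunConfig(resample_factor=1/5, seed=100, n_init=4500,
                moving_stain_label="ERBB2")
result = register_pair(fixed, moving, run)
report = evaluate_result(result, fixed_lm, moving_lm)
for stage in ("initial", "affine", "affine_diffeo"):
    print(f"{stage:14s} median rTRE = {report[stage].median_rtre:.5f}")
print(f"robustness     = {report['affine_diffeo'].robustness:.3f}")
print(f"min Jacobian   = {report['min_jacobian']:.3f}")
```

Output:

```
initial        median rTRE = 0.06197
affine         median rTRE = 0.02092
affine_diffeo  median rTRE = 0.00393
robustness     = 1.000
min Jacobian   = 0.592
```

The unregistered pair starts at a median relative error of 6.2% of the
image diagonal; the affine stage cuts it to 2.1%, the diffeomorphic stage
to 0.39%.  Every landmark improved (robustness 1) and the minimum Jacobian
determinant of the deformation stays positive (0.59), i.e. the map is
invertible everywhere.

The same pipeline is available from the shell:

```bash
histalign synth --preset small --seed 0 --out pair/
histalign register --fixed pair/fixed.png --moving pair/moving.png \
    --fixed-landmarks pair/fixed_landmarks.csv \
    --moving-landmarks pair/moving_landmarks.csv \
    --moving-stain ERBB2 --out run/
histalign evaluate --report run/report.json --out aggregate.json
histalign sweep --pairs-dir pair/ --sigma-s 2,6,10 --sigma-t 2,6,10 --out grid.csv
```

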