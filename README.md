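# salseg

Saliency-driven segmentation of stained nucleated blood cells — and salient
objects in general — by simulating fixational eye movements: a coarse gaze
region is found by fast fixation prediction, then repeatedly refined by an
on-line-trained pixel classifier in a positive-feedback loop that stops when
the "perception saturates".

## Who this is for

Researchers working on leukocyte (white-blood-cell) analysis in
Wright–Giemsa-stained smear micrographs, where nucleated cells are darkly
stained and therefore visually salient, but staining and imaging conditions
shift colours too much for fixed thresholds or pre-trained models. The
method needs **no prior knowledge and no labelled data**: all training
samples are drawn from the image being segmented.

## The method

1. **Fixation prediction (spectral residual).** On the 64×64 luminance
   frame, with `F` the 2-D DFT, `A(f) = |F(I)|`, `P(f) = phase(F(I))`,
   `L(f) = log A(f)`, the spectral residual is `R(f) = L(f) − h_n ∗ L(f)`
   (`h_n` a 3×3 mean filter) and the saliency map is
   `SR(x) = |F⁻¹(exp(R + jP))|²`. The top n = 100 pixels define a minimal
   fixation rectangle.
2. **On-line EPELM classification.** m = 500 high-gradient pixels inside the
   fixation area (positives, RGB features, target +1) and 500 pixels outside
   (negatives, −1) train an ensemble of p = 3 polyharmonic extreme learning
   machines `f_r(x) = Σᵢ βᵢ G(aᵢ, bᵢ, x) + P(x)` — random inner weights, an
   affine trend `P(x)`, output coefficients by Moore–Penrose pseudoinverse.
   Each member's sign-thresholded output over all pixels is one binary
   *stimulus*; stimuli accumulate into a vote-fraction saliency map.
3. **Background suppression (RBD).** Superpixels with high *boundary
   connectivity* `BndCon = B(p)/√A(p)` (soft geodesic-colour version) get
   background probability `w_bg = 1 − exp(−BndCon²/2σ²)`; superpixel
   saliencies minimise
   `Σ w_bg s² + Σ w_fg (s−1)² + Σ w_ij (sᵢ−sⱼ)²`, a single linear solve.
4. **Positive feedback.** Threshold the map → new fixation area → sample,
   learn, classify again → accumulate the new stimuli. Stop when two
   consecutive binary fixation masks are similar enough
   (F-measure ≥ 0.95, β² = 0.3): the perception is saturated. The final
   mask is the segmentation.

## Worked example

```python
from salseg import synth, pipeline, metrics

img, truth, _ = synth.generate_smear(synth.SmearParams(seed=42))
result = pipeline.segment(img, pipeline.PipelineConfig(seed=7))
res = metrics.precision_recall(result.mask, truth)
print(result.report["converged"], result.report["iterations"])
print(f"P = {res.precision:.3f}, R = {res.recall:.3f}, F = {res.f_measure:.3f}")
```

prints

```
True 2
P = 0.977, R = 0.979, F = 0.977
```

The loop thresholded the optimized map (mask area 320 px at 64×64),
re-learned once, and stopped at consecutive-mask similarity F = 0.978 ≥
0.95 — saturation after two iterations. Against the exact ground-truth cell
outline the final mask scores F = 0.977 (β² = 0.3, precision-weighted).

The same run from a shell:

```bash
salseg synth --n 1 --seed 42 --out fixtures/
salseg segment fixtures/img_000.png --out out/ --seed 7
salseg eval --pred out/ --truth fixtures/ --out scores.csv
```

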