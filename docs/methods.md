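# Methods

## Problem and pipeline

Capsule endoscopy produces tens of thousands of frames per examination;
screening them for tumoral tissue is a texture-classification problem.
`wcetex` implements a multi-scale texture feature model for such frames
and an evaluation harness to score feature sets by sensitivity and
specificity.

For a frame `I`, the pipeline is:

1. **Color decomposition.** `I` is converted to HSV (hexcone model, all
   components in [0, 1]); the three planes `I^i` are processed
   independently and symmetrically. Hue is treated as a plain scalar —
   no circular statistics — because the moments downstream only
   correlate descriptor values, never raw hue angles.
2. **Field-of-view mask.** Capsule optics image a circular field inside
   a black square; statistics are restricted to an FOV mask. The
   default is the inscribed disc (radius 0.5 × min dimension); a
   threshold mode (brightness cut, largest connected component, holes
   filled) suits real frames with off-centre optics.
3. **Wavelet focus images.** Each plane gets a two-level wavelet
   decomposition into detail bands `D_l`, `l = 1..6` (three
   orientations per level) plus a level-2 approximation. Two *focus
   images* per channel are synthesized by inverse transform of a
   band-selected coefficient set: focus 1 from bands {1, 2, 3}
   (high-frequency), focus 2 from bands {4, 5, 6} (medium-frequency);
   the approximation is always zeroed. Texture lives in these
   medium/high-frequency scales; the smooth shading discarded with the
   approximation carries none.
4. **Co-occurrence descriptors.** Each of the six synthesized images is
   min-max quantized over the FOV to `N_g = 32` levels ("dispersion":
   detail reconstructions concentrate near zero, so the affine rescale
   spreads the texture over all levels before quantization), and
   co-occurrence matrices are accumulated at distance `d = 1` in the
   four directions {0°, 45°, 90°, 135°}, counting only pairs whose two
   pixels both lie inside the FOV. Four statistics per matrix — angular
   second moment F1, correlation F2, inverse difference moment F3,
   entropy F4 — give the 96-value descriptor tensor
   `F_m(C_α(N^{i,j}))`, indexed (measure, direction, channel, focus).
5. **Color-scale moments.** With keys {H, S, V, h, s, v} (uppercase =
   focus 1, lowercase = focus 2), the tensor is collapsed into the
   140-component observation vector: for each measure, 21 second-order
   moments `φ = Σ_α F(a)·F(b)` over unordered key pairs (diagonal
   included), 6 marginal third-order moments `γ = Σ_α F(k)³`, and 8
   joint third-order moments `ζ = Σ_α F(a)·F(b)·F(c)` over the triples
   HSV, hSV, HsV, HSv, hsv, Hsv, hSv, hsV (one letter per color, both
   cases; triples mixing two scales of the same color are redundant
   with φ and excluded). All moments are raw product sums over the four
   directions — no centering, no normalization — so third-order terms
   retain sign information about skewed, non-Gaussian descriptor
   distributions.
6. **Evaluation.** Features are z-scored, optionally PCA-reduced
   (typical operating points: 140→70 and 140→40 components), and
   classified by a stock multilayer perceptron under stratified 10-fold
   cross-validation repeated 10 times. Sensitivity = abnormal recall,
   specificity = normal recall, reported as mean ± std over repeats.

A single-scale ablation restricts the keys to {H, S, V} (40 components:
6 φ + 3 γ + 1 ζ per measure), quantifying what the cross-scale terms
add. A 54-feature baseline (texture-unit spectra or plain intensity
histograms over R, G, B, H, S, V, each summarized by nine distribution
statistics) provides a reference feature set of comparable size.

## Parameters that matter

| parameter | default | why |
| --- | --- | --- |
| wavelet | `db2` | shortest Daubechies filter beyond Haar; compact support preserves fine texture. Exposed, not hard-wired — the feature layout is filter-agnostic. |
| transform variant | undecimated frame | shift-covariant sub-bands, same-shape focus images; `decimated` available (energy-preserving pyramid). |
| levels | 2 (fixed) | the descriptor layout is built around exactly two scales; other depths are rejected. |
| `N_g` | 32 | co-occurrence level count; 32 levels retain texture discrimination at a fraction of the 256-level cost. |
| `d` | 1 | nearest-neighbour pair displacement; texture at the finest scale. |
| symmetric accumulation | on | Haralick's convention; each pair counted in both orders. |
| MLP | 1 hidden layer of ⌊(n_feat+2)/2⌋ logistic units, lr 0.3, momentum 0.2, 500 epochs | stock defaults, kept fixed so scores reflect features, not tuning. The epoch budget is fixed: no plateau-based early stop. |
| CV | 10 folds × 10 repeats, stratified | every frame tested once per repeat; per-repeat rates pool fold confusions. |

## Numerical choices

- **Boundary handling.** Both transform variants use periodic extension
  (the stationary transform is inherently periodic; the decimated path
  uses periodization mode). This keeps the decimated orthogonal
  transform exactly energy-preserving and reconstruction exact to
  machine precision. Inputs with dimensions not divisible by 4 are
  symmetrically padded before the frame transform and cropped after
  inversion.
- **Quantizer degeneracy.** A value range below 1e-12 (relative) is
  treated as a constant plane mapping to level 0; otherwise min-max
  dispersion would amplify the ~1e-16 wavelet residue of a constant
  input into spurious full-range texture.
- **F2 degeneracy.** When either marginal standard deviation is zero
  the correlation is defined as 0.
- **F3/F4 conventions.** The default F3 uses the squared-difference
  weight `1/(1+(i−j)²)`; a first-power variant (`as_printed`, weight
  `1/(1+(i−j))` with the `j = i+1` cell excluded — that cell would
  divide by zero, and cells below the diagonal acquire negative
  weights) is preserved for comparability. F4 defaults to the
  nonnegative entropy `−Σ p log₂ p`; the sign is configuration and
  irrelevant to classification.
- **Leakage.** Standardization and PCA are fitted on training folds
  only; a `global` PCA scope reproduces protocols that fit PCA once on
  the full table before CV.
- **Seeds.** One master seed drives everything: per-repeat splitter
  seeds and per-fold MLP initialization seeds are drawn from it
  deterministically, so a fixed seed yields bit-identical feature CSVs
  and CV reports.

## Synthetic data: what it emulates, and what it does not

No public corpus accompanies the task the pipeline targets, so the
package ships a generator whose frames exercise exactly the statistics
the features measure: a smooth low-frequency HSV background inside a
circular FOV (black corners outside); two additive band-limited noise
textures, built by ring band-pass filtering white noise in the
frequency domain — a high band (0.25–0.45 cycles/pixel) landing in the
level-1 wavelet details and a mid band (0.10–0.20) landing in the
level-2 details; and, in abnormal frames, a circular lesion patch
(30 % of the FOV area by default) where both band amplitudes are
multiplied up (defaults 2.0× high, 1.6× mid) and the texture passes
through the zero-preserving map `(exp(λt)−1)/λ` with `λ = 1.5`, which
skews its amplitude distribution. The lesion therefore injects signal
into cross-scale second-order moments *and* third-order moments, and
the mid-band change is invisible to the single-scale ablation by
construction. Setting both multipliers to 1 and `λ = 0` makes the
classes exchangeable (null configuration).

What the generator does **not** emulate: mucosal color variability
between subjects, specular highlights, bubbles/froth, peristaltic
motion blur, lesion shape irregularity, and patient-level correlation
between frames. Passing the end-to-end study therefore shows that the
pipeline detects joint multi-scale/higher-order texture differences of
the stated effect size through the full chain — not that it reaches any
particular performance on clinical material.

## Study sizes

The end-to-end study uses 200 frames per class at 128×128 — large
enough for stable 10×10-fold rates (40 test frames per fold), small
enough to run on a desk machine in a few minutes. Oracle tests use
≤8×8 planes where exhaustive enumeration is exact; wavelet contracts
are checked on 100 random planes.

## Known limitations

- Frame-level stratified folding is the default; frames from one
  subject can land in train and test folds. Patient-grouped folding is
  available via the `groups` argument when patient ids exist.
- The baseline's IDM/contrast/covariance definitions for 1-D spectra
  are this package's documented interpretation (bin-distance from the
  mode; second central moment; cross moment against the V-channel
  spectrum) — reproducible here, but not guaranteed byte-compatible
  with other implementations of the same scheme.
- Descriptor values enter the moments unstandardized; measures with
  larger dynamic range (e.g. entropy vs. ASM) dominate raw moment
  magnitudes. PCA after z-scoring compensates at the classifier, but
  the raw vector is scale-inhomogeneous by design.
- The 500-epoch constant-rate MLP can oscillate on tiny fold sizes;
  with the study sizes above this was not observed, but very small
  corpora may need a smaller learning rate.
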