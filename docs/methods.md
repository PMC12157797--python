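# Methods

## Overview

`colorqr` implements a smartphone-style colorimetric readout pipeline for
free chlorine in drinking water.  A *back-compatible Color QR code* — a
standard QR symbol in which selected data modules are replaced by colored
reference patches — is photographed next to a reacted assay (a bromothymol
blue test strip, or a DPD cuvette).  The embedded patches serve two roles at
once: the symbol provides geometry (localization, perspective rectification,
an identifier selecting the chart layout) and the patches provide a
color-constancy chart from which a scene-specific color correction is
fitted.  Corrected assay colors are then converted to a three-class chlorine
verdict and, in the acceptable range, a ppm estimate.

## Color QR carrier

Symbols are QR model 2, byte mode, versions 1–10 (side length `17 + 4v`
modules), with Reed–Solomon error correction over GF(256) and standard mask
selection.  Version 3 (29×29) carries the default payload, a URL plus
fragment identifier.  The default error-correction level is Q: version 3-Q
holds 32 payload bytes, which fits the 29-byte default payload while leaving
2×18 correction codewords; level H (24 bytes at version 3) is selectable for
shorter payloads.

Back-compatibility is structural rather than statistical: each palette
entry is assigned only to a module whose binary value matches the entry's
side of the mid-gray threshold (Rec.601 luminance 0.299R + 0.587G + 0.114B
compared to 128).  Placements are chosen greedily, row-major over the data
region.  Grayscale binarization of a rendered chart therefore reproduces the
binary module matrix *exactly*, so any standard decoder reads the payload
without spending error-correction budget; the EC margin remains available
for capture noise.  Both shipped palettes have 24 entries: a 6-step neutral
ramp, an 8-step dye ramp (blue for BTB, pink for DPD), and 10 saturated
anchors so the correction is constrained in all of RGB space.  The numeric
palette values are package constants, not measured chart colors.

## Detection and rectification

Scenes are binarized with Otsu's threshold and scanned row-wise for the
1:1:3:1:1 dark/light run signature of the finder patterns, with a vertical
cross-check; candidate centers are clustered and the three strongest
clusters retained.  The corner finder is the one whose vertex angle is
closest to 90°, fixing the TL/TR/BL ordering.  The symbol version is
estimated from the finder spacing in module units; the bottom-right
alignment pattern is refined by template correlation around its affine
prediction, and a projective transform is estimated from the four
correspondences (falling back to the affine map for version 1 or when the
alignment refinement fails).  The module grid is sampled at cell centers and
decoded by the package's QR codec, which reads the format information,
unmasks, de-interleaves and Reed–Solomon-corrects each block.

Rectification composes the detected image→module transform with the layout's
module→canvas scaling and inverse-warps the scene (bilinear, white fill)
into a canonical frame in which the symbol occupies a fixed square and the
assay hardware search window lies at a fixed region to its right.  Only
planar projective distortion is modelled.

## Color correction

From the n = 24 pairs (captured patch color c_i, reference color r_i) a
thin-plate spline is fitted per output channel:

    f_k(c) = a0_k + a_k·c + Σ_i w_ik φ(‖c − c_i‖),   φ(r) = r² ln r

by solving the block system [[K + λI, P], [Pᵀ, 0]]·[w; a] = [y; 0] with
K_ij = φ(‖c_i − c_j‖) and P_i = (1, c_iᵀ).  At λ = 0 (the default) the map
interpolates the chart exactly; λ > 0 trades interpolation for smoothness.
The polyharmonic kernel φ(r) = r is selectable.  Colors are raw 8-bit sRGB
without linearization.  Numerical note: at 8-bit color scale the saddle
system's condition number reaches ~1e13, so the solve is followed by two
steps of iterative refinement, which restores near-machine accuracy; the
side conditions Σw = 0, Σ w_i c_i = 0 then hold to ~1e-10.  Degenerate
charts (captured colors affinely coplanar) and n < 8 are rejected.

Measurement order is mean-then-correct: the ROI's mean color is passed
through the map once; whole-image pixel-wise correction exists for display
only.  A diagonal (von Kries) white-balance baseline fitted on the white
patch is provided for comparison; it equals the spline under purely diagonal
illuminant distortion and falls behind as soon as a non-linearity (e.g. the
generator's optional gamma 2.2) enters the capture.

## ROI extraction

* **Strip pad** — multi-scale normalized cross-correlation of a structural
  pad template (dark frame, neutral interior) over the hardware window,
  scales {0.75, 1.0, 1.25, 1.5}, acceptance threshold 0.5.  NCC is invariant
  to affine intensity changes, so the frame structure dominates while the
  pad's concentration-dependent interior color does not.  The detector is a
  pluggable stand-in for an appearance-trained cascade with the same
  box+score contract.  The measured region is the detected box shrunk by
  1.6× per axis, keeping it inside the ink window under a few pixels of
  detection offset.
* **Cuvette** — the face is painted black at its edges, so it is found as
  the largest 4-corner contour of the dark mask (fixed threshold 80, which
  tolerates global gain 0.5–1.5) whose bounding-box aspect ratio is within
  ±25% of 3.0 (face 3.3 cm × 1.1 cm) and whose area is plausible.  Corner
  counting merges near-collinear Douglas–Peucker vertices, since the
  polygon simplification retains its arbitrary starting point even when it
  lies mid-edge.  The measured region is a centered inner ROI 5× smaller per
  axis (25× by area).

ROI color is the per-channel mean over the box; the per-channel standard
deviation is kept as a dispersion diagnostic.

## Colorimetric models

Corrected ROI colors become six features: R, G, B and hexcone H (degrees,
0 for achromatic colors), L, S.  Classes follow the manufacturers'
half-open intervals: low C < 0.2, acceptable 0.2 ≤ C < 0.9 (BTB) or
0.2 ≤ C < 1.1 (DPD), excess above.  The classifier is an RBF SVC (C = 1,
gamma = 'scale') on standardized features — all six for BTB, (G, B) for DPD
— trained on an 80/20 stratified split (default split seed 42, stored with
the model).  Models persist to JSON (scaler, support coefficients,
intercepts, regression block, bounds, seed); prediction from a deserialized
model reconstructs the one-vs-one decision functions directly and is
test-verified to match the in-memory SVC exactly.

The ppm estimate is produced only for the acceptable class:

* **BTB** — OLS of C on ln(Rc) (corrected red channel), with 95% confidence
  and prediction intervals from the OLS machinery.
* **DPD** — OLS of C on the first principal component of centered
  (ln G, ln B), loadings sign-fixed so the score increases with C.

Regression output falling outside the acceptable interval is clipped to the
interval edges and flagged, recording the hazard of samples passed to the
regression by a misclassification.

## Synthetic data

The generator emulates the acquisition protocol: illuminants on the
Planckian locus from 2500 to 6500 K in 500 K steps, hand-held perspective
jitter, and sensor noise; concentrations span 0–8.4 ppm.

* **BTB response** — R = exp((b − C)/|m|) with m = −0.64, b = 3.3, the
  exact inverse of the calibration line, so calibration recovery is a
  closed-loop check; G = 200 − 25C and B = 150 − 10C decay linearly.
* **DPD response** — ln G and ln B decay linearly (G = 230·e^(−0.25C),
  B = 235·e^(−0.35C)) with R pinned at 230, giving a near-neutral
  zero-analyte color and a pink reacted color.
* **Illuminant** — diagonal von Kries gains from a published polynomial
  blackbody approximation, normalized per channel by the 6500 K illuminant
  so the reference condition is exactly neutral (the chart's stored
  reference values are defined at 6500 K, so green-normalized gains would
  leave a spurious ~2% cast at the reference point itself).
* **Scene** — canonical canvas (symbol at the layout square, hardware in the
  window with ±20 px positional jitter), per-pixel gains, optional gamma
  2.2 (off by default; it is the non-linearity that separates the spline
  from white balance), projective warp with corner jitter bounded by
  `warp_jitter` × canvas size (default 0.03), additive Gaussian noise
  (default σ = 2), quantization to 8 bits.  One seeded generator drives
  everything; identical seeds give byte-identical images.

What the generator does *not* model: demosaicing, lens distortion, chromatic
aberration, device tone curves, specular reflections, print/substrate
effects, shadows and spatially varying illumination, and the saturation
channel's non-monotone behavior at high concentrations (any such effect here
emerges only from clipping).  Passing tests therefore demonstrate the
pipeline's correctness and its illuminant/perspective robustness under these
idealized captures, not field performance on real photographs.

## Problem sizes and reproducibility

The end-to-end evaluation uses 200 scenes (stratified concentrations,
illuminant grid swept cyclically, σ = 2, jitter 0.03), chosen as a
desk-scale analogue of the acquisition campaign; it trains the classifier
80/20 and fits the medium-range regression on the pipeline's own features.
Calibration recovery uses n = 100 medium-range samples at σ = 2.  All
randomness flows from explicit seeds; there is no hidden global RNG state.

## Known limitations

* Only byte-mode QR payloads and symbol versions 1–10 are supported.
* Detection assumes one symbol per scene and planar geometry; curved or
  heavily occluded charts are out of scope.
* The correction is fitted in RGB on 8-bit values; no attempt is made at
  spectral or physically based color science.
* DPD prediction intervals are not propagated through the PCA step (the
  point estimate and R² are reported).
* The palette colors and DPD channel coefficients are synthetic defaults,
  not measurements of the commercial products.
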