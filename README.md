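# colorqr

Smartphone-style colorimetric readout of free-chlorine water tests using
**back-compatible Color QR codes**.

Free chlorine (FC) keeps drinking water safe, but quantifying it usually
needs a bench colorimeter.  Two cheap visual tests exist — a bromothymol
blue (BTB) strip that turns blue, and a DPD cuvette assay that turns pink —
yet reading them by eye is subjective and, from a photo, hopeless: the
apparent color depends on the light and the camera.  `colorqr` solves this
by printing the assay next to a QR code whose data modules double as dozens
of colorimetric reference patches.  A standard decoder still reads the
payload (the colors are placed so grayscale binarization is unchanged),
while the patches give every photograph its own color-constancy chart.

The pipeline, per image:

1. **Locate & decode** the QR symbol (finder-pattern scan, projective
   rectification, in-package QR codec).
2. **Sample** the embedded palette and fit a **thin-plate-spline color
   correction** from captured → reference colors:
   `f_k(c) = a0_k + a_k·c + Σ_i w_ik φ(‖c − c_i‖)`, `φ(r) = r² ln r` —
   a non-linear map that outperforms diagonal white balance.
3. **Extract the ROI**: the strip's ink pad (multi-scale normalized
   cross-correlation) or the cuvette's black-bordered face (contour +
   aspect gate) with a centered inner ROI 25× smaller.
4. **Model**: six features (R, G, B, H, L, S) feed an SVM 3-class verdict —
   *low* (< 0.2 ppm), *acceptable*, *excess* (≥ 0.9 ppm BTB / 1.1 ppm DPD) —
   and, inside the acceptable range, a regression `C = m·ln(Rc) + b` (BTB,
   corrected red channel) or OLS on PC1 of (ln G, ln B) (DPD) yields ppm.

No image dataset ships with the underlying assays, so the package includes
a fully labelled synthetic generator (dye responses, Planckian illuminants
2500–6500 K, perspective jitter, sensor noise) that exercises every stage
end to end.

## Worked example

```
$ colorqr generate --payload "http://diesmar.com/#AdDk" --ec H --chemistry BTB --out qr.png
wrote qr.png (370x370, 24 reference patches)

$ colorqr simulate --n 30 --chemistry BTB --seed 4 --out ds30
wrote 30 scenes + truth.csv to ds30

$ colorqr train --dataset ds30 --chemistry BTB --out model.json
trained on 30 scenes: train acc 1.000, held-out acc 1.000; model -> model.json

$ colorqr analyze --image ds30/scene_0004.png --model model.json --chemistry BTB
qr_id: n87RXv6i3  correction RMSE: 0.00
class: acceptable  ppm: 0.62
```

The last command read one photograph: it decoded the chart identifier
(`n87RXv6i3`), fitted the spline correction (chart residual 0.00 — the
illuminant was fully cancelled), classified the strip in the acceptable
0.2–0.9 ppm band and estimated 0.62 ppm from the corrected red channel.

The same flow in Python:

```python
import colorqr as cq
from colorqr.synth import default_spec, render_scene

spec = cq.synth.default_spec("BTB")
scene = render_scene(spec=spec, chemistry="BTB", concentration=0.5,
                     cct=3000, warp_jitter=0.03, noise_sigma=2.0, seed=7)
result = cq.analyze_scene(scene.image, spec, "BTB")
print(result.features.Rc)        # corrected red channel, ~79.4 at 0.5 ppm
```

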