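# uripad

Digital readout for paper-based colorimetric uric acid assays.

Urinary uric acid is a low-cost biomarker for renal dysfunction and
hyperuricemia. A paper-based analytical device (PAD) detects it without lab
instrumentation: filter paper treated with potassium ferricyanide receives a
diluted urine sample, ferric chloride is added, and uric acid drives the
formation of Prussian blue — the more analyte, the darker the spot. `uripad`
turns a photograph or scan of that spot into a concentration estimate with a
clinical classification, and analyzes the kinetics of the color-forming
reaction itself.

## What it computes

**Color scale.** Each pixel's gray value is the channel mean,
`gray = (R + G + B) / 3`, on the 0 (black) – 255 (white) scale. Because the
signal darkens with concentration, analysis uses the complementary CMY gray,
`CMY = 255 − RGB`, on which higher = darker = more uric acid.

**Calibration.** The spot intensity saturates with concentration; the
calibration model is an exponential saturation

```
G(C) = G0 + (Gmax − G0) · (1 − exp(−C/τ))
```

with baseline `G0`, asymptote `Gmax`, and scale `τ` (ppm), fitted to
replicate standards by nonlinear least squares. The operational saturation
concentration is `C_sat95 = τ·ln 20`, where the curve reaches 95% of its
span (≈500 ppm under the default truth parameters); inversion censors there,
returning the bound with an `above_saturation` flag. An additive linear
temperature model (`gray = intercept + slope·T`, slope ≈ 0.56 gray/°C over
25–50 °C) corrects for the thermal drift of the paper substrate.

**Readout pipeline** (one image → one answer): load image → RGB gray → CMY
gray → auto-detect the spot disc (background median + 3×MAD threshold,
largest component, 15% radial shrink against coffee-ring edges) → single-pass
Tukey 1.5×IQR outlier screen → mean CMY gray → inverse calibration →
multiply by the urine dilution factor (default 2X) → classify against the
published 300–700 ppm acceptable range.

**Kinetics.** A video of the forming spot, converted to frames (30 fps),
gives x(t) = CMY intensity. The three classical integrated rate laws are
linearized —

```
zero order:    x = K·t
first order:   2.303·log10(a − x) = −K·t + c
second order:  1/(a − x) = K·t + c
```

— each fitted by least squares over the pre-completion window (x ≤ 0.95·a),
with the asymptote `a` grid-searched to maximize linearity. The order with
the best straight line wins; for first order, K = −ln 10 × slope (s⁻¹).
Prussian-blue formation follows first-order kinetics with K ≈ 0.64 s⁻¹.

## Worked example

No public image dataset exists for this assay, so the package ships a
synthetic generator whose defaults encode the study conditions
(saturation at 500 ppm, K = 0.64 s⁻¹, gray 82→96 over 25→50 °C):

```bash
uripad simulate standards --seed 1 --out fixtures
uripad calibrate fixtures/standards_seed1.csv --out curve.json
#   r_squared = 1.00000; C_sat95 = 500.0 ppm

uripad simulate spot --seed 2 --concentration 275 --out fixtures
uripad quantify fixtures/spot_275ppm_seed2.png --calibration curve.json
#   uric acid 550 ppm (+/- 1) -- within acceptable limit
#   [mean CMY gray 141.2, 8176 px, 199 outliers removed]

uripad simulate kinetics --seed 3 --out fixtures
uripad kinetics fixtures/kinetics_seed3.csv
#   best_order: 1   K_best: 0.627   a: 150.4
```

The 275-ppm spot was applied at the default 2X dilution, so the undiluted
urine reads 550 ppm — inside the 300–700 ppm acceptable band. The kinetics
run recovers first-order behavior with K within 2% of the generating
0.64 s⁻¹. Add `--json` (quantify) for the machine-readable result; every
command seeds its randomness explicitly.

The same API is available from Python:

```python
import uripad as up

truth = up.TruthBundle()                      # study-condition ground truth
curve = up.fit_calibration(up.gen_standards(range(0, 1001, 50), truth, seed=1))
result = up.quantify_image("spot.png", curve, dilution_factor=2)
print(result.report_line())
```

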