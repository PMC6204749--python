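# Methods

This note documents the models, the numerical choices, and the synthetic
data underlying `uripad`, and what the tests do and do not demonstrate.

## Color representation

Pixels are 8-bit RGB; the per-pixel gray value is the unweighted channel
mean `(R + G + B)/3`, kept as an exact fraction — rounding to integers
happens only at display, never inside the pipeline. Quantification operates
on the CMY gray value `255 − gray`, so intensity increases with the darkness
of the Prussian-blue product and hence with analyte concentration. The
scheme is carried as a tag on every gray matrix and a conversion applied
twice is an error rather than a silent corruption.

16-bit rasters are mapped to the 8-bit contract by integer division by 257
(65535 → 255 exactly); alpha channels are dropped; single-channel images are
promoted to three identical channels. Images smaller than 16×16 px are
rejected as too small for ROI analysis.

## Spot ROI detection

The paper spot is found automatically: the outer 10% frame of the image is
taken as background, pixels above `median + 3×MAD` of that frame are
foreground, the largest 8-connected component is the spot, and the enclosing
circle (centroid center, maximum pixel distance radius) is shrunk by a 15%
radial margin. The margin discards the rim, where drying concentrates
solute (the coffee-ring effect) and where the disc boundary mixes spot and
paper pixels. Membership is decided by pixel-center distance with row-major,
0-based coordinates. Failure modes are explicit: no pixel above threshold
("no spot detected") and a component covering more than half the image
border ("spot not separable from background"). Real devices photographed at
an angle, under uneven illumination, or with several spots per frame are out
of scope; the detector assumes one roughly circular spot on lighter paper.

## Outlier screening and the mean

Pixel vectors are screened once with Tukey fences: values outside
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` (linear-interpolation quartiles) are removed,
and the arithmetic mean of the survivors is the spot's gray value. The rule
is parameter-free and robust for the unimodal pixel distributions a spot
produces; it is *not* idempotent for arbitrary pathological inputs (a second
pass after removing a value can shrink the IQR to zero on tiny discrete
vectors), so idempotence is verified on representative spot data rather than
claimed universally. At least 5 values are required.

## Calibration model

Concentration–intensity data saturate, so the curve is

    G(C) = G0 + (Gmax − G0)(1 − e^(−C/τ)),

chosen for being three-parameter, strictly increasing, and analytically
invertible. Fitting is plain (unweighted) nonlinear least squares over all
replicate points, initialized at G0 = mean gray of the lowest standard,
Gmax = largest mean gray, τ = half the largest concentration, with 1e-8
parameter tolerance. Preconditions: ≥4 distinct concentrations including an
anchor at each end (≤50 ppm and ≥400 ppm), since baseline and plateau are
otherwise unidentifiable. Grossly inverted standards (mean grays
monotonically decreasing over the lower half of the range) are rejected.

The reported saturation point is `C_sat95 = τ·ln 20`, where the curve covers
95% of its span. Inversion:

* gray ≥ 95% of span → return `(C_sat95, above_saturation)`: the estimate is
  a lower bound, because past saturation the signal does not discriminate;
* G0 ≤ gray < 95% of span → exact inverse `−τ·ln(1 − (gray−G0)/span)`;
* G0 − 2·residual_sd < gray < G0 → clamp to 0 ppm (blank-level noise);
* anything lower → "signal below blank" error.

The interval half-width is first-order error propagation (delta method):
`z(0.95) · residual_sd / |dG/dC|` evaluated at the estimate, scaled by the
dilution factor; `z(0.95) = 1.6449`. This treats the calibration residual
SD as the dominant uncertainty and ignores parameter covariance — adequate
for a screening device, not a metrological uncertainty budget.

Weighted fits, IUPAC LOD/LOQ, and humidity effects are deliberately out of
scope.

## Temperature correction

Gray value drifts up with temperature (paper yellowing); over 25–50 °C the
drift is well described by a line. The model is OLS `gray = intercept +
slope·T` with reference temperature 25 °C (room temperature, where
calibrations are made); correction subtracts `slope·(T − T_ref)` and clamps
to [0, 255] with a logged warning. A temperature-specific calibration per
temperature would be the rigorous alternative and is not implemented. The
default truth slope is (96 − 82)/(50 − 25) = 0.56 gray/°C.

## Kinetics

Prussian-blue formation is summarized by intensity x(t) with asymptote `a`
(the limiting intensity, proxy for initial reactant). Candidate rate laws
are compared through their linearizations — x vs t (order 0), log10(a−x) vs
t (order 1), 1/(a−x) vs t (order 2) — each fitted by OLS, the best r²
winning. For order 1, K = −ln 10 × slope; the classical "2.303" factor is
the rounded ln 10 and is used here at full precision so exact data yield
exact K.

Two numerical choices matter:

* **Fitting window.** Only points with x ≤ 0.95·a enter a fit (≈ the first
  three half-lives). Past that, a − x has decayed below any realistic noise
  floor, log10(a−x) and 1/(a−x) amplify noise asymmetrically, and OLS drags
  the slope toward zero — on default-noise simulations the full-series fit
  underestimates K by ~20%, while the windowed fit is unbiased within ~3%.
  The window falls back to all points when fewer than 5 survive.
* **Asymptote estimation.** `a` is not observable in a finite recording; it
  is grid-searched over (max x, 1.5·max x] in 200 steps to maximize the
  linearized r², ties toward smaller a. In order selection, orders 1 and 2
  each use the asymptote tuned on their own axis — a first-order-tuned `a`
  systematically handicaps the 1/(a−x) fit on genuinely second-order data
  and can flip the selection.

Degenerate inputs are rejected explicitly: all-zero series ("no product
formation"), constant series (no curvature; float-exact `ptp == 0` test, so
rounding noise cannot masquerade as signal), zero time variance. Series
need ≥10 samples; frame sequences convert to time as `index/fps` (default
30 fps). Missing frames are expected to be dropped upstream, not
interpolated.

## Clinical remark

Estimates (after multiplying by the dilution factor, default 2X for the
standard 2X-diluted sample; 2X–5X supported) are classified against the
published urinary acceptable range: `< 300` ppm below range, `300–700` ppm
within acceptable limit (boundaries inclusive), `> 700` ppm above. The ppm
(mg/L) concentration scale and the mg/day excretion scale found in the
hyperuricemia literature are related by 24-h urine volume, which this
package does not model; the classification follows the concentration-scale
convention.

## Synthetic data: what it emulates and what it does not

There is no public image corpus for this assay, so every pipeline stage is
exercised against a generator with explicit ground truth. Defaults are the
study conditions:

| parameter | default | anchor |
|---|---|---|
| calibration G0, Gmax | 20, 170 gray | magnitudes chosen; span arbitrary |
| calibration τ | 500/ln 20 ≈ 166.9 ppm | saturation at 500 ppm |
| kinetics K, a | 0.64 s⁻¹, 150 gray | K printed; a chosen |
| sampling | 30 fps, 10 s | 30 fps printed; duration chosen |
| temperature anchors | (25 °C, 82), (50 °C, 96) gray | printed endpoints |
| pixel noise SD | 2 gray | chosen, realistic scanner noise |
| series noise SD | 1 gray | chosen |
| outliers | 2% of disc pixels, +60 gray | chosen, dust/ring artifacts |
| standards | 0–1000 ppm step 50, 4 replicates | n = 4 replicates printed |

Replicate-level noise on standards is `pixel_sd/√1000`, the residual scatter
after averaging a ~1000-pixel spot. Spot images are neutral gray (R=G=B):
chromatic realism would not change any gray value and is omitted. Generators
are pure functions of (parameters, seed); noiseless variants come from
switching the noise fields off.

Passing tests therefore demonstrate correctness of the *algorithms* under
the stated noise model — they do not validate robustness to perspective,
illumination gradients, white-balance drift, reagent batch effects, or real
urine matrix variation, none of which the generator simulates.

## Problem sizes

Default test and reproduction workloads are deliberately desk-scale: 200×200
px spot images (~8 000 disc pixels), 21-concentration standard curves with 4
replicates, 300-sample kinetics series, and 5–20 simulation seeds per
recovery check — enough for the standard errors of the recovered parameters
to sit well inside the asserted tolerances.
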