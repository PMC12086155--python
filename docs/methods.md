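# Methods

This note documents the models, defaults and design choices behind
`leafcolor`, and what its synthetic-data tests do and do not demonstrate
about real photographs.

## Image front end

**Decoding.** Images (PNG/JPEG/GIF) are decoded with Pillow to 8-bit RGB;
grayscale sources replicate the single channel, alpha is discarded. The
internal convention is a row-major `(height, width, 3)` uint8 array,
origin top-left; no geometric quantity is ever reported, so the
convention is purely internal.

**Palette reduction.** `quantize_palette` emulates conversion to a
256-color GIF with Pillow's median-cut quantizer and dithering disabled.
Dithering would scatter mixed colors through the per-color histogram and
corrupt the codeset-mode dark-green count, so it is never used. If an
image already has no more colors than the budget it is returned
bit-identically — palette reduction is then a no-op, not a re-encoding.
The quantization algorithm itself is a free choice (any ≤256-color
reduction is consistent with a GIF workflow); median-cut is the
conventional one.

**Segmentation.** Two deliberately simple rules, selectable per protocol:
`black-background` marks a pixel vegetation when its Rec.601 luma exceeds
a threshold (default 20 on the 0–255 scale), for plants photographed on
a black cloth; `excess-green` uses 2G − R − B > threshold (default 20),
for plants among soil and pots. Real studies often delegate this step to
an external tool, so a precomputed mask (single-channel PNG, nonzero =
vegetation) bypasses segmentation entirely and decouples index
computation from segmentation quality. Multi-plant photos are handled by
per-plant crop boxes (`crop_tiles`); whether multi-plant scenes should be
analyzed per plant or per photo before correlating with per-plant weight
is genuinely ambiguous in practice — the pipeline supports per-tile
analysis and leaves the choice to the user.

**No color correction.** Images are treated as white-balanced as shot.
Color-chart calibration would improve cross-device comparability but is a
separate preprocessing problem; the agreement analysis below is the
package's answer to device differences.

## Color indices

Only *green* pixels — G strictly greater than both R and B, ties
excluded — enter the two indices. Both are computed over the green-pixel
histogram:

* normalized intensity: count-weighted mean of (R/255 + G/255 + B/255)/3.
  Normalizing before or after averaging is equivalent by linearity; the
  implementation divides per channel first, fixed for bit-reproducibility.
* dark-green proportion: `threshold` mode counts green pixels with
  G ≤ 85 (the dark band of the dark/medium/light split at 85/170);
  `codeset` mode counts only the four exact codes (0,43,0), (0,85,0),
  (51,85,0), (51,85,51), which are the dark codes a 256-color quantizer
  typically produces for lettuce canopies.

The two dark-green definitions do not coincide: the codeset is a strict
subset of the dark band, so codeset ≤ threshold holds for every
histogram (a property test asserts this). `threshold` is the default
because it is robust to which exact palette a quantizer emits; `codeset`
is provided for fidelity to workflows defined in terms of specific
palette codes. Similarly, the denominator of both indices is the green
pixel count, not all segmented vegetation pixels; computing over all
segmented pixels is possible by skipping `filter_green`, and the choice
is documented because published workflows describe both readings.
Reported precision is three decimals for both indices.

Degenerate input — no pixel passing the green rule — raises
`NoGreenPixelsError` rather than returning 0/0.

## Device agreement

`BlandAltman(x, y).fit()` computes, for d = y − x over n complete pairs
(pairs with a missing side are dropped and counted): m = mean(d), s =
sample standard deviation (n − 1 denominator — the conventional choice;
only "the standard deviation" is usually stated), 95% LOA m ± 1.96 s and
95% CI m ± 1.96 s/√n. z is fixed at 1.96 rather than a t-quantile, and
no confidence intervals around the LOA themselves are computed; both
choices match the way these intervals are typically printed in crop
studies. Monte-Carlo tests confirm the consequences: CI coverage of a
known bias is ≈ 95% (slightly below at n = 50, where a t-quantile would
be exact), and the within-LOA fraction converges to ≈ 0.95.

The sign convention is x = device A (reference phone), y = device B, so
a positive m means device B reads higher. With no ground truth to prefer
either device, per-plant values are averaged (`average_metrics`) before
the growth statistics.

`reconstruct_ci_from_loa` inverts the printed formulas: the LOA midpoint
is m, its half-width is 1.96 s, and dividing by √n gives the CI
half-width. It is exact algebra, useful for checking published agreement
tables when raw pairs are unavailable.

## Growth statistics

One-way ANOVA (scipy) compares any response across the four treatments;
pairwise contrasts are Welch t-tests, unadjusted by default because
published pairwise p-values in this setting are typically raw (Holm
adjustment is a flag). Leaf counts are analyzed with the same machinery,
treated as continuous — a pragmatic convention, not a claim that a count
model would not fit better.

The weight–color relationship is an ANCOVA fitted by statsmodels OLS:
`fresh_weight ~ C(treatment) + predictor`, fixed intercept per treatment,
common slope. A "mixed-effects" label is sometimes attached to this
analysis, but with one endpoint observation per plant and treatment as
the only grouping, a random plant effect is unidentifiable — the fixed-
intercept ANCOVA is the identifiable form. For data pooled across
experiments, `method="mixed"` fits a random intercept per experiment
(statsmodels MixedLM) on top of the treatment fixed effects. Two R²
values are emitted rather than guessing which variant a given report
used: `r_squared` is the marginal squared correlation of the predictor
alone with fresh weight, `r_squared_full` the coefficient of
determination of the full fit (for the mixed variant, the squared
correlation of fitted and observed values). Rank deficiency — a constant
predictor, or a single treatment — raises `ModelError` naming the
deficient term.

## Synthetic study generator

The generator defines the study conditions under which the pipeline is
tested; its defaults emulate a small greenhouse fertilizer trial:

| parameter | default | meaning |
|---|---|---|
| treatments | C, LV, N, I | control and three fertilizers |
| n_per_treatment | 8 | plants per treatment (32 total) |
| dark_mean | C 0.25, I 0.30, LV 0.40, N 0.55 | treatment mean dark-green proportion |
| dark_sd | 0.08 | between-plant color spread |
| intensity link | 0.35 − 0.35·dark + N(0, 0.02) | negative color–intensity association |
| weight_intercepts (g) | C 10, I 12, LV 20, N 25 | treatment baselines |
| beta | 150 g per unit dark proportion | weight–color slope |
| sigma | 8 g | weight noise |
| leaf_mean | 10–11.5 | Poisson leaf counts, weak treatment effect |

These place intensity ≈ 0.1–0.4, dark proportion ≈ 0.1–0.8 and fresh
weight ≈ 20–150 g — the ranges a smartphone lettuce trial actually
yields — and encode the expected qualitative pattern: nitrogen darkens
the canopy and raises weight; intensity and weight are negatively
related, dark proportion and weight positively.

Canopy images are elliptical leaf blobs on a noisy dark (or soil-colored)
background; each leaf pixel draws an exact palette color from a
categorical mixture, so the emitted mask and metrics are exact ground
truth. Geometry is decorative — only the color distribution feeds the
statistics — and no lighting, shadow, overlap-occlusion or JPEG-artifact
effects are modeled. Devices are modeled two ways, because camera
differences in the field are observed only qualitatively: image-level as
a chroma gain about the per-pixel mean plus an additive intensity shift
(a "more saturated" renderer), metric-level as an additive bias plus
independent normal noise on the index scale. All generators are
deterministic in their seed and use documented distributions only
(uniform placement, normal noise, categorical mixture, Poisson counts).

**What passing tests show — and don't.** Green tests demonstrate that the
formulas are implemented exactly (oracle equivalence against a per-pixel
loop), that the intervals are calibrated under their own normality
assumptions, and that the estimation pipeline recovers generating
parameters at realistic effect sizes and sample sizes. They do not
demonstrate segmentation robustness on real soil/shadow backgrounds,
illumination invariance, or that real cameras differ by a constant bias —
real device differences are scene-dependent in ways the forward model
deliberately simplifies.

## Numerical and testing choices

* Histogram statistics are exact integer/rational arithmetic in floating
  point; oracle-equivalence tests assert agreement with a brute-force
  per-pixel loop to 1e-12.
* Monte-Carlo suite sizes (1000 agreement replicates at n = 50, 500
  slope-recovery experiments, 60–100 directional seeds, 100 random
  64×64 oracle images) keep the full test run near ten seconds while
  leaving tolerance bands at roughly three Monte-Carlo standard
  deviations: ±2% for CI coverage at 1000 replicates, ±3% at 500, ±0.01
  for the large-n LOA fraction.
* Simulated studies in tests use 96–128 px images; image size only
  scales the per-image pixel count (binomial noise on realized color
  fractions shrinks as pixel count grows), not the structure of any
  statistic.
* The CLI exits nonzero when any per-image analysis in a batch failed,
  after logging and skipping the offending file; missing directories or
  metadata fail fast before any output is written.

## Known limitations

* Segmentation thresholds are global constants per run; scenes with
  bright soil or deep shadow need an external mask.
* The codeset dark-green mode is tied to one specific quantizer palette;
  a different quantizer can legitimately produce near-identical images
  whose codeset proportion differs (this is exactly why threshold mode
  is the default).
* The ANCOVA assumes a common slope across treatments; no interaction
  term is offered.
* Agreement analysis models a constant device offset; proportional-bias
  (regression-based) Bland-Altman variants and repeated-measures LOA are
  out of scope.
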