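# Methods

This note documents the models and procedures implemented in `amberscan`,
the choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Segmentation pipeline

The segmenter composes fixed primitive operators in two phases.

**Inflorescence isolation.** The image is converted to CIELAB (D65, with the
common 8-bit encoding L = L\*·255/100, a/b offset by +128, kept as floats so
no quantization error enters downstream scoring). A global threshold at
L = 41 separates plant matter from the dark background — valid because the
intended imagery is copy-stand photography under fixed illumination. A 27×27
opening removes thin protrusions and speckle, a 41×41 dilation restores a
safety margin, and the minimum enclosing circle of the result defines the
region of interest; everything outside is set to black, and the frame is
cropped to the circle's bounding box. Pixels blacked out this way are
excluded from all stigma statistics.

**Stigma isolation.** Within the crop: the CMYK K-channel (naive device
conversion, K = 255 − max(R,G,B)) is median-blurred at 11 px and adaptively
thresholded against a Gaussian-weighted local mean (window 11, offset 2 —
the offset is not fixed by the design and is exposed in config). In
parallel, a max-RGB white balance (per-channel global rescale so each
channel's maximum becomes 255; a per-pixel-max variant is available via
`maxrgb_mode`) feeds a blue-channel threshold at 111 that responds to
white/pale structures. The AND of these two masks, closed at 5×5 and XOR-ed
with the blue-gate mask, cancels small bright speckle (trichome glands)
that both gates agree on; an inverted K-threshold at 110 then rescues all
large bright structures (the stigmas), and the OR of the two branches is
the final mask, intersected with the circle so the count invariants hold.

Two published descriptions of the branch order disagree (one lists
AND→close→XOR→OR, the other omits the XOR); the running-text order is the
default and the `caption_variant` flag switches to the shorter one. The
"copy of the maxRGB binary image" used as the XOR operand is interpreted as
the blue-thresholded max-RGB mask — the only max-RGB-derived binary defined
at that point.

All windowed operators use edge-repeat reflection at borders; morphology
uses square all-ones structuring elements (dilation/erosion as separable
running max/min, with constant padding 0/1 so blobs touching the frame are
preserved); `close = erode∘dilate` and `open = dilate∘erode` by definition.

## Amber score

The yellowness index maps a pixel's (L\*, b\*) to
`100 · clamp(t, 0, 1)` where `t` is the scalar projection onto the segment
from the white anchor to the yellow anchor. Both anchors are obtained by
passing the anchor colors — sRGB (255,255,255) and (255,255,0) — through
the same sRGB→CIELAB conversion used on image pixels, so the endpoints score
exactly 0 and 100 by construction. Clamping (rather than exclusion) is
applied to pixels that project outside the segment, e.g. bluish pixels with
negative b\*. The projection construction is the unique linear index that
guarantees the 0/100 anchors; alternatives that weight lightness differently
would need external calibration data to pin down.

The inflorescence's score is the arithmetic mean over the stigma mask.
Stage assignment is nearest-center against the reference scores
(28, 37, 54, 65) — population means of the automated score within each
manually assessed stage — with midpoint ties resolved to the lower stage
(the more conservative, earlier-harvest call). The references are
configurable per genotype; no published decision boundaries exist, so
nearest-center is a convention of this package, not a claim about the
original scoring.

## Cannabinoid metrics

TCC is the exact 14-term sum over
CBDA, THCA, CBD, THC, CBC, CBN, CBDVA, CBDV, CBGA, CBG, THCV, THCVA, CBNA,
CBCA in mg/g dry weight; a missing analyte is a hard error because a
partial sum would silently change the statistic's meaning.
TCY = TCC × gross inflorescence weight / 1000 (grams of cannabinoid).
Chemovar classes use the CBDA:THCA ratio with strict outer inequalities, so
the exact 3:1 and 1:3 boundaries fall in the even-ratio class. Peak-stage
detection is an argmax over the four stages with ties resolved to the
earliest stage (earlier harvest is operationally preferable; configurable).
Replicates within a (genotype, stage) cell are not averaged silently — they
are rejected as duplicates, since the intended design has exactly one
inflorescence per cell.

## Chemometrics

Preprocessing is an ordered chain of per-spectrum operators — polynomial
detrend (default order 1), Savitzky–Golay derivative (polynomial 2,
derivative 2, 5-point window; ends handled by polynomial interpolation so
the derivative is exact for polynomials, matching common toolbox behavior),
SNV — followed by mean centering, the only step that pools over samples.
Centering means are fitted on calibration rows only and refit inside every
cross-validation fold; the per-spectrum steps cannot leak by construction.
The chain order (scatter correction after the derivative, centering last)
is configurable through the compact step string, e.g.
`"detrend:1,savgol:2:2:5,snv,mc"`.

The calibration/validation split is Kennard–Stone (classic max–min
Euclidean selection, initialized at the two most distant samples, ties to
the lowest index) at a 75/25 ratio, run on the row-wise-preprocessed
spectra — centering is excluded there because it would require pooled
statistics before any split exists. Cross-validation is venetian blinds:
sample *i* belongs to fold `(i // thickness) mod splits`, default 10 splits
of thickness 1.

The regression is single-response PLS via scikit-learn's NIPALS
`PLSRegression` with scaling disabled (deterministic); default latent
variables: 6 (whole-flower context) or 8 (trimmed context). Metrics:
RMSEC/RMSECV/RMSEP as root mean squared errors on calibration, concatenated
held-out CV predictions, and validation respectively; prediction bias
`mean(ŷ − y)`; R²_pred reported both as the squared Pearson correlation of
measured vs predicted (primary) and as 1 − SSE/SST; RPD = sd(validation y,
n−1 denominator) / RMSEP. Perfect prediction yields RPD = ∞, flagged rather
than clipped; zero validation variance is an error.

The permutation test shuffles y (n = 200 by default, seed mandatory),
recomputes the cross-validated error per shuffle, and reports the empirical
p-value `(1 + #{permuted RMSECV ≤ actual}) / (n_perm + 1)` together with
paired Wilcoxon signed-rank, sign, and randomization-t tests comparing each
sample's actual absolute CV residual with its mean absolute residual across
the permuted models. The paired tests are residual-based (not fold-error
based): that makes them sensitive to per-sample improvement, and their
minimum attainable p is not floored at 1/(n_perm+1).

## Synthetic data generators

All generators are pure functions of (scenario, seed).

**Images.** A scene is a dark background, a textured green bud ellipse,
stigma filaments, and trichome speckle. Geometry is kept proportional to
the copy-stand setup the segmentation constants were designed for: on the
512 px default canvas the bud spans ~320 px, filaments are ~7 px wide
(enough to survive the 11 px median) and trichome dots are 1–2 px. The bud's
channel ceiling keeps its K above the 110 rescue gate; trichome dots are
neutral-hued but mixed-pixel dimmed (gray ~118–142), as tiny translucent
glands image at this resolution — when they leak into a mask, their
near-zero b\* drags the amber score down, reproducing the known confusion
mode between trichomes and stigmas. Filaments are drawn without
anti-aliasing so the ground-truth mask is exact; each stigma pixel is
colored at the yellow anchor with probability `amber_fraction` and at white
otherwise, plus per-pixel Gaussian RGB jitter. The recorded ground-truth
yellowness is the index evaluated on the drawn pixels themselves, so
generator and scorer are consistent by construction. Not emulated: specular
highlights, depth-of-field blur, leaf matter, overlapping inflorescences,
camera noise beyond white jitter — passing tests say the operator chain
recovers structures with these statistics, not that it handles arbitrary
field photography.

**Cohorts.** 25 genotypes × 4 stages with a planted chemovar mix
(9 high-THCA, 5 high-CBDA, 11 even-ratio) and planted TCC peak-stage counts
(1, 2, 10, 12 across stages 1–4, the distribution reported for the study
population); peak amplitudes are drawn within 4.03–87.06 mg/g. Trajectories
are unimodal with 8–20% decay per stage off-peak and 2% multiplicative
noise; CBDA+THCA carry ~90% of TCC at the genotype's chemovar ratio; CBGA
decays after stage 1 for high-THCA/even-ratio genotypes and peaks at stage
3 for high-CBDA ones; weights grow with stage so yield peaks late. The
truth table records the generator's own argmax over the realized series,
making peak-count recovery checkable exactly.

**Spectra.** Beer–Lambert linear mixtures on the 128-channel 950–1650 nm
grid: a fixed baseline (smooth polynomial plus broad constant matrix bands,
including a 1450 nm water-band analog) + Σ concentration × Gaussian band
shape, then per-spectrum multiplicative scatter (sd 5%) and additive noise.
The matrix bands matter: they dominate each spectrum's internal variance,
which keeps SNV's per-spectrum scaling nearly concentration-independent —
the regime in which SNV is a scatter correction rather than a nonlinear
distortion, as in real plant NIR where water/cellulose features dwarf
analyte bands. Noise is parametrized as an SNR (clean signal RMS /
noise sd; default 100). The band library is arbitrary but frozen in a
versioned module; it does not model real cannabinoid band assignments.
An analyte counts as *learnable* when its own signal contribution exceeds
10× the noise sd — the usual quantification-limit convention; at the default
settings that selects CBDA and THCA, while low-abundance analytes sit at
1–3× the floor (detectable at best) and THCV has zero amplitude by design
as a negative control.

## Problem sizes and determinism

Default study sizes are those of the emulated design: 100 samples
(25 genotypes × 4 stages), 128 spectral channels, 75/25 split, 10-fold
venetian blinds, 200 permutations. Validation suites use 20-image panels
for segmentation/score recovery and 20 seeded repeats (60 permutations
each) for null calibration of the permutation test — sizes chosen to give
stable pass/fail behavior at interactive runtimes. Every stochastic path
takes an explicit seed; identical (data, config, seed) reproduce results
bit-for-bit.

## Known limitations

* The segmentation constants assume copy-stand geometry, fixed lighting and
  a dark background; there is no lighting normalization beyond max-RGB.
* CMYK has no colorimetric standard; the naive max-based conversion is a
  device convention, and the K thresholds are defined on that convention.
* The amber-stage references (28/37/54/65) are population values; per-
  genotype recalibration is supported but not automated.
* The yellowness index is a two-channel (L\*, b\*) construction; stigmas
  that mature toward red/brown rather than yellow-amber shift mostly in a\*
  and will be under-scored.
* PLS latent-variable counts are fixed by configuration, not selected;
  the package reports RMSECV for the configured count only.
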