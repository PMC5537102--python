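# Methods

This note documents the models, parameters and numerical choices behind
each stage, what the phantom generator does and does not emulate, and the
known limitations.

## Phantom generator

Each phantom is a single-channel 8-bit image with a zero-valued frame, a
speckle-textured scan rectangle, a hypoechoic elliptical nodule, a tick
ruler and burned-in annotations. A 3-channel replicated-grayscale writer
is provided for compatibility with capture chains that store gray content
in RGB.

**Speckle.** White Gaussian noise, low-pass filtered at the requested
correlation length (default 2 px), unit-normalized and mapped through
`mean · exp(0.45 z)`, clipped to [1, 255]. This yields the granular,
positively skewed texture characteristic of coherent imaging with a
tunable grain size. It is *not* an acoustic simulation: there is no
point-spread-function model, no attenuation with depth, no fan geometry
(the texture region is rectangular). Default mean intensity 120.

**Nodule.** The interior of the nodule ellipse is multiplied by 0.65
(benign) or 0.35 (malignant): both classes are hypoechoic, malignant ones
markedly more so. This single echogenicity contrast is what makes the
phantom cohorts classifiable; real malignancy cues (margins,
calcifications, aspect ratio) are not modelled, so classifier accuracy on
phantoms says nothing quantitative about clinical accuracy — it verifies
the pipeline's plumbing, cost logic and evaluation protocol.

**Tick ruler.** 2×2 dots at intensity 255 every `tick_spacing` px
(default 20, cohort range 8–40) down a column at `tick_column_frac` of
the width (default 0.92). The fraction is validated to lie strictly in
(0.7, 1.0), inside the region the calibration stage searches; the texture
rectangle's right edge adapts so the ruler stays detached from it.

**Artifacts.** Up to three intensity levels, one per histogram partition
[0,100] / [101,200] / [201,255] (defaults 40, 150, 230). Caliper crosses
are drawn at the four nodule boundary points at the brightest level, a
dashed outline around the nodule at the middle level, and one detached
text-like block per level in the bottom margin. Each block (≈360 px) is
deliberately larger than the whole ruler (≈70 px), so each planted level
is the modal intensity of its partition among detached pixels — the
estimator's target is unambiguous. After texture drawing, any clean
non-zero pixel that collides with a requested level is nudged by ±1
intensity, so level-matched detection has exact ground truth. Levels must
be ≥ 1 because the removal step only considers non-zero pixels.

**Determinism.** `generate_phantom(spec, seed)` is bitwise reproducible;
cohort generation derives per-phantom seeds, labels, spacings and nodule
geometry from the cohort seed. Exactly `round(n · malignant_fraction)`
phantoms are malignant.

## Calibration

The right 30% of the image is binarized by a local-mean adaptive
threshold (15 px window, pixel must exceed its local mean by 10 intensity
levels — the offset suppresses most binarized speckle while 255-valued
dots on a dark margin always pass). Columns with ≥ 4 candidate pixels
are autocorrelated after mean-centring (FFT, all columns at once).
Centring is essential: a dense aperiodic column has near-zero
coefficients at nonzero lags, while a periodic tick column keeps peaks
near the zero-lag value, so tick columns cannot be out-scored by
binarized speckle regardless of pixel counts. The spacing is the first
local maximum at lag ≥ 2 exceeding half the zero-lag value; the score is
the normalized peak height, with a floor of 0.5 below which the image is
reported as having no tick bar and passes through at native scale with a
warning (a per-image failure should not abort a cohort).

Rescaling uses bicubic interpolation (anti-aliased when shrinking),
rounded and clipped to [0, 255]; ratio 1.0 short-circuits to an exact
copy so the identity contract holds bitwise. The cohort plan scales every
image toward the *largest* spacing, so all ratios are ≥ 1 (upsampling
only — no texture is destroyed by decimation).

## Artifact removal and POCS

Connected components use 8-connectivity. Level estimation takes the modal
histogram bin (width 1) per partition, ties toward the lower intensity,
empty partitions omitted. Matching is exact equality by default — burned
overlays carry fixed intensities; a `band` parameter widens matching to
±band for captures whose overlays are anti-aliased. Because the level
estimate comes from detached regions only, an on-texture artifact drawn
at an intensity that never occurs detached would be missed; the phantom's
text blocks exist precisely to make every level observable.

POCS alternates two projections until the mean absolute change on masked
pixels drops to `tol` (0.1 intensity levels) or `max_iters` (50):
smoothness — per 8×8 tile, orthonormal 2-D DCT, keep the `kept_coeffs`
(10) lowest-frequency coefficients in zig-zag order, inverse transform;
data consistency — reset all known pixels to their observed values. Data
consistency is applied last, so known pixels of the output equal the
input exactly. Images are edge-padded to a multiple of the block size and
cropped back.

Initialization: masked pixels start at the median of their known 5×5
neighbours; pixels deep inside a thick artifact (no known neighbour in
the window) take the value of their nearest known pixel. The block
transform cannot move information across tile boundaries, so tiles that
contain no known pixels keep whatever the initialization gave them — a
plausible local seed is therefore part of the method, not merely a speed
optimization.

When calibration has located the tick ruler, the cleaning stage also adds
the ruler strip (tick column ± 1–2 px) to the removal mask (configurable,
default on), so the ruler does not survive into the learning stages.

## Augmentation

Nine patches per image: centres at the nodule centre (midpoint of the ROI
bounding box) plus the 3×3 grid of offsets {−s, 0, +s}² with stride
s = patch/2 (128 for 256-px patches). Whether the source procedure used a
grid, random offsets or hand placement is not documented; the grid is the
choice here because it guarantees every patch contains nodule texture and
each off-centre patch contains surrounding tissue, and it is
deterministic. Patch origins are clamped into the image; images smaller
than the patch are zero-padded (bottom/right) with a logged warning. An
image exactly the patch size yields nine identical patches — the count
law |samples| = 9 × |cases| is kept exact rather than deduplicating.
Crops are taken after calibration and restoration. TI-RADS scores
{3, 4a, 4b, 4c, 5} map to malignant, {1, 2} to benign; the label is a
pure function of the score.

## Classifier

The "cascade" is an averaged committee of 10 independently seeded
100-tree random forests: no stage-wise thresholds are defined anywhere,
and a committee yields the single continuous score per sample that ROC
analysis needs. Cost sensitivity follows the standard cost-sensitive
classifier semantics: at training time, each instance is weighted by the
cost of misclassifying its class; at prediction time, the label minimizes
expected cost Σᵢ P(i|x)·C[i][j], which for a 2×2 zero-diagonal matrix is
a threshold at C[ben][mal] / (C[ben][mal] + C[mal][ben]) on the averaged
malignant probability. Ties go to malignant — the clinically conservative
direction. With equal off-diagonal costs this is exactly argmax.
The automatic cost matrix sets C[mal][ben] = n_benign / n_malignant and
C[ben][mal] = 1, so the rarer class is protected; both entries are
overridable.

The default feature extractor (39 values: 16-bin normalized histogram;
GLCM contrast/homogeneity/energy/correlation at distance 1 in 4
directions on 32 grey levels; log-scaled mean-square energies of the 7
sub-bands of a 2-level db2 wavelet decomposition) exists so the pipeline
is testable at desk scale. CNN embeddings are an injection point
(`register_embedding`), held to a 1024-feature contract, never a
dependency.

Evaluation is per-sample by default; per-case aggregation (mean score,
majority label over the nine crops) is available via
`PipelineConfig(aggregate="case")`.

## Evaluation

Positive class is malignant everywhere. ROC and AUC use the threshold
sweep / trapezoidal rule with the tie convention that equals the pairwise
rank statistic P(s⁺ > s⁻) + ½P(tie); the test suite checks this against
an exhaustive pairwise oracle. Rates with empty denominators are reported
as undefined with a flag rather than silently as 0.

Cross-validation is stratified at case level: cases are shuffled within
class and dealt round-robin into one continuous stream, which bounds both
the per-class counts and the *total* fold sizes within one case of each
other (a per-class-only stratifier can make totals differ by two). All
nine crops of a case share its fold, preventing crop leakage.

## Problem sizes and numerical notes

Tests and the acceptance script run on phantom cohorts of 20–30 images at
360×560 (the typical size of open thyroid ultrasound collections) or
272×320, with 306/132/438/77-case cohorts for the exact augmentation
count laws; these sizes exercise every code path while keeping runs
reproducible on a laptop. POCS convergence on phantoms is monotone after
the first iterations and typically stops by tolerance in 10–20
iterations. All randomness flows from explicit seeds; the pipeline's
master seed derives the cohort, fold and training seeds, and manifests
serialize with sorted keys so determinism is byte-checkable.

## Limitations

- The phantom is a structural stand-in, not an acoustic simulation;
  classifier performance on phantoms validates mechanics, not clinical
  merit.
- Exact-level artifact matching assumes hard-burned overlays; smoothed or
  alpha-blended annotations need the band option and will reduce recall.
- Calibration reads relative scale only; physical units (mm per tick) in
  burned-in text are not parsed.
- Restoration is POCS-only; no exemplar-based or diffusion inpainting.
- The XML annotation dialect of the public thyroid database is not
  parsed; annotations are JSON sidecars (a converter is future work).
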