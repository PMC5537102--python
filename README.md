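# thyroprep

Preprocessing and classification pipeline for thyroid-nodule ultrasound
images, built for computer-aided diagnosis (CAD) experiments where raw
clinical captures must be turned into clean, scale-normalized, labelled
training patches before any classifier sees them.

Clinical B-mode captures are awkward inputs for texture learning: pixel
scale varies with machine and depth setting, and radiologists burn
caliper crosses, outlines and text into the very textures a model should
learn. `thyroprep` implements the full chain that fixes this, plus the
downstream classifier and its evaluation:

1. **Scale calibration** — find the vertical ruler of tick dots in the
   right margin by adaptive thresholding and per-column autocorrelation;
   the first periodic peak gives the tick spacing *m* (px). Every image
   in a cohort is rescaled by *r* = (largest *m* in cohort) / *m* with
   bicubic interpolation, so one pixel spans the same physical distance
   everywhere.
2. **Artifact removal with POCS restoration** — non-zero pixels are
   segmented into connected components; the largest is the texture
   region, the rest are "possible artifacts". Their histogram is split
   into [0,100], [101,200], [201,255], each partition's modal intensity
   becomes an artifact level, and every level-matched pixel is erased.
   Gaps are restored by projection onto convex sets: alternate a
   data-consistency projection (reset known pixels) with a smoothness
   projection (per 8×8 tile, keep the 10 lowest-frequency DCT
   coefficients) until the filled pixels stop changing.
3. **Nine-crop augmentation** — each annotated image yields exactly nine
   256×256 patches centred on a 3×3 grid (stride 128) around the nodule
   centre, labels inherited from the parent's TI-RADS score (≥ 3 is
   malignant-suspicious), so |samples| = 9 × |cases| per class.
4. **Cost-sensitive random-forest cascade** — a committee of 10 forests
   (100 trees each) trained on pluggable per-patch features, with
   instance weights and minimum-expected-cost prediction under a 2×2
   cost matrix derived from the class distribution
   (C[mal][ben] = n_benign / n_malignant).
5. **Evaluation** — accuracy, sensitivity (TPR), specificity (TNR), ROC
   and AUC, under stratified *case-level* k-fold cross-validation so the
   nine crops of one image never leak across folds.

A built-in **phantom generator** produces synthetic ultrasound-like
images (speckle texture, hypoechoic nodule, tick ruler, annotation
artifacts at known intensities) with complete ground truth, so every
stage is testable end to end without clinical data. Feature extraction
is pluggable: the bundled extractor is a 39-dim texture descriptor
(histogram, grey-level co-occurrence, wavelet energies); a CNN embedding
can be registered and is held to a 1024-feature contract.

## Worked example

```python
from thyroprep import PipelineConfig, run_pipeline

config = PipelineConfig(simulate_n=30, k_folds=3, master_seed=29)
report, manifest = run_pipeline(config)
print(manifest["augmentation"]["n_samples"], round(report.accuracy, 3),
      round(report.auc, 3))
```

prints

```
270 0.922 0.969
```

— 30 phantoms became 9 × 30 = 270 labelled patches, and pooled
out-of-fold predictions classify malignant vs benign crops with 92.2%
accuracy and AUC 0.969 (malignant phantom nodules are markedly more
hypoechoic, so texture features separate them). Rerunning with the same
config reproduces the manifest byte for byte. Stage-by-stage versions of
this flow live in `examples/` (simulation, calibration, artifact
removal, augmentation, training/evaluation, full pipeline), e.g.
calibration on a five-phantom cohort recovers every planted tick spacing
exactly and artifact removal recovers the planted intensity levels
(40, 150, 230) with mask recall 1.000 and masked-region MAE 4.1 after
restoration vs 28.3 with gaps left black.

A thin CLI mirrors the stages:

```bash
thyroprep simulate --n 10 --seed 1 --out-dir phantoms/
thyroprep calibrate --in-dir phantoms/ --out-dir calibrated/
thyroprep clean --in-dir calibrated/ --out-dir cleaned/
thyroprep augment --in-dir phantoms/ --out-dir dataset/
thyroprep run --config pipeline.toml
```

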