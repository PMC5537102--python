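"""Detect tick bars on a cohort and rescale everything to one scale.

The tick spacing m (pixels between ruler dots) encodes the physical size
of a pixel; each image is scaled by (largest spacing in cohort) / m with
bicubic interpolation so all images share the coarsest scale.
"""

from thyroprep import calibrate_cohort, generate_cohort, rescale_image

cohort = generate_cohort(n_images=5, malignant_fraction=0.4, seed=7)
images = {ph.image_id: ph.pixels for ph in cohort}

detections, plan, failed = calibrate_cohort(images)
print(f"reference spacing: {plan.reference_spacing} px; failures: {failed}")
print(f"{'id':<12} {'truth m':>8} {'found m':>8} {'score':>6} {'ratio':>7} {'new size':>12}")
for ph in cohort:
    det = detections[ph.image_id]
    ratio = plan.per_image_ratio[ph.image_id]
    rescaled = rescale_image(ph.pixels, ratio)
    print(f"{ph.image_id:<12} {ph.truth_tick_spacing:>8} {det.spacing_m:>8} "
          f"{det.score:>6.2f} {ratio:>7.2f} {str(rescaled.shape):>12}")

# 'found m' should match 'truth m' within a pixel; after rescaling, every
# image's tick spacing equals the reference, i.e. one pixel spans the
# same physical distance everywhere.
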