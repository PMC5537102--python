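"""Nine-crop augmentation: one annotated image -> nine labelled patches.

Patch centres sit on a 3x3 grid (stride = half the patch) around the
nodule centre, so every patch sees nodule texture and the outer patches
also see surrounding tissue — the label is inherited from the parent.
"""

from thyroprep import PhantomSpec, crop_nine, generate_cohort, generate_phantom
from thyroprep.augmentation import augment_dataset

ph = generate_phantom(PhantomSpec(class_label="malignant"), seed=1)
samples = crop_nine(ph.pixels, ph.roi, parent_id=ph.image_id)
print(f"{len(samples)} patches of {samples[0].patch.shape}, label {samples[0].label!r}")
for s in samples[:3]:
    print(f"  crop {s.crop_index}: origin {s.offset}")

cohort = generate_cohort(12, malignant_fraction=1 / 3, seed=2)
_, report = augment_dataset([(p.pixels, p.roi) for p in cohort],
                            parent_ids=[p.image_id for p in cohort])
print(report.to_string(index=False))

# The count law is exact: samples = 9 x cases, per class and in total.
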