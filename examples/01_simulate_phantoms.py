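"""Generate a small phantom cohort and inspect its ground truth.

Each phantom is a speckle-textured image with a hypoechoic nodule, a tick
ruler in the right margin and burned-in annotation artifacts, plus the
exact truth of everything planted.
"""

from thyroprep import generate_cohort

cohort = generate_cohort(n_images=6, malignant_fraction=0.5, seed=42)

print(f"{'id':<12} {'size':<10} {'label':<10} {'tick col':>8} {'spacing':>8} {'artifact px':>12}")
for ph in cohort:
    h, w = ph.pixels.shape
    print(f"{ph.image_id:<12} {h}x{w:<6} {ph.label:<10} "
          f"{ph.truth_tick_column:>8} {ph.truth_tick_spacing:>8} "
          f"{ph.truth_artifact_mask.sum():>12}")

# Tick spacing varies across the cohort, so calibration has real work to
# do; the artifact mask records exactly which pixels the annotations
# overwrote, so removal and restoration can be scored.
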