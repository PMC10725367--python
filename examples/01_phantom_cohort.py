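"""Generate a small synthetic phantom cohort and save it as PNGs.

Benign-like phantoms have smooth near-elliptical boundaries, homogeneous
interiors and a sharp rim; malignant-like ones are spiculated with
heterogeneous speckle texture and a diffuse rim.
"""

from lesiongraph import generate_cohort, save_cohort

cohort = generate_cohort(n_benign=5, n_malignant=5, seed=0)
manifest = save_cohort(cohort, "scratch/example_cohort")

for i, (image, mask, label) in enumerate(cohort):
    name = "malignant" if label else "benign"
    print(f"phantom {i}: {name:9s}  lesion={int(mask.sum()):6d} px  "
          f"intensity range=[{image.min()}, {image.max()}]")
print(f"\nmanifest written to {manifest}")
print("Each line is one image/mask pair; lesion size and intensity spread "
      "differ systematically between the two classes.")
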