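"""Generate a seeded CT-like phantom and inspect its content.

The phantom emulates the structure of annotated rib-fracture CT: bone-density
tubes on a soft-tissue background, small bright lesions attached to the tubes
(instance labels 1-4, or -1 for "fracture of uncertain type") and optional
off-rib decoy blobs that carry lesion intensity but no label.
"""

import numpy as np

from ribseg import PhantomConfig, generate_phantom, write_sample

cfg = PhantomConfig(
    grid_size=(64, 64, 64),
    spacing_mm=(1.25, 0.75, 0.75),   # anisotropic, like thick-slice CT
    n_ribs=3, n_lesions=3, n_decoys=2,
    uncertain_fraction=0.2,
    seed=7,
)
sample = generate_phantom(cfg, index=0)

print("image HU range:", sample.image.values.min(), "to", sample.image.values.max())
print("label values present:", np.unique(sample.labels.values))
for rec in sample.lesion_catalogue:
    print(f"  lesion {rec.instance_id}: centre {tuple(round(c, 1) for c in rec.centroid_voxel)}, "
          f"radius {rec.radius_mm:.1f} mm, label {rec.label}")
for rec in sample.decoy_catalogue:
    print(f"  decoy  {rec.instance_id}: centre {tuple(round(c, 1) for c in rec.centroid_voxel)} (unlabelled)")

write_sample(sample, "phantom_image.nii.gz", "phantom_label.nii.gz",
             "phantom_catalogue.json")
print("wrote phantom_image.nii.gz / phantom_label.nii.gz / phantom_catalogue.json")
# Each lesion is one connected instance; decoys appear only in the image,
# which is what later makes them stage-1 false positives.
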