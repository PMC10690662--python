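"""Build a paired synthetic T1w/PET subject and inject a hypometabolic lesion.

The phantom is an ellipsoidal brain with CSF/GM/WM shells sharing geometry
across both modalities, plus a 36-label toy atlas.  The lesion multiplies
PET uptake by a factor < 1 inside a sphere, emulating focal hypometabolism.
"""

import numpy as np

import sipcom as sp

spec = sp.PhantomSpec(shape=(64, 64, 64), voxel_size_mm=2.0, seed=42)
study = sp.generate_phantom(spec)

print(f"brain mask: {study.mask.n_voxels} voxels "
      f"({study.mask.n_voxels * study.pet.voxel_volume_ml:.0f} mL)")
print(f"atlas labels in use: {np.unique(study.atlas.data[study.mask.data]).size}")
print(f"PET intensity range in brain: "
      f"[{study.pet.data[study.mask.data].min():.3f}, "
      f"{study.pet.data[study.mask.data].max():.3f}]")

lesion = sp.LesionSpec(center_mm=(0.0, 25.0, 0.0), radius_mm=9.0, factor=0.7)
lesioned = sp.inject_lesion(study.pet, lesion, study.mask)
support = sp.lesion_mask(study.pet, lesion)
drop = 100 * (1 - lesioned.data[support].sum() / study.pet.data[support].sum())

print(f"\nlesion: {support.sum()} voxels "
      f"({support.sum() * study.pet.voxel_volume_ml:.1f} mL), "
      f"mean uptake reduced by {drop:.0f}%")
print("voxels changed outside the lesion:",
      int((lesioned.data != study.pet.data)[~support].sum()))
# A 30% uptake reduction inside the sphere and bit-identical values outside:
# exactly the controlled ground truth the detection stages are tested on.
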