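# sipcom

Detection of focal hypometabolism in interictal [18F]FDG-PET by subtracting
a **pseudo-normal PET predicted from the patient's own T1w MRI**.

In presurgical evaluation of drug-resistant focal epilepsy, the
epileptogenic zone typically shows reduced FDG uptake. Voxel-wise
comparison against a control database (SPM-style) requires heavy smoothing
and inherits the controls' regional variance. This package implements the
alternative: a 3D conditional adversarial network (pix2pix-style) learns the
T1w→PET mapping from healthy controls; for a patient, the predicted
pseudo-normal PET is scaled to the clinical PET's global mean, subtracted,
and the difference is standardized within the brain mask,

    Z_i = (D_i − μ_D) / σ_D,      D = clinical − predicted,

with the map oriented so hypometabolism is positive. Clusters with
Z > 2.33 covering at least 1 mL inside the brain mask eroded by three
voxels are reported as hypometabolic foci, localized to an 18-region
bilateral cortical label scheme and scored for concordance with the
resection zone (RZ).

The package is usable end-to-end without any imaging data: a synthetic
phantom module generates paired T1w/PET volumes with shared anatomy, a
brain mask, a 36-label toy atlas, and injectable lesions of controlled
volume and intensity. The network layer (3D convolutions, transpose
convolutions, batch normalization, PReLU, Adam, adversarial/MSE losses) is
implemented in-package on numpy with reverse-mode autodiff.

## Worked example

```python
import math
import sipcom as sp

# paired phantom: "clinical" PET carries a 2 mL lesion at 70% uptake;
# the pseudo-normal prediction is the same anatomy, independent noise
spec = sp.PhantomSpec(shape=(64, 64, 64), voxel_size_mm=1.0,
                      semi_axes_mm=(26, 28, 26), seed=7)
study = sp.generate_phantom(spec)
predicted = sp.generate_phantom(spec, pet_noise_seed=1007).pet
radius = (3 * 2000 / (4 * math.pi)) ** (1 / 3)
lesion = sp.LesionSpec(center_mm=(0, 14, 0), radius_mm=radius, factor=0.7)
clinical = sp.inject_lesion(study.pet, lesion, study.mask)

zmap, clusters, prov = sp.run_sipcom(clinical, study.mask, predicted=predicted)
print(len(clusters), clusters.clusters[0].volume_ml, clusters.clusters[0].peak_z)
```

prints

```
1 2.146 11.164251...
```

one detected cluster of 2.146 mL (the injected 2 mL sphere, slightly grown
by smoothing) with peak Z ≈ 11, far above the 2.33 threshold; no false
positives elsewhere. `examples/` contains narrative scripts for each
capability: phantom generation, the subtraction pipeline, toy model
training, and cohort evaluation (run as `python examples/04_cohort_evaluation.py`).

A packaged 20-patient cohort fixture (per-patient resection zone and the
region sets detected by visual reading, SPM and the subtraction pipeline)
drives the cohort-level evaluation:

```python
records = sp.load_cohort()
sp.cohort_rates(records, "sipcom")   # (12, 20, 0.6)  -> 60% RZ concordance
sp.cohort_rates(records, "spm")      # (7, 20, 0.35)
sp.cohort_rates(records, "visual")   # (17, 20, 0.85)
```

## Command line

```bash
sipcom simulate --out sim/ --n-subjects 4 --seed 1 --lesion-radius-mm 8
sipcom train    --data sim/ --out model.ckpt --epochs 20
sipcom sipcom   --clinical pet.nii.gz --mask mask.nii.gz \
                --t1w t1w.nii.gz --model model.ckpt --out run/
sipcom metrics  --predicted pred.nii.gz --truth pet.nii.gz --mask mask.nii.gz
sipcom evaluate
```

Inputs must be co-registered 3D NIfTI volumes on a common lattice;
registration, bias correction and skull stripping are upstream concerns.

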