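"""Subtraction Z-map and cluster extraction, with flood-fill oracle checks."""

import numpy as np
import pytest

import sipcom as sp
from sipcom.core import ZMap
from sipcom.io_prep import BrainMask, Volume3D

from conftest import brute_force_clusters


def _zmap_from_array(z, mask=None, affine=None):
    affine = np.eye(4) if affine is None else affine
    mask = np.ones(z.shape, bool) if mask is None else mask
    return ZMap(
        volume=Volume3D(z, affine),
        mask=BrainMask(mask, affine),
        mu=0.0,
        sigma=1.0,
    )


class TestScalePredicted:
    def test_ratio_definition(self, small_study):
        pet = small_study.pet
        clinical = pet.with_data(pet.data * 2.0)
        scaled, ratio = sp.scale_predicted(pet, clinical, small_study.mask)
        assert ratio == pytest.approx(2.0)
        assert np.allclose(scaled.data, pet.data * 2.0)

    def test_equal_mean_unchanged(self, small_study):
        scaled, ratio = sp.scale_predicted(
            small_study.pet, small_study.pet, small_study.mask
        )
        assert ratio == 1.0
        assert np.array_equal(scaled.data, small_study.pet.data)

    def test_means_equal_after_scaling(self, small_study):
        rng = np.random.default_rng(5)
        clinical = small_study.pet.with_data(
            small_study.pet.data + rng.normal(0, 0.05, small_study.pet.shape)
        )
        scaled, _ = sp.scale_predicted(small_study.pet, clinical, small_study.mask)
        m = small_study.mask.data
        assert scaled.data[m].mean() == pytest.approx(clinical.data[m].mean(), rel=1e-9)

    def test_zero_mean_rejected(self, small_study):
        zero = small_study.pet.with_data(np.zeros(small_study.pet.shape))
        with pytest.raises(ValueError, match="zero mean"):
            sp.scale_predicted(zero, small_study.pet, small_study.mask)


class TestDifferenceZmap:
    def test_constant_offset_removed_by_centering(self, small_study):
        # adding a global constant to the clinical PET leaves Z unchanged
        pet = small_study.pet
        rng = np.random.default_rng(21)
        noisy = pet.with_data(pet.data + rng.normal(0, 0.02, pet.shape))
        z_base = sp.difference_zmap(noisy, pet, small_study.mask)
        z_off = sp.difference_zmap(
            noisy.with_data(noisy.data + 0.3), pet, small_study.mask
        )
        assert np.allclose(
            z_base.data[small_study.mask.data],
            z_off.data[small_study.mask.data],
            atol=1e-9,
        )

    def test_three_voxel_closed_form(self):
        # in-mask differences {1, 2, 3}: Z = (x - 2)/sqrt(2/3)
        clinical = Volume3D(np.array([1.0, 2.0, 3.0]).reshape(1, 1, 3))
        predicted = Volume3D(np.zeros((1, 1, 3)))
        mask = BrainMask(np.ones((1, 1, 3), bool))
        zmap = sp.difference_zmap(clinical, predicted, mask, hypometabolism_positive=False)
        expected = np.array([-1, 0, 1]) / np.sqrt(2.0 / 3.0)
        assert np.allclose(zmap.data.ravel(), expected)
        assert zmap.sigma == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_hypometabolism_positive_sign_convention(self, small_study):
        pet = small_study.pet
        lesion = sp.LesionSpec(center_mm=(0, 20, 0), radius_mm=8, factor=0.5)
        clinical = sp.inject_lesion(pet, lesion, small_study.mask)
        zmap = sp.difference_zmap(clinical, pet, small_study.mask)
        core = sp.lesion_mask(pet, lesion) & small_study.mask.data
        assert zmap.data[core].mean() > 0  # reduced uptake -> positive Z

    def test_normalization_invariant(self, small_study):
        rng = np.random.default_rng(11)
        clinical = small_study.pet.with_data(
            small_study.pet.data + rng.normal(0, 0.02, small_study.pet.shape)
        )
        zmap = sp.difference_zmap(clinical, small_study.pet, small_study.mask)
        zin = zmap.data[small_study.mask.data]
        assert abs(zin.mean()) < 1e-6
        assert abs(zin.std() - 1.0) < 1e-6

    def test_identical_volumes_rejected(self, small_study):
        with pytest.raises(ValueError, match="zero variance"):
            sp.difference_zmap(small_study.pet, small_study.pet, small_study.mask)


class TestExtractClusters:
    def test_all_zero_map_empty_table(self):
        zmap = _zmap_from_array(np.zeros((8, 8, 8)))
        table = sp.extract_clusters(
            zmap, sp.DetectionConfig(min_volume_ml=0.001, mask_erosion_voxels=0)
        )
        assert len(table) == 0

    def test_block_cluster_statistics(self):
        z = np.zeros((5, 5, 5))
        z[1:3, 1:3, 1:3] = 3.0  # 2x2x2 block at 1 mm voxels = 0.008 mL
        zmap = _zmap_from_array(z)
        table = sp.extract_clusters(
            zmap, sp.DetectionConfig(min_volume_ml=0.004, mask_erosion_voxels=0)
        )
        assert len(table) == 1
        c = table.clusters[0]
        assert c.n_voxels == 8
        assert c.peak_z == pytest.approx(3.0)
        assert c.volume_ml == pytest.approx(0.008)
        assert c.centroid_ijk == pytest.approx((1.5, 1.5, 1.5))

    def test_min_volume_boundary_excludes_cluster(self):
        z = np.zeros((5, 5, 5))
        z[1:3, 1:3, 1:3] = 3.0
        zmap = _zmap_from_array(z)
        table = sp.extract_clusters(
            zmap, sp.DetectionConfig(min_volume_ml=0.009, mask_erosion_voxels=0)
        )
        assert len(table) == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(25):
            shape = tuple(rng.integers(10, 17, size=3))
            z = rng.normal(0, 1.2, shape)
            mask = np.ones(shape, bool)
            zmap = _zmap_from_array(z, mask)
            config = sp.DetectionConfig(
                z_threshold=1.5,
                min_volume_ml=0.001,
                connectivity=connectivity,
                mask_erosion_voxels=0,
            )
            table = sp.extract_clusters(zmap, config)
            oracle = brute_force_clusters(z, mask, 1.5, connectivity)
            ours = [
                {tuple(v) for v in c.voxels} for c in table.clusters
            ]
            assert sorted(map(sorted, ours)) == sorted(map(sorted, oracle))
            for c in table.clusters:
                vox = c.voxels
                zv = z[vox[:, 0], vox[:, 1], vox[:, 2]]
                assert c.peak_z == pytest.approx(zv.max())
                assert c.mean_z == pytest.approx(zv.mean())

    def test_detection_monotonicity(self):
        # raising the threshold shrinks the detected voxel set (a higher
        # threshold can split a component, so the *count* is not monotone);
        # raising the minimum volume never increases the cluster count
        rng = np.random.default_rng(99)
        z = rng.normal(0, 1.5, (16, 16, 16))
        zmap = _zmap_from_array(z)

        def detected_voxels(threshold):
            table = sp.extract_clusters(
                zmap,
                sp.DetectionConfig(
                    z_threshold=threshold, min_volume_ml=0.001, mask_erosion_voxels=0
                ),
            )
            return {tuple(v) for c in table.clusters for v in c.voxels}

        v1, v2, v3 = (detected_voxels(t) for t in (1.0, 2.0, 3.0))
        assert v3 <= v2 <= v1

        n_by_vol = [
            len(
                sp.extract_clusters(
                    zmap,
                    sp.DetectionConfig(
                        z_threshold=1.0, min_volume_ml=v, mask_erosion_voxels=0
                    ),
                )
            )
            for v in (0.001, 0.003, 0.01)
        ]
        assert n_by_vol == sorted(n_by_vol, reverse=True)

    def test_clusters_respect_eroded_mask(self, small_study):
        z = np.zeros(small_study.pet.shape)
        z[small_study.mask.data] = 5.0  # everything supra-threshold
        zmap = _zmap_from_array(z, small_study.mask.data, small_study.pet.affine)
        config = sp.DetectionConfig(min_volume_ml=0.008, mask_erosion_voxels=3)
        table = sp.extract_clusters(zmap, config)
        eroded = sp.erode_mask(small_study.mask, 3)
        for c in table.clusters:
            assert np.all(eroded.data[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]])


class TestRunSipcom:
    def test_oracle_predictor_recovers_lesion(self, small_study, small_spec):
        lesion = sp.LesionSpec(center_mm=(0, 20, 0), radius_mm=10, factor=0.7)
        clinical = sp.inject_lesion(small_study.pet, lesion, small_study.mask)
        predicted = sp.generate_phantom(small_spec, pet_noise_seed=1234).pet
        zmap, table, prov = sp.run_sipcom(
            clinical,
            small_study.mask,
            predicted=predicted,
            detection=sp.DetectionConfig(min_volume_ml=1.0),
            atlas=small_study.atlas,
            labels=small_study.labels,
        )
        assert len(table) >= 1
        top = table.clusters[0]
        center = np.asarray(top.centroid_xyz_mm)
        assert np.linalg.norm(center - np.array([0, 20, 0])) < lesion.radius_mm
        assert top.regions  # atlas annotation attached
        assert prov["n_clusters"] == len(table)

    def test_supplying_clinical_as_predicted_rejected(self, small_study):
        with pytest.raises(ValueError, match="zero variance"):
            sp.run_sipcom(
                small_study.pet, small_study.mask, predicted=small_study.pet
            )

    def test_requires_prediction_source(self, small_study):
        with pytest.raises(ValueError, match="supply either"):
            sp.run_sipcom(small_study.pet, small_study.mask)
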