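"""Region parsing, patient concordance and cohort-level scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sipcom as sp
from sipcom.core import ZMap, DetectionConfig, extract_clusters
from sipcom.io_prep import BrainMask, Volume3D
from sipcom.regions import REGION_CODES


class TestParseRegionSet:
    def test_hemisphere_distributes_left(self):
        assert sp.parse_region_set("AML + ATL R") == {"AML_R", "ATL_R"}

    def test_none_is_empty(self):
        assert sp.parse_region_set("N") == frozenset()

    def test_per_code_hemispheres(self):
        assert sp.parse_region_set("AML L + ATL L + ATL R") == {
            "AML_L",
            "ATL_L",
            "ATL_R",
        }

    def test_unknown_code_named_in_error(self):
        with pytest.raises(ValueError, match="XYZ"):
            sp.parse_region_set("XYZ R")

    def test_missing_hemisphere_rejected(self):
        with pytest.raises(ValueError, match="hemisphere"):
            sp.parse_region_set("AML + ATL")

    @given(
        codes=st.sets(
            st.tuples(st.sampled_from(REGION_CODES), st.sampled_from("LR")),
            min_size=0,
            max_size=6,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_format_parse_round_trip(self, codes):
        region_set = frozenset(sp.RegionCode(f"{c}_{h}") for c, h in codes)
        assert sp.parse_region_set(sp.format_region_set(region_set)) == region_set

    def test_every_fixture_cell_round_trips(self, cohort):
        for record in cohort:
            for attr in ("rz", "seeg", "visual", "spm", "sipcom"):
                s = getattr(record, attr)
                assert sp.parse_region_set(sp.format_region_set(s)) == s


class TestPatientConcordance:
    def test_overlapping_sets_concordant(self, cohort):
        p17 = next(r for r in cohort if r.patient == 17)
        assert p17.sipcom == {"ATL_R", "PLT_R", "OI_R"}
        assert p17.rz == {"ATL_R", "PLT_R", "TPO_R"}
        assert sp.patient_concordant(p17, "sipcom")

    def test_empty_method_set_discordant(self, cohort):
        p2 = next(r for r in cohort if r.patient == 2)
        assert p2.sipcom == frozenset()
        assert not sp.patient_concordant(p2, "sipcom")

    def test_method_equal_to_rz_concordant(self, cohort):
        record = cohort[0]
        clone = sp.PatientRecord(
            patient=99,
            engel_class="1a",
            mri_status="negative",
            lobar_localization="test",
            rz=record.rz,
            seeg=record.rz,
            visual=record.rz,
            spm=record.rz,
            sipcom=record.rz,
        )
        assert all(sp.patient_concordant(clone, m) for m in ("visual", "spm", "sipcom"))

    def test_monotone_under_set_growth(self, cohort):
        # adding regions to a method set never flips concordant -> discordant
        for r in cohort:
            if sp.patient_concordant(r, "sipcom"):
                grown = sp.PatientRecord(
                    patient=r.patient,
                    engel_class=r.engel_class,
                    mri_status=r.mri_status,
                    lobar_localization=r.lobar_localization,
                    rz=r.rz,
                    seeg=r.seeg,
                    visual=r.visual,
                    spm=r.spm,
                    sipcom=r.sipcom | {"MO_L"},
                )
                assert sp.patient_concordant(grown, "sipcom")


class TestCohortRates:
    def test_surgery_idem_resolves_to_seeg(self, cohort):
        p1 = next(r for r in cohort if r.patient == 1)
        assert p1.rz == p1.seeg
        p7 = next(r for r in cohort if r.patient == 7)
        assert p7.rz == {"AML_L", "ATL_L"}  # surgery narrower than SEEG
        p16 = next(r for r in cohort if r.patient == 16)
        assert p16.rz == {"MP_R", "LPr_R"}

    def test_whole_cohort_rates(self, cohort):
        assert sp.cohort_rates(cohort, "sipcom") == (12, 20, 0.6)
        assert sp.cohort_rates(cohort, "spm") == (7, 20, 0.35)
        assert sp.cohort_rates(cohort, "visual") == (17, 20, 0.85)

    def test_engel_subgroups(self, cohort):
        assert sp.cohort_rates(cohort, "sipcom", "engel_good")[:2] == (9, 14)
        assert sp.cohort_rates(cohort, "spm", "engel_good")[:2] == (5, 14)
        assert sp.cohort_rates(cohort, "sipcom", "engel_poor")[:2] == (3, 6)
        assert sp.cohort_rates(cohort, "spm", "engel_poor")[:2] == (2, 6)

    def test_mri_subgroups(self, cohort):
        assert sp.cohort_rates(cohort, "sipcom", "mri_positive")[:2] == (8, 12)
        assert sp.cohort_rates(cohort, "spm", "mri_positive")[:2] == (6, 12)
        assert sp.cohort_rates(cohort, "sipcom", "mri_negative")[:2] == (4, 8)
        assert sp.cohort_rates(cohort, "spm", "mri_negative")[:2] == (1, 8)
        assert sp.cohort_rates(cohort, "visual", "mri_negative")[:2] == (5, 8)
        assert sp.cohort_rates(cohort, "visual", "mri_positive")[:2] == (12, 12)

    def test_callable_subgroup_and_empty_subgroup(self, cohort):
        count, n, _ = sp.cohort_rates(cohort, "sipcom", lambda r: r.patient <= 10)
        assert n == 10
        with pytest.raises(ValueError, match="empty"):
            sp.cohort_rates(cohort, "sipcom", lambda r: False)

    def test_unknown_method_rejected(self, cohort):
        with pytest.raises(ValueError, match="unknown method"):
            sp.cohort_rates(cohort, "seeg-x")


class TestRegionRecallPrecision:
    def test_perfect_agreement(self, cohort):
        perfect = [
            sp.PatientRecord(
                patient=r.patient,
                engel_class=r.engel_class,
                mri_status=r.mri_status,
                lobar_localization=r.lobar_localization,
                rz=r.rz,
                seeg=r.seeg,
                visual=r.rz,
                spm=r.rz,
                sipcom=r.rz,
            )
            for r in cohort
        ]
        assert sp.region_recall_precision(perfect, "sipcom") == (1.0, 1.0)

    def test_all_empty_degenerate(self, cohort):
        empty = [
            sp.PatientRecord(
                patient=r.patient,
                engel_class=r.engel_class,
                mri_status=r.mri_status,
                lobar_localization=r.lobar_localization,
                rz=r.rz,
                seeg=r.seeg,
                visual=frozenset(),
                spm=frozenset(),
                sipcom=frozenset(),
            )
            for r in cohort
        ]
        recall, precision = sp.region_recall_precision(empty, "sipcom")
        assert recall == 0.0 and precision is None

    def test_fixture_regression_values(self, cohort):
        # frozen from an independent hand tally over the fixture rows
        recall, precision = sp.region_recall_precision(cohort, "spm")
        assert recall == pytest.approx(12 / 47)
        assert precision == pytest.approx(12 / 14)
        recall, precision = sp.region_recall_precision(cohort, "sipcom")
        assert recall == pytest.approx(22 / 47)
        assert precision == pytest.approx(22 / 24)


class TestAssignClusterRegions:
    def _table_from_block(self, z, affine=np.eye(4)):
        zmap = ZMap(
            volume=Volume3D(z, affine),
            mask=BrainMask(np.ones(z.shape, bool), affine),
            mu=0.0,
            sigma=1.0,
        )
        return extract_clusters(
            zmap, DetectionConfig(min_volume_ml=0.001, mask_erosion_voxels=0)
        )

    def test_cluster_inside_single_region(self, small_study):
        atlas = small_study.atlas
        # put a block strictly inside one atlas label
        lbl = atlas.data[16, 20, 16]
        assert lbl > 0
        z = np.zeros(atlas.shape)
        sel = atlas.data == lbl
        z[sel] = 5.0
        table = self._table_from_block(z, atlas.affine)
        table = sp.assign_cluster_regions(table, atlas, small_study.labels)
        for c in table.clusters:
            assert len(c.regions) == 1
            assert list(c.region_fractions.values()) == [pytest.approx(1.0)]

    def test_straddling_cluster_gets_both_fractions(self):
        atlas_data = np.zeros((10, 10, 10), dtype=np.int16)
        atlas_data[:6] = 1  # 60% of the block
        atlas_data[6:] = 2  # 40%
        atlas = Volume3D(atlas_data)
        import pandas as pd

        labels = pd.DataFrame(
            [
                {"label_id": 1, "region_code": "AML", "hemisphere": "L"},
                {"label_id": 2, "region_code": "ATL", "hemisphere": "L"},
            ]
        )
        z = np.zeros((10, 10, 10))
        z[:, 4:6, 4:6] = 5.0  # column through both labels, 60/40
        table = self._table_from_block(z)
        table = sp.assign_cluster_regions(table, atlas, labels)
        c = table.clusters[0]
        assert c.region_fractions["AML_L"] == pytest.approx(0.6)
        assert c.region_fractions["ATL_L"] == pytest.approx(0.4)

    def test_cluster_outside_labels_empty(self):
        atlas = Volume3D(np.zeros((10, 10, 10), dtype=np.int16))
        import pandas as pd

        labels = pd.DataFrame(
            [{"label_id": 1, "region_code": "AML", "hemisphere": "L"}]
        )
        z = np.zeros((10, 10, 10))
        z[2:5, 2:5, 2:5] = 5.0
        table = self._table_from_block(z)
        table = sp.assign_cluster_regions(table, atlas, labels)
        assert table.clusters[0].regions == frozenset()


class TestScoreControlFP:
    def test_hand_computed_summary(self):
        out = sp.score_control_fp([0, 2, 4])
        assert out["mean"] == pytest.approx(2.0)
        assert out["sd"] == pytest.approx(2.0)  # sample SD
        assert out["min"] == 0 and out["max"] == 4

    def test_all_empty(self):
        out = sp.score_control_fp([0, 0, 0])
        assert out["mean"] == 0.0 and out["sd"] == 0.0

    def test_single_subject_flagged(self):
        out = sp.score_control_fp([3])
        assert out["n"] == 1 and out["sd"] == 0.0


def test_evaluation_report_counts_and_rates(cohort):
    report = sp.evaluation_report(cohort)
    row = report[(report.method == "sipcom") & (report.subgroup == "all")].iloc[0]
    assert row.concordant == 12 and row.n == 20
    assert row.rate_pct == pytest.approx(60.0)
    assert (report.concordant <= report.n).all()
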