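"""Cumulative index, feature schema partitions and row assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kneemorph as km
from kneemorph.features import (
    BONES,
    PATHOLOGIES,
    PATHOLOGY_LOCATIONS,
    SUBSET_SIZES,
    FeatureDef,
    FeatureSchema,
)


class TestCumulativeIndex:
    def test_saturates_at_six(self):
        flags = km.PathologyFlags.all_present()
        assert km.cumulative_index(flags, "femur") == 6
        assert km.cumulative_index(flags, "tibia") == 6
        # osteonecrosis is graded at the four femorotibial sites only, so the
        # patella can realize at most 5 of the 6 tracked pathology kinds
        assert km.cumulative_index(flags, "patella") == 5

    def test_clean_bone_is_zero(self):
        flags = km.PathologyFlags.none()
        for bone in BONES:
            assert km.cumulative_index(flags, bone) == 0

    def test_pathology_counts_once_across_locations(self):
        flags = km.PathologyFlags.none()
        flags.set("cysts", "medial/femur", 1)
        flags.set("cysts", "lateral/femur", 1)
        flags.set("edema", "medial/femur", 1)
        assert km.cumulative_index(flags, "femur") == 2

    def test_modality_or_semantics(self):
        flags = km.PathologyFlags.none()
        flags.set("cysts", "medial/femur", 1, modality="MRI")  # CT silent
        assert km.cumulative_index(flags, "femur") == 1

    def test_trochlea_counts_toward_femur(self):
        flags = km.PathologyFlags.none()
        flags.set("cysts", "femoropatellar/trochlea", 1)
        assert km.cumulative_index(flags, "femur") == 1
        assert km.cumulative_index(flags, "patella") == 0

    def test_unknown_bone_rejected(self):
        with pytest.raises(ValueError, match="unknown bone"):
            km.cumulative_index(km.PathologyFlags.none(), "femour")

    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=8))
    def test_monotone_and_bounded(self, picks):
        flags = km.PathologyFlags.none()
        keys = sorted(flags.flags)
        previous = km.cumulative_index(flags, "femur")
        for pick in picks:
            flags.flags[keys[pick % len(keys)]] = 1
            current = km.cumulative_index(flags, "femur")
            assert previous <= current <= 6
            previous = current


class TestCompartmentIndex:
    def test_other_compartment_unaffected(self):
        flags = km.PathologyFlags.none()
        flags.set("cysts", "medial/femur", 1)
        assert km.compartment_cumulative_index(flags, "femur", "lateral") == 0
        assert km.compartment_cumulative_index(flags, "femur", "medial") == 1

    def test_two_pathologies_in_one_compartment(self):
        flags = km.PathologyFlags.none()
        flags.set("cysts", "medial/femur", 1)
        flags.set("sclerosis", "medial/femur", 1)
        assert km.compartment_cumulative_index(flags, "femur", "medial") == 2

    def test_compartment_sum_dominates_whole_bone_index(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            flags = km.PathologyFlags.none()
            for key in flags.flags:
                flags.flags[key] = int(rng.random() < 0.3)
            for bone in BONES:
                whole = km.cumulative_index(flags, bone)
                by_comp = sum(
                    km.compartment_cumulative_index(flags, bone, comp)
                    for comp in ("medial", "lateral", "femoropatellar")
                )
                assert by_comp >= whole

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValueError, match="unknown compartment"):
            km.compartment_cumulative_index(km.PathologyFlags.none(), "femur", "central")


class TestSchema:
    def test_printed_subset_sizes(self, schema):
        for subset, size in SUBSET_SIZES.items():
            assert len(schema.subset_names(subset)) == size, subset

    def test_partitions(self, schema):
        mri = set(schema.subset_names("MRI"))
        ct = set(schema.subset_names("CT"))
        d2 = set(schema.subset_names("2D"))
        d3 = set(schema.subset_names("3D"))
        tot = set(schema.subset_names("Tot"))
        assert mri | ct == d2 and not (mri & ct)
        assert d2 | d3 == tot and not (d2 & d3)
        assert not (set(schema.subset_names("Bone")) & set(schema.subset_names("Cartilage")))

    def test_bad_counts_rejected(self, schema):
        with pytest.raises(ValueError, match="subset"):
            FeatureSchema(schema.features[:-1])

    def test_yaml_roundtrip(self, schema, tmp_path):
        path = tmp_path / "schema.yaml"
        schema.save(path)
        loaded = FeatureSchema.load(path)
        assert loaded.names == schema.names

    def test_unknown_subset_rejected(self, schema):
        with pytest.raises(ValueError, match="unknown subset"):
            schema.subset_names("4D")


class TestAssembly:
    def test_full_record_gives_96_values(self, default_cohort, schema):
        row = km.assemble_features(default_cohort[0], schema)
        assert len(row.values) == 96
        assert np.all(np.isfinite(row.values))

    def test_missing_value_names_feature(self, default_cohort, schema):
        import copy

        record = copy.deepcopy(default_cohort[0])
        site = ("medial", "femur", "anterior")
        del record.thickness[site]
        with pytest.raises(KeyError, match="MRI act medial/femur anterior"):
            km.assemble_features(record, schema)

    def test_subset_selection_counts(self, default_cohort, schema):
        frame = km.cohort_to_frame(default_cohort[:5], schema)
        for subset, size in SUBSET_SIZES.items():
            reduced = km.select_subset(frame, subset, schema)
            assert reduced.shape[1] == size + 4  # + metadata columns

    def test_reassembly_is_idempotent(self, default_cohort, schema):
        frame = km.cohort_to_frame(default_cohort[:3], schema)
        once = km.select_subset(frame, "Cartilage", schema)
        twice = km.select_subset(once, "Cartilage", schema)
        assert twice.equals(once)


class TestValidation:
    def test_clean_synthetic_record_passes(self, default_cohort):
        report = km.validate_record(default_cohort[0])
        assert report.ok

    def test_out_of_range_grade_flagged(self, default_cohort):
        import copy

        record = copy.deepcopy(default_cohort[0])
        record.grades.icrs[("medial", "femur")] = 7
        report = km.validate_record(record)
        assert any("ICRS" in e and "7" in e for e in report.errors)

    def test_missing_thickness_names_site(self, default_cohort):
        import copy

        record = copy.deepcopy(default_cohort[0])
        del record.thickness[("lateral", "tibia", "middle")]
        report = km.validate_record(record)
        assert any("lateral" in e and "tibia" in e for e in report.errors)


def test_morphometry_from_parts_roundtrip(phantom_extraction):
    parts = [p for p in phantom_extraction["morphometry"] if p.part != "fibula"]
    values = km.SubjectRecord.morphometry_from_parts(parts)
    assert set(values) == set(km.features.MORPHOMETRY_FEATURES)
    assert values["FemBMD"] == pytest.approx(1.32, abs=0.01)
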