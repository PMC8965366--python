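"""Preprocessing: normalization, cropping, patch grid and its inverse,
stratified folds, flip augmentation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusegan.preprocessing import (
    DegenerateRangeError,
    GeometryError,
    assign_split_tags,
    augment_flip,
    augment_flip_pair,
    crop_resize,
    extract_patches,
    make_folds,
    minmax_normalize,
    reassemble,
)
from fusegan.synthetic import SyntheticConfig, Volume, generate_cohort


def _vol(data, modality="MRI"):
    return Volume(np.asarray(data, dtype=np.float64), modality)


class TestMinMaxNormalize:
    def test_affine_map(self):
        v = _vol(np.full((4, 4, 4), 2.0))
        v.data[0, 0, 0] = 4.0
        v.data[1, 1, 1] = 6.0
        out = minmax_normalize(v)
        assert out.data[0, 0, 0] == 0.5
        assert out.data[1, 1, 1] == 1.0
        assert out.data[2, 2, 2] == 0.0
        assert out.intensity_range == (2.0, 6.0)

    def test_unit_range_identity(self):
        rng = np.random.default_rng(0)
        data = rng.random((4, 4, 4))
        data[0, 0, 0], data[1, 1, 1] = 0.0, 1.0
        out = minmax_normalize(_vol(data))
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateRangeError):
            minmax_normalize(_vol(np.full((4, 4, 4), 3.0)))


class TestCropResize:
    def test_exact_crop_recovers_inner_cube(self):
        rng = np.random.default_rng(1)
        inner = (rng.random((8, 8, 8)) + 0.1).astype(np.float32)  # strictly positive
        padded = np.zeros((16, 16, 16))
        padded[4:12, 4:12, 4:12] = inner
        out = crop_resize(_vol(padded), 8)
        np.testing.assert_array_equal(out.data, inner)

    def test_resize_shape_contract(self):
        rng = np.random.default_rng(2)
        out = crop_resize(_vol(rng.random((40, 40, 40)) + 0.1), 32)
        assert out.data.shape == (32, 32, 32)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            crop_resize(_vol(np.zeros((8, 8, 8))), 8)


class TestPatchGrid:
    @pytest.mark.parametrize(
        "edge,patch,stride,expected",
        [(128, 64, 32, 27), (64, 64, 32, 1), (96, 64, 32, 8), (16, 8, 4, 27)],
    )
    def test_patch_counts(self, edge, patch, stride, expected):
        v = _vol(np.zeros((edge, edge, edge)))
        ps = extract_patches(v, patch, stride)
        assert len(ps) == expected
        if expected == 1:
            assert ps.origins == [(0, 0, 0)]

    def test_indivisible_geometry_rejected(self):
        with pytest.raises(GeometryError):
            extract_patches(_vol(np.zeros((20, 20, 20))), 8, 5)

    @given(
        edge=st.integers(8, 32),
        patch=st.integers(4, 16),
        stride=st.integers(1, 8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_count_closed_form_matches_window_scan(self, edge, patch, stride):
        if patch > edge or (edge - patch) % stride != 0:
            return
        v = _vol(np.zeros((edge, edge, edge)))
        ps = extract_patches(v, patch, stride)
        # brute-force enumeration of valid window corners on one axis
        axis_offsets = [
            o for o in range(0, edge - patch + 1)
            if o % stride == 0
        ]
        assert len(ps) == len(axis_offsets) ** 3
        assert len(ps) == ((edge - patch) // stride + 1) ** 3

    def test_origin_order_is_lexicographic(self):
        ps = extract_patches(_vol(np.zeros((16, 16, 16))), 8, 8)
        assert ps.origins == sorted(ps.origins)


class TestReassembly:
    @pytest.mark.parametrize("edge,patch,stride", [(16, 8, 4), (16, 8, 8), (12, 4, 2)])
    def test_extract_reassemble_identity(self, edge, patch, stride, rng):
        data = rng.random((edge, edge, edge))
        v = _vol(data)
        out = reassemble(extract_patches(v, patch, stride))
        np.testing.assert_array_equal(out.data.astype(np.float32), v.data)

    def test_overlap_is_arithmetic_mean(self):
        # two half-overlapping patches along one axis with constant values
        from fusegan.preprocessing import PatchSet

        origins = [
            (x, y, z) for x in (0, 2) for y in (0, 2) for z in (0, 2)
        ]
        patches = [
            np.full((4, 4, 4), 1.0 if x == 0 else 3.0) for (x, y, z) in origins
        ]
        ps = PatchSet(patches=patches, origins=origins, patch_size=4, source_shape=6)
        out = reassemble(ps)
        np.testing.assert_array_equal(out.data[:2], np.full((2, 6, 6), 1.0, np.float32))
        np.testing.assert_array_equal(out.data[2:4], np.full((2, 6, 6), 2.0, np.float32))
        np.testing.assert_array_equal(out.data[4:], np.full((2, 6, 6), 3.0, np.float32))

    def test_single_patch_roundtrip(self, rng):
        v = _vol(rng.random((8, 8, 8)))
        out = reassemble(extract_patches(v, 8, 8))
        np.testing.assert_array_equal(out.data.astype(np.float32), v.data)

    def test_inconsistent_patch_shape_rejected(self):
        from fusegan.preprocessing import PatchSet

        ps = PatchSet(
            patches=[np.zeros((3, 3, 3))], origins=[(0, 0, 0)], patch_size=4,
            source_shape=4,
        )
        with pytest.raises(GeometryError):
            reassemble(ps)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(
        SyntheticConfig(
            volume_size=8, n_paired_per_class=20, n_unpaired_per_class=3,
            lesion_regions=[((4, 4, 4), 2)], seed=2,
        )
    )


class TestFolds:

    def test_stratified_sizes(self, cohort):
        plan = make_folds(cohort, 10, "incomplete", seed=0)
        for label in (0, 1):
            sizes = [
                sum(
                    1
                    for s in cohort.paired
                    if s.label == label and plan.assignments[s.subject_id] == f
                )
                for f in range(10)
            ]
            assert sizes == [2] * 10

    def test_unpaired_tagged_test_in_incomplete_protocol(self, cohort):
        plan = make_folds(cohort, 10, "incomplete", seed=0)
        assign_split_tags(cohort, plan, validation_fold=0)
        assert all(s.split_tag == "test" for s in cohort.unpaired)
        tags = {s.split_tag for s in cohort.paired}
        assert tags == {"train", "validation"}

    def test_complete_protocol_holdout_split(self, cohort):
        plan = make_folds(cohort, 4, "complete", seed=0)
        assign_split_tags(cohort, plan, validation_fold=1)
        holdout = [s for s in cohort if plan.assignments[s.subject_id] == 1]
        for s in holdout:
            assert s.split_tag == ("validation" if s.has_pet else "test")

    def test_same_seed_same_assignments(self, cohort):
        a = make_folds(cohort, 5, "incomplete", seed=9)
        b = make_folds(cohort, 5, "incomplete", seed=9)
        assert a.assignments == b.assignments

    def test_too_small_class_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            make_folds(tiny_cohort, 10, "incomplete", seed=0)

    def test_plan_csv(self, cohort, tmp_path):
        plan = make_folds(cohort, 5, "incomplete", seed=1)
        assign_split_tags(cohort, plan)
        path = plan.to_csv(tmp_path / "folds.csv", cohort)
        lines = path.read_text().strip().splitlines()
        assert len(lines) - 1 == len(cohort.paired)


class TestFlips:
    def test_probability_zero_is_identity(self, rng):
        v = _vol(rng.random((6, 6, 6)))
        out = augment_flip(v, probability=0.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.data, v.data)

    def test_double_flip_is_involution(self, rng):
        v = _vol(rng.random((6, 6, 6)))
        flip_rng = np.random.default_rng(1)
        once = augment_flip(v, probability=1.0, rng=flip_rng)
        twice = augment_flip(once, probability=1.0, rng=flip_rng)
        np.testing.assert_array_equal(twice.data, v.data)

    def test_pair_flipped_identically(self, rng):
        mri = _vol(rng.random((6, 6, 6)))
        pet = _vol(rng.random((6, 6, 6)), "PET")
        m, p = augment_flip_pair(mri, pet, probability=0.5, rng=np.random.default_rng(3))
        # whatever flips happened to MRI also happened to PET: flipping back
        # with the same axes must recover both originals simultaneously
        for axes in itertools.chain.from_iterable(
            itertools.combinations((0, 1), r) for r in range(3)
        ):
            if np.array_equal(np.flip(m.data, axes), mri.data):
                np.testing.assert_array_equal(np.flip(p.data, axes), pet.data)
                break
        else:
            pytest.fail("MRI flip not an axis flip of the original")

    def test_fixed_rng_reproducible(self, rng):
        v = _vol(rng.random((6, 6, 6)))
        a = augment_flip(v, probability=0.5, rng=np.random.default_rng(7))
        b = augment_flip(v, probability=0.5, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.data, b.data)
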