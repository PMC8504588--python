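"""Sub-target division rules: length limits, look-up table, tiling
invariants, pediatric and large-patient adjustments."""

import numpy as np
import pytest

import tbiplan as tp
from tbiplan.segmentation import (
    SegmentationParams,
    appa_length_lookup,
    compute_vmat_limit,
    divide_ptv,
)


class TestVmatLimit:
    def test_machine_constraint_derivation(self):
        # MLC travel 14.5 cm, split arcs, 5 mm margin/side, 5 cm feathering
        field, opt, sub = compute_vmat_limit(14.5, 0.5, 5.0)
        assert (field, opt, sub) == (29.0, 28.0, 23.0)

    def test_zero_margins(self):
        assert tuple(compute_vmat_limit(10.0, 0.0, 0.0)) == (20.0, 20.0, 20.0)

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValueError, match="not positive"):
            compute_vmat_limit(14.5, 0.5, 28.0)


def brute_force_lookup(remaining, params):
    best = None
    for count in range(1, 50):
        for length in params.appa_allowed_lengths:
            if count * length >= remaining + params.feet_margin_min - 1e-9:
                cand = (count, length)
                if best is None or cand < best:
                    best = cand
    return best[1], best[0]


class TestAppaLookup:
    @pytest.mark.parametrize(
        "remaining,expected",
        [(45.0, (25.0, 2)), (65.0, (35.0, 2)), (20.0, (25.0, 1))],
    )
    def test_documented_cases(self, remaining, expected):
        assert appa_length_lookup(remaining, SegmentationParams()) == expected

    def test_agrees_with_exhaustive_search(self):
        params = SegmentationParams()
        for remaining in range(1, 201):
            assert appa_length_lookup(float(remaining), params) == brute_force_lookup(
                float(remaining), params
            ), remaining

    def test_rejects_nonpositive_remainder(self):
        with pytest.raises(ValueError):
            appa_length_lookup(0.0, SegmentationParams())


class TestBuildPtv:
    def test_missing_structure_named(self, adult_case):
        from tbiplan.volumes import StructureSet

        st = adult_case["structures"]
        partial = StructureSet(st.grid, {"body": st.masks["body"], "lungs": st.masks["lungs"]})
        with pytest.raises(ValueError, match="kidneys"):
            tp.build_ptv(partial, adult_case["params"])

    def test_zero_contraction_is_set_difference(self, adult_case):
        st = adult_case["structures"]
        params = SegmentationParams(skin_contraction=0.0)
        ptv = tp.build_ptv(st, params)
        expected = st.masks["body"] & ~st.masks["lungs"] & ~st.masks["kidneys"]
        assert np.array_equal(ptv, expected)

    def test_default_ptv_excludes_organs_and_respects_skin_distance(self, adult_case):
        from scipy import ndimage

        st = adult_case["structures"]
        ptv = adult_case["ptv"]
        assert not (ptv & st.masks["lungs"]).any()
        assert not (ptv & st.masks["kidneys"]).any()
        dist = ndimage.distance_transform_edt(st.masks["body"], sampling=st.grid.spacing)
        assert dist[ptv].min() >= adult_case["params"].skin_contraction


def check_partition(sts):
    """The partition property: contiguous tiling, 5 cm opt overlaps, equal
    AP/PA lengths, feet margin, collinear points."""
    sts.validate()
    subs = sts.subtargets
    h = sts.params.ofz_halfwidth_mm
    for a, b in zip(subs, subs[1:]):
        assert a.z_interval[0] == pytest.approx(b.z_interval[1], abs=1e-6)
        overlap = b.opt_interval[1] - a.opt_interval[0]
        assert overlap == pytest.approx(2 * h, abs=1e-6)
    appa = [s for s in subs if s.kind == "APPA"]
    if appa:
        lengths = {round(s.length_mm, 3) for s in appa}
        assert len(lengths) == 1
        feet = sts.ptv_z_extent[0]
        assert appa[-1].z_interval[0] <= feet - 10.0 * sts.params.feet_margin_min + 1e-6
    xs = {round(p[0], 6) for p in [s.isocenter for s in subs] + list(sts.junction_points)}
    ys = {round(p[1], 6) for p in [s.isocenter for s in subs] + list(sts.junction_points)}
    assert len(xs) == 1 and len(ys) == 1


class TestDividePtv:
    def test_adult_subtarget_count(self, adult_case):
        sts = adult_case["subtargets"]
        kinds = [s.kind for s in sts.subtargets]
        assert len(kinds) in (7, 8)
        n_appa = kinds.count("APPA")
        assert n_appa in (2, 3)
        assert all(k == "APPA" for k in kinds[-n_appa:])

    def test_partition_invariants(self, adult_case):
        check_partition(adult_case["subtargets"])

    def test_isocenters_at_subtarget_centers(self, adult_case):
        for s in adult_case["subtargets"].subtargets:
            assert s.isocenter[2] == pytest.approx(
                0.5 * (s.z_interval[0] + s.z_interval[1]), abs=1e-6
            )

    def test_junction_points_at_overlap_centers(self, adult_case):
        sts = adult_case["subtargets"]
        for (a, b), p in zip(zip(sts.subtargets, sts.subtargets[1:]), sts.junction_points):
            assert p[2] == pytest.approx(a.z_interval[0], abs=1e-6)

    def test_trunk_only_toy_is_all_vmat(self, adult_case):
        st = adult_case["structures"]
        ptv = adult_case["ptv"].copy()
        zc = st.grid.axis_coords(2)
        legs_top = st.landmarks["legs_top"]
        ptv[:, :, zc < legs_top + 50.0] = False  # keep trunk and head only
        sts = divide_ptv(ptv, st.grid, st.landmarks, adult_case["params"])
        assert all(s.kind == "VMAT" for s in sts.subtargets)
        assert sts.subtargets[-1].z_interval[0] == pytest.approx(
            sts.ptv_z_extent[0], abs=1e-6
        )

    def test_long_head_subtarget_rejected(self, adult_case):
        st = adult_case["structures"]
        landmarks = dict(st.landmarks)
        landmarks["neck_bottom"] = landmarks["head_top"] - 300.0  # 30 cm head
        with pytest.raises(ValueError, match="head sub-target"):
            divide_ptv(adult_case["ptv"], st.grid, landmarks, adult_case["params"])

    def test_missing_landmark_rejected(self, adult_case):
        st = adult_case["structures"]
        with pytest.raises(ValueError, match="legs_top"):
            divide_ptv(
                adult_case["ptv"], st.grid,
                {k: v for k, v in st.landmarks.items() if k != "legs_top"},
                adult_case["params"],
            )

    def test_partition_holds_on_random_phantoms(self):
        """Tiling/overlap/margin/collinearity across the supported size range."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            h = float(rng.uniform(120.0, 200.0))
            spec = tp.PhantomSpec.default_adult(h, seed=int(rng.integers(1 << 16)),
                                                voxel_spacing=(7.5, 7.5, 5.0))
            vol, st = tp.generate_phantom(spec)
            params = SegmentationParams()
            ptv = tp.build_ptv(st, params)
            sts = divide_ptv(ptv, st.grid, st.landmarks, params)
            check_partition(sts)


def pediatric_case(gap_scale=1.0, h=140.0, seed=2):
    spec = tp.PhantomSpec.default_pediatric(
        h, seed=seed, voxel_spacing=(5.0, 5.0, 5.0),
        lung_center_z=0.215 * h, lung_length=0.11 * h,
        kidney_center_z=0.065 * h + (1.0 - gap_scale) * 0.05 * h,
        kidney_length=0.05 * h,
    )
    vol, st = tp.generate_phantom(spec)
    params = SegmentationParams()
    ptv = tp.build_ptv(st, params)
    sts = divide_ptv(ptv, st.grid, st.landmarks, params)
    return st, sts


class TestPediatricAdjust:
    def test_junction_overlap_lands_in_gap(self):
        st, sts = pediatric_case()
        adjusted = tp.pediatric_adjust(sts, st)
        check_partition(adjusted)
        lung_lo, _ = st.mask_z_extent("lungs")
        _, kid_hi = st.mask_z_extent("kidneys")
        h = adjusted.params.ofz_halfwidth_mm
        assert any(
            kid_hi - 1e-6 <= z - h and z + h <= lung_lo + 1e-6
            for z in adjusted.junction_z()
        )
        # lengths never increased
        for a, b in zip(sts.subtargets, adjusted.subtargets):
            if a.kind == b.kind == "VMAT":
                assert b.length_mm <= a.length_mm + 1e-6

    def test_small_gap_rejected(self):
        st, sts = pediatric_case(gap_scale=0.2)  # < 5 cm lung-kidney gap
        with pytest.raises(ValueError, match="gap"):
            tp.pediatric_adjust(sts, st)

    def test_adult_flag_is_noop(self):
        st, sts = pediatric_case()
        assert tp.pediatric_adjust(sts, st, is_pediatric=False) is sts


class TestLargePatientAdjust:
    def test_triggered_reduction_retiles(self, adult_case):
        sts = adult_case["subtargets"]
        adjusted = tp.large_patient_adjust(sts, arm_extent_cm=45.0, reduction_cm=2.0)
        check_partition(adjusted)
        before = [s.length_mm for s in sts.subtargets if s.kind == "VMAT"][1:]
        after = [s.length_mm for s in adjusted.subtargets if s.kind == "VMAT"][1:]
        assert all(b == pytest.approx(a - 20.0) for a, b in zip(before, after))

    def test_below_threshold_is_noop(self, adult_case):
        sts = adult_case["subtargets"]
        assert tp.large_patient_adjust(sts, arm_extent_cm=38.0) is sts

    def test_invalid_reduction_rejected(self, adult_case):
        with pytest.raises(ValueError, match="1-2 cm"):
            tp.large_patient_adjust(adult_case["subtargets"], 45.0, reduction_cm=3.0)
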