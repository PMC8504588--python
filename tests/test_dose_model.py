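"""Dose engine closed forms, beam constructors, weight optimization, DVH."""

import math

import numpy as np
import pytest

from tbiplan.dose_model import (
    Beam,
    BeamSegment,
    PhysicsConstants,
    compute_beam_dose,
    compute_dvh,
    lung_dose_rate,
    make_feathered_appa,
    make_step_wedge,
    optimize_segment_weights,
    vmat_surrogate_dose,
)
from tbiplan.segmentation import SubTarget
from tbiplan.volumes import DoseGrid


def open_beam(mu=100.0, gantry=0.0, energy=6, half_cm=10.0):
    return Beam(
        isocenter=(0.0, 0.0, 0.0),
        gantry=gantry,
        collimator=90.0,
        energy=energy,
        mu=mu,
        segments=[BeamSegment((-half_cm, half_cm, -half_cm, half_cm), 1.0)],
    )


class TestEngine:
    def test_mu_linearity(self, water_slab):
        d1 = compute_beam_dose(open_beam(100.0), water_slab)
        d2 = compute_beam_dose(open_beam(200.0), water_slab)
        assert np.array_equal(d2.values, 2.0 * d1.values)

    def test_depth_dose_matches_closed_form(self, water_slab):
        """Beyond dmax the central-axis ratio between two depths is the
        exponential attenuation times the inverse-square factor."""
        c = PhysicsConstants()
        dg = compute_beam_dose(open_beam(), water_slab, c)
        g = dg.grid
        ix, iz = g.shape[0] // 2, g.shape[2] // 2
        ys = g.axis_coords(1)
        prof = dg.values[ix, :, iz]
        depth = 100.0 - ys  # entry surface at y = +100 mm for an AP beam
        i1, i2 = 10, 30
        sad = 1000.0
        expected = math.exp(-c.mu_eff_per_cm[6] / 10.0 * (depth[i1] - depth[i2]))
        expected *= ((sad - 100.0 + depth[i2]) / (sad - 100.0 + depth[i1])) ** 2
        assert prof[i1] / prof[i2] == pytest.approx(expected, rel=1e-6)

    def test_opposed_beams_symmetric_about_midplane(self, water_slab):
        ap = compute_beam_dose(open_beam(gantry=0.0), water_slab)
        pa = compute_beam_dose(open_beam(gantry=180.0), water_slab)
        tot = (ap + pa).values
        g = ap.grid
        mid = tot[g.shape[0] // 2, :, g.shape[2] // 2]
        assert np.allclose(mid, mid[::-1], rtol=1e-6)

    def test_beam_missing_volume_warns_and_zeroes(self, water_slab):
        b = Beam(
            isocenter=(0.0, 0.0, 5000.0),  # far above the slab
            gantry=0.0,
            collimator=90.0,
            mu=100.0,
            segments=[BeamSegment((-1.0, 1.0, -1.0, 1.0), 1.0)],
        )
        with pytest.warns(UserWarning, match="misses"):
            dg = compute_beam_dose(b, water_slab)
        assert not dg.values.any()

    def test_dose_additivity(self, water_slab):
        beams = [open_beam(gantry=g) for g in (0.0, 180.0)]
        total = DoseGrid.zeros(compute_beam_dose(beams[0], water_slab).grid)
        parts = []
        for b in beams:
            parts.append(compute_beam_dose(b, water_slab, grid=total.grid))
            total = total + parts[-1]
        assert np.array_equal(total.values, parts[0].values + parts[1].values)


def appa_subtarget(lo_cm, hi_cm, index=6):
    lo, hi = lo_cm * 10.0, hi_cm * 10.0
    return SubTarget(
        index=index,
        kind="APPA",
        z_interval=(lo, hi),
        opt_interval=(lo - 25.0, hi + 25.0),
        isocenter=(0.0, 0.0, 0.5 * (lo + hi)),
    )


class TestFeatheredAppa:
    def test_segments_are_nested_intervals(self):
        ap, pa = make_feathered_appa(appa_subtarget(-30.0, 0.0))
        for b in (ap, pa):
            edges = [s.aperture[:2] for s in b.segments]
            for (a1, a2), (b1, b2) in zip(edges, edges[1:]):
                assert b1 >= a1 and b2 <= a2  # each contained in the previous
        assert ap.gantry == 0.0 and pa.gantry == 180.0
        assert ap.collimator == 90.0 and ap.energy == 6
        assert len(ap.segments) == 3

    def test_last_subtarget_inferior_edge_at_max_opening(self):
        ap, _ = make_feathered_appa(appa_subtarget(-30.0, 0.0), is_last=True)
        for s in ap.segments:
            assert s.aperture[0] == -20.0  # cm from the isocenter

    def test_rejects_vmat_subtarget(self):
        st = SubTarget(1, "VMAT", (0.0, 230.0), (-25.0, 230.0), (0.0, 0.0, 115.0))
        with pytest.raises(ValueError, match="AP/PA"):
            make_feathered_appa(st)

    def test_feathering_spans_junction(self):
        """Fluence steps 1 -> 2/3 -> 1/3 -> 0 in half-feather steps across
        the 5 cm zone at a junction-facing end."""
        ap, _ = make_feathered_appa(appa_subtarget(-30.0, 0.0))
        iso_z = -150.0

        def fluence(z_mm):
            f = 0.0
            for s in ap.normalized_segments():
                x1, x2 = s.aperture[0] * 10.0, s.aperture[1] * 10.0
                if x1 <= z_mm - iso_z <= x2:
                    f += s.relative_weight
            return f

        assert fluence(30.0) == 0.0
        assert fluence(12.5) == pytest.approx(1 / 3)
        assert fluence(-12.5) == pytest.approx(2 / 3)
        assert fluence(-30.0) == pytest.approx(1.0)


class TestStepWedge:
    def test_nine_gantries_forty_apart(self):
        beams = make_step_wedge((0.0, 0.0, 0.0))
        assert [b.gantry for b in beams] == [i * 40.0 for i in range(9)]
        assert all(len(b.segments) == 5 for b in beams)

    def test_staircase_fluence_profile(self):
        """Five equal levels over the 5 cm junction, monotone toward the
        ascending side."""
        b = make_step_wedge((0.0, 0.0, 0.0), ascending="inferior")[0]
        levels = []
        for z in (-20.0, -10.0, 0.0, 10.0, 20.0):
            f = sum(
                s.relative_weight
                for s in b.normalized_segments()
                if s.aperture[0] * 10.0 <= z <= s.aperture[1] * 10.0
            )
            levels.append(round(f, 6))
        assert levels == [1.0, 0.8, 0.6, 0.4, 0.2]

    def test_summed_dose_monotone_across_junction(self, water_cylinder):
        beams = make_step_wedge((0.0, 0.0, 0.0), mu=900.0)
        total = None
        for b in beams:
            dg = compute_beam_dose(b, water_cylinder)
            total = dg if total is None else total + dg
        zc, col = total.column(0.0, 0.0)
        sel = (zc >= -25.0) & (zc <= 25.0)
        ramp = col[sel]
        assert np.all(np.diff(ramp) <= 1e-9)  # ascending toward inferior
        assert ramp[0] > ramp[-1] > 0.0


class TestOptimizeSegmentWeights:
    def test_single_segment_reaches_prescription(self, water_slab):
        b = open_beam()
        target = np.zeros(compute_beam_dose(b, water_slab).grid.shape, dtype=bool)
        g = compute_beam_dose(b, water_slab).grid
        # a thin mid-depth slab the open beam covers uniformly
        target[g.shape[0] // 2 - 2 : g.shape[0] // 2 + 2, g.shape[1] // 2, g.shape[2] // 2] = True
        out, w = optimize_segment_weights([b], target, water_slab, rx=2.0, grid=g)
        assert out[0].segments[0].relative_weight == pytest.approx(1.0)
        dg = compute_beam_dose(out[0], water_slab, grid=g)
        assert dg.values[target].mean() == pytest.approx(2.0, rel=1e-3)

    def test_two_symmetric_segments_get_equal_weights(self, water_slab):
        b = Beam(
            isocenter=(0.0, 0.0, 0.0),
            gantry=0.0,
            collimator=90.0,
            mu=100.0,
            segments=[
                BeamSegment((-10.0, -1.0, -10.0, 10.0), 1.0),
                BeamSegment((1.0, 10.0, -10.0, 10.0), 1.0),
            ],
        )
        grid = compute_beam_dose(b, water_slab).grid
        zc = grid.axis_coords(2)
        target = np.zeros(grid.shape, dtype=bool)
        mid = (grid.shape[0] // 2, grid.shape[1] // 2)
        target[mid[0], mid[1], (np.abs(zc) > 20.0) & (np.abs(zc) < 80.0)] = True
        out, w = optimize_segment_weights([b], target, water_slab, rx=2.0, grid=grid)
        assert out[0].segments[0].relative_weight == pytest.approx(
            out[0].segments[1].relative_weight, rel=1e-6
        )

    def test_objective_never_worse_than_equal_weights(self, water_cylinder):
        ap, pa = make_feathered_appa(appa_subtarget(-30.0, 0.0))
        grid = compute_beam_dose(ap, water_cylinder).grid
        zc = grid.axis_coords(2)
        target = np.zeros(grid.shape, dtype=bool)
        body = water_cylinder.values > -350.0
        from tbiplan.volumes import resample_to_grid, ImageVolume

        body_d = resample_to_grid(
            ImageVolume(water_cylinder.grid, body.astype(float)), grid, order=0, cval=0
        ).values > 0.5
        target[body_d & (zc[None, None, :] > -250) & (zc[None, None, :] < -50)] = True
        out, w = optimize_segment_weights(
            [ap, pa], target, water_cylinder, rx=2.0, grid=grid,
            max_points=int(target.sum()),
        )

        def objective(beams):
            total = DoseGrid.zeros(grid)
            for b in beams:
                total = total + compute_beam_dose(b, water_cylinder, grid=grid)
            return float(np.sum((total.values[target] - 2.0) ** 2))

        # equal weights at the best overall scale
        eq = [
            Beam(
                isocenter=b.isocenter, gantry=b.gantry, collimator=b.collimator,
                energy=b.energy, mu=1.0, segments=[
                    BeamSegment(s.aperture, 1.0) for s in b.segments
                ],
            )
            for b in (ap, pa)
        ]
        unit = DoseGrid.zeros(grid)
        for b in eq:
            unit = unit + compute_beam_dose(b, water_cylinder, grid=grid)
        u = unit.values[target]
        scale = float(u @ np.full_like(u, 2.0) / (u @ u))
        obj_eq = float(np.sum((scale * u - 2.0) ** 2))
        assert objective(out) <= obj_eq + 1e-9

    def test_all_zero_target_rejected(self, water_slab):
        b = open_beam()
        grid = compute_beam_dose(b, water_slab).grid
        # target fully outside the aperture -> zero columns -> zero solution
        target = np.zeros(grid.shape, dtype=bool)
        target[0, 0, -1] = True
        with pytest.raises(ValueError, match="zero"):
            optimize_segment_weights([b], target, water_slab, rx=2.0, grid=grid)


def vmat_subtarget(lo_cm=-10.0, hi_cm=13.0):
    lo, hi = lo_cm * 10.0, hi_cm * 10.0
    return SubTarget(
        index=2, kind="VMAT",
        z_interval=(lo, hi), opt_interval=(lo - 25.0, hi + 25.0),
        isocenter=(0.0, 0.0, 0.5 * (lo + hi)),
    )


class TestVmatSurrogate:
    def test_zero_base_gives_uniform_rx(self, water_slab):
        st = vmat_subtarget()
        dg = vmat_surrogate_dose(st, None, 2.0, water_slab)
        zc = dg.grid.axis_coords(2)
        inside = (zc > st.opt_interval[0] + 5.0) & (zc < st.opt_interval[1] - 5.0)
        mid = dg.values[dg.grid.shape[0] // 2, dg.grid.shape[1] // 2, :]
        assert np.allclose(mid[inside], 2.0)
        assert np.all(mid[zc > st.opt_interval[1] + 5.0] == 0.0)

    def test_base_exceeding_rx_rejected(self, water_slab):
        st = vmat_subtarget()
        grid = vmat_surrogate_dose(st, None, 2.0, water_slab).grid
        base = DoseGrid(grid, np.full(grid.shape, 2.5))
        with pytest.raises(ValueError, match="exceeds"):
            vmat_surrogate_dose(st, base, 2.0, water_slab, grid=grid)

    def test_complement_of_linear_wedge(self, water_slab):
        """Surrogate z-profile descends as the complement of an ascending
        wedge so that their sum is the prescription."""
        from tbiplan.planning import linear_junction_base

        st = vmat_subtarget()
        rx = 2.0
        grid = vmat_surrogate_dose(st, None, rx, water_slab).grid
        zc = grid.axis_coords(2)
        base_z = linear_junction_base(zc, st.z_interval[0], "inferior", rx)
        base = DoseGrid(grid, np.broadcast_to(base_z, grid.shape).copy())
        dg = vmat_surrogate_dose(st, base, rx, water_slab, grid=grid)
        mid = dg.values[grid.shape[0] // 2, grid.shape[1] // 2, :]
        sel = (zc >= st.opt_interval[0]) & (zc <= st.z_interval[0] + 25.0)
        assert np.allclose(mid[sel] + base_z[sel], rx, atol=1e-9)


class TestDvh:
    def test_uniform_prescription(self, water_slab):
        g = compute_beam_dose(open_beam(), water_slab).grid
        mask = np.ones(g.shape, dtype=bool)
        dose = DoseGrid(g, np.full(g.shape, 2.0))
        m = compute_dvh(dose, mask, rx=2.0)
        assert m.vx[100] == 100.0 and m.vx[110] == 0.0
        assert m.dmean_gy == pytest.approx(2.0)

    def test_constructed_half_hot(self, water_slab):
        g = compute_beam_dose(open_beam(), water_slab).grid
        mask = np.ones(g.shape, dtype=bool)
        vals = np.zeros(g.shape)
        vals[: g.shape[0] // 2] = 2.4  # half at 1.2 rx, half at 0
        dose = DoseGrid(g, vals)
        m = compute_dvh(dose, mask, rx=2.0)
        frac = 100.0 * (g.shape[0] // 2) / g.shape[0]
        assert m.vx[100] == pytest.approx(frac)
        assert m.vx[110] == pytest.approx(frac)
        assert m.dmean_gy == pytest.approx(1.2 * frac / 100.0 * 2.0)

    def test_vx_monotone_and_matches_brute_force(self, water_slab):
        rng = np.random.default_rng(11)
        g = compute_beam_dose(open_beam(), water_slab).grid
        levels = (90, 95, 100, 110)
        for _ in range(20):
            vals = rng.uniform(0.0, 3.0, g.shape)
            mask = rng.random(g.shape) > 0.5
            m = compute_dvh(DoseGrid(g, vals), mask, rx=2.0, levels=levels)
            brute = {
                x: 100.0 * np.sum(vals[mask] >= x / 100.0 * 2.0) / np.sum(mask)
                for x in levels
            }
            for x in levels:
                assert m.vx[x] == pytest.approx(brute[x], abs=0.0)
            ordered = [m.vx[x] for x in sorted(levels)]
            assert all(a >= b for a, b in zip(ordered, ordered[1:]))

    def test_misaligned_grids_rejected(self, water_slab):
        g = compute_beam_dose(open_beam(), water_slab).grid
        with pytest.raises(ValueError, match="match"):
            compute_dvh(DoseGrid(g, np.zeros(g.shape)), np.ones((2, 2, 2), bool), 2.0)

    def test_empty_mask_rejected(self, water_slab):
        g = compute_beam_dose(open_beam(), water_slab).grid
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(DoseGrid(g, np.zeros(g.shape)), np.zeros(g.shape, bool), 2.0)


class TestLungDoseRate:
    def test_halving_mu_rate_halves_nothing_but_rate(self):
        beams = [open_beam(mu=1650.0)]
        beams[0].mu_rate = 200.0
        r200 = lung_dose_rate(beams, lung_dose_per_fraction_gy=1.25)
        beams[0].mu_rate = 100.0
        r100 = lung_dose_rate(beams, lung_dose_per_fraction_gy=1.25)
        assert r100 == pytest.approx(r200 / 2.0)

    def test_zero_mu_rejected(self):
        b = open_beam(mu=0.0)
        with pytest.raises(ValueError, match="beam-on"):
            lung_dose_rate([b], 1.25)

    def test_no_beams_rejected(self):
        with pytest.raises(ValueError, match="no lung"):
            lung_dose_rate([], 1.25)
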