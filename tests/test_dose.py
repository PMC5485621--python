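"""Dose engine: calibration, ray tracing, beam model, optimization, plans."""

import numpy as np
import pytest

from synctplan.dose import (
    BeamSpec,
    CalibrationCurve,
    EngineConfig,
    Objectives,
    PlanSpec,
    beam_dose,
    compose_plan,
    equispaced_beams,
    hu_to_density,
    normalize_plan,
    optimize_weights,
    radiological_depth,
    recompute_on,
    unit_beam_doses,
)
from synctplan.grid import StructureSet, VolumeGrid
from synctplan.synct import CTVolume

PARALLEL = EngineConfig(mode="parallel")


def _water(shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0), rho=1.0):
    return VolumeGrid(np.full(shape, rho), spacing)


class TestCalibrationCurve:
    def test_water_and_air_conventions(self):
        c = CalibrationCurve()
        assert c.density(np.array([0.0]))[0] == 1.0
        assert c.density(np.array([-1000.0]))[0] == pytest.approx(0.0, abs=1e-9)

    def test_linear_between_control_points(self):
        c = CalibrationCurve(points=((-1024, 0.0), (0, 1.0), (3071, 2.0)))
        assert c.density(np.array([-512.0]))[0] == pytest.approx(0.5, rel=1e-9)

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            CalibrationCurve(points=((-1024, 0.0), (-1024, 0.1), (3071, 2.0)))
        with pytest.raises(ValueError, match="non-negative"):
            CalibrationCurve(points=((-1024, 0.5), (0, 0.1), (3071, 2.0)))
        with pytest.raises(ValueError, match="cover"):
            CalibrationCurve(points=((0, 0.0), (100, 1.0)))

    def test_clamped_at_ends(self):
        c = CalibrationCurve()
        assert c.density(np.array([5000.0]))[0] == c.density(np.array([3071.0]))[0]


class TestRadiologicalDepth:
    def test_three_voxel_closed_form(self):
        dens = VolumeGrid(np.array([1.0, 0.25, 1.0]).reshape(3, 1, 1), (1, 1, 1))
        p = radiological_depth(dens, (-5.0, 0.5, 0.5), (1, 0, 0))
        assert p.total_weq == pytest.approx(2.25, abs=1e-12)

    def test_uniform_density_equals_geometric_depth(self):
        dens = _water((20, 20, 20), (2.5, 2.5, 2.5))
        p = radiological_depth(dens, (-10.0, 25.0, 25.0), (1, 0, 0))
        assert p.total_weq == pytest.approx(50.0, abs=1e-9)

    def test_oblique_ray_through_slab(self):
        dens = VolumeGrid(np.ones((40, 40, 1)), (1.0, 1.0, 1.0))
        p = radiological_depth(dens, (-5.0, 10.0, 0.5), (1, 1, 0))
        assert p.total_weq == pytest.approx(25.0 * np.sqrt(2), rel=1e-9)

    def test_matches_fine_step_integration(self):
        rng = np.random.default_rng(0)
        dens = VolumeGrid(rng.uniform(0, 2, (24, 24, 24)), (1.7, 2.1, 2.5))
        g0, sp = np.zeros(3), np.array(dens.spacing)

        def fine(o, d, step=0.01):
            d = np.asarray(d) / np.linalg.norm(d)
            ts = np.arange(0.0, 160.0, step)
            pts = np.asarray(o)[None] + ts[:, None] * d[None]
            idx = np.floor((pts - g0) / sp).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(dens.shape)), axis=1)
            return dens.values[idx[ok, 0], idx[ok, 1], idx[ok, 2]].sum() * step

        for _ in range(50):
            o = rng.uniform(-30, -5, 3)
            d = rng.uniform(0.2, 1.0, 3)
            exact = radiological_depth(dens, o, d).total_weq
            approx = fine(o, d)
            if approx > 1.0:
                assert abs(exact - approx) / approx < 0.005

    def test_ray_missing_grid_is_empty(self):
        dens = _water((5, 5, 5))
        p = radiological_depth(dens, (-100.0, -100.0, 0.0), (0, 0, 1))
        assert p.empty and p.total_weq == 0.0

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            radiological_depth(_water(), (0, 0, 0), (0, 0, 0))


class TestBeamDose:
    def test_water_depth_dose_exponential(self):
        water = _water()
        beam = BeamSpec(0.0, (40.0, 40.0, 40.0), (60.0, 60.0))
        dose = beam_dose(beam, water, PARALLEL)
        y = water.voxel_centers(1)
        axis = dose.values[20, :, 20]
        for i, j in ((8, 20), (10, 30), (5, 35)):
            ratio = axis[j] / axis[i]
            expect = np.exp(-PARALLEL.mu_eff_per_mm * (y[j] - y[i]))
            assert abs(ratio / expect - 1) < 1e-3

    def test_linear_in_weight(self):
        water = _water((24, 24, 24))
        b1 = BeamSpec(30.0, (24.0, 24.0, 24.0), (40.0, 40.0), weight=1.0)
        b2 = BeamSpec(30.0, (24.0, 24.0, 24.0), (40.0, 40.0), weight=2.0)
        d1, d2 = beam_dose(b1, water, PARALLEL), beam_dose(b2, water, PARALLEL)
        assert np.allclose(d2.values, 2.0 * d1.values)

    def test_lung_slab_transmits_more_than_water(self):
        shape, sp = (24, 40, 24), (2.0, 2.0, 2.0)
        water = VolumeGrid(np.ones(shape), sp)
        lung = water.copy()
        lung.values[:, 10:30, :] = 0.26  # lung-density slab
        beam = BeamSpec(0.0, (24.0, 40.0, 24.0), (40.0, 40.0))
        d_w = beam_dose(beam, water, PARALLEL)
        d_l = beam_dose(beam, lung, PARALLEL)
        assert d_l.values[12, 35, 12] > d_w.values[12, 35, 12]

    def test_dose_nonnegative_and_zero_outside_wide_field(self):
        water = _water((24, 24, 24))
        beam = BeamSpec(0.0, (24.0, 24.0, 24.0), (20.0, 20.0))
        d = beam_dose(beam, water, PARALLEL)
        assert (d.values >= 0).all()
        # far outside the aperture the penumbra has decayed to nothing
        assert d.values[1, 12, 1] < 1e-4 * d.values[12, 12, 12]


class TestComposePlan:
    def test_single_beam_equals_beam_dose(self):
        water = _water((24, 24, 24))
        plan = PlanSpec(equispaced_beams((24.0, 24.0, 24.0), 1), 60.0, 20.0, 3)
        total = compose_plan(plan, water, PARALLEL)
        single = beam_dose(plan.beams[0], water, PARALLEL)
        assert np.allclose(total.values, single.values)

    def test_opposed_beams_symmetric(self):
        water = _water((31, 31, 31))
        iso = (31.0, 31.0, 31.0)
        plan = PlanSpec([BeamSpec(0.0, iso, (30.0, 30.0)),
                         BeamSpec(180.0, iso, (30.0, 30.0))], 60.0, 20.0, 3)
        dose = compose_plan(plan, water, PARALLEL)
        assert np.allclose(dose.values, dose.values[:, ::-1, :], rtol=1e-3,
                           atol=1e-6 * dose.values.max())

    def test_zero_weights_zero_dose(self):
        water = _water((16, 16, 16))
        plan = PlanSpec(equispaced_beams((16.0, 16.0, 16.0), 3), 60.0, 20.0, 3)
        plan = plan.with_weights([0.0, 0.0, 0.0])
        assert (compose_plan(plan, water, PARALLEL).values == 0).all()

    def test_beam_order_permutation_invariant(self):
        water = _water((16, 16, 16))
        beams = equispaced_beams((16.0, 16.0, 16.0), 3)
        for i, b in enumerate(beams):
            b.weight = 1.0 + i
        p1 = PlanSpec(beams, 60.0, 20.0, 3)
        p2 = PlanSpec(beams[::-1], 60.0, 20.0, 3)
        assert np.allclose(compose_plan(p1, water, PARALLEL).values,
                           compose_plan(p2, water, PARALLEL).values)

    def test_determinism(self):
        water = _water((16, 16, 16))
        plan = PlanSpec(equispaced_beams((16.0, 16.0, 16.0), 5), 59.4, 1.8, 33)
        d1 = compose_plan(plan, water, EngineConfig())
        d2 = compose_plan(plan, water, EngineConfig())
        assert np.array_equal(d1.values, d2.values)


def _box_structures(grid, ptv_slice):
    ptv = np.zeros(grid.shape, np.uint8)
    ptv[ptv_slice] = 1
    return StructureSet({"PTV": grid.with_values(ptv)})


class TestOptimizeWeights:
    def test_single_beam_scalar_solve(self):
        water = _water((24, 24, 24))
        st = _box_structures(water, np.s_[10:14, 10:14, 10:14])
        plan = PlanSpec(equispaced_beams((24.0, 24.0, 24.0), 1), 60.0, 20.0, 3)
        uds = unit_beam_doses(plan, water, PARALLEL)
        out = optimize_weights(plan, water, st, Objectives(ptv_dose_gy=60.0),
                               PARALLEL, unit_doses=uds)
        mean_unit = uds[0].values[st.array("PTV")].mean()
        assert out.beams[0].weight == pytest.approx(60.0 / mean_unit, rel=0.02)

    def test_objectives_already_met_keep_weights(self):
        water = _water((24, 24, 24))
        st = _box_structures(water, np.s_[10:14, 10:14, 10:14])
        plan = PlanSpec(equispaced_beams((24.0, 24.0, 24.0), 1), 60.0, 20.0, 3)
        uds = unit_beam_doses(plan, water, PARALLEL)
        opt = optimize_weights(plan, water, st, Objectives(ptv_dose_gy=60.0),
                               PARALLEL, unit_doses=uds)
        again = optimize_weights(opt, water, st, Objectives(ptv_dose_gy=60.0),
                                 PARALLEL, unit_doses=uds)
        assert np.allclose(again.weights, opt.weights, rtol=1e-6)

    def test_two_beam_normal_equations(self):
        # two-voxel PTV, two beams: the non-negative least-squares solution
        # coincides with the hand-computable 2x2 linear solve
        water = _water((24, 24, 24))
        ptv = np.zeros(water.shape, np.uint8)
        ptv[11, 4, 11] = 1   # on the 0-deg beam axis, outside the 90-deg field
        ptv[4, 11, 11] = 1   # on the 90-deg beam axis, outside the 0-deg field
        st = StructureSet({"PTV": water.with_values(ptv)})
        plan = PlanSpec([BeamSpec(0.0, (24.0, 24.0, 24.0), (20.0, 20.0)),
                         BeamSpec(90.0, (24.0, 24.0, 24.0), (20.0, 20.0))],
                        60.0, 20.0, 3)
        uds = unit_beam_doses(plan, water, PARALLEL)
        A = np.array([[ud.values[11, 4, 11] for ud in uds],
                      [ud.values[4, 11, 11] for ud in uds]])
        expected = np.linalg.solve(A, np.array([60.0, 60.0]))
        assert (expected > 0).all()  # analytic solution is feasible
        out = optimize_weights(plan, water, st, Objectives(ptv_dose_gy=60.0),
                               PARALLEL, unit_doses=uds)
        assert np.allclose(out.weights, expected, rtol=1e-6)

    def test_infeasible_bounds_warn_best_effort(self, caplog):
        water = _water((24, 24, 24))
        ptv = np.zeros(water.shape, np.uint8)
        ptv[10:14, 10:14, 10:14] = 1
        oar = np.zeros(water.shape, np.uint8)
        oar[10:14, 16:20, 10:14] = 1  # directly behind the PTV for beam 0
        st = StructureSet({"PTV": water.with_values(ptv),
                           "spinal_cord": water.with_values(oar)})
        plan = PlanSpec(equispaced_beams((24.0, 24.0, 24.0), 1), 60.0, 20.0, 3)
        with caplog.at_level("WARNING", logger="synctplan.dose"):
            optimize_weights(plan, water, st,
                             Objectives(ptv_dose_gy=60.0,
                                        oar_bounds_gy={"spinal_cord": 1.0}),
                             PARALLEL)
        assert "best-effort" in caplog.text


class TestNormalizePlan:
    def test_scale_factor_is_prescription_over_d95(self):
        grid = VolumeGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        dose = grid.with_values(np.full((10, 10, 10), 50.0))
        ptv = grid.with_values(np.ones((10, 10, 10), np.uint8))
        plan = PlanSpec(equispaced_beams((5.0, 5.0, 5.0), 1), 60.0, 20.0, 3)
        plan2, dose2, s = normalize_plan(plan, dose, ptv)
        assert s == pytest.approx(1.2, rel=1e-12)
        assert np.allclose(dose2.values, 60.0)
        assert plan2.normalization_factor == s

    def test_95pct_coverage_after_normalization(self):
        rng = np.random.default_rng(4)
        grid = VolumeGrid(np.zeros((20, 20, 20)), (1, 1, 1))
        dose = grid.with_values(rng.uniform(40, 70, (20, 20, 20)))
        ptv = grid.with_values(np.ones(grid.shape, np.uint8))
        plan = PlanSpec(equispaced_beams((10.0, 10.0, 10.0), 1), 60.0, 20.0, 3)
        _, dose2, _ = normalize_plan(plan, dose, ptv)
        frac = 100.0 * np.mean(dose2.values >= 60.0 - 1e-9)
        assert frac == pytest.approx(95.0, abs=100.0 / dose.values.size + 0.02)

    def test_normalizing_twice_gives_unit_factor(self):
        grid = VolumeGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        rng = np.random.default_rng(1)
        dose = grid.with_values(rng.uniform(30, 60, grid.shape))
        ptv = grid.with_values(np.ones(grid.shape, np.uint8))
        plan = PlanSpec(equispaced_beams((5.0, 5.0, 5.0), 1), 60.0, 20.0, 3)
        plan, dose, _ = normalize_plan(plan, dose, ptv)
        _, _, s2 = normalize_plan(plan, dose, ptv)
        assert s2 == pytest.approx(1.0, rel=1e-12)

    def test_zero_d95_rejected(self):
        grid = VolumeGrid(np.zeros((5, 5, 5)), (1, 1, 1))
        ptv = grid.with_values(np.ones(grid.shape, np.uint8))
        plan = PlanSpec(equispaced_beams((2.0, 2.0, 2.0), 1), 60.0, 20.0, 3)
        with pytest.raises(ValueError, match="D95"):
            normalize_plan(plan, grid.copy(), ptv)


class TestRecomputeOn:
    def test_same_ct_gives_identical_dose(self):
        water = _water((20, 20, 20))
        ct = CTVolume(water.with_values(np.zeros(water.shape)), "synCT")
        plan = PlanSpec(equispaced_beams((20.0, 20.0, 20.0), 3), 59.4, 1.8, 33)
        curve = CalibrationCurve()
        d1 = recompute_on(plan, ct, curve, PARALLEL)
        d2 = recompute_on(plan, CTVolume(ct.grid.copy(), "planCT"), curve, PARALLEL)
        assert np.array_equal(d1.values, d2.values)

    def test_air_ct_beats_water_ct_along_axis(self):
        shape = (20, 20, 20)
        grid = VolumeGrid(np.zeros(shape), (2.0, 2.0, 2.0))
        water_ct = CTVolume(grid.with_values(np.zeros(shape)), "planCT")
        air_ct = CTVolume(grid.with_values(np.full(shape, -1000.0)), "planCT")
        # a field much wider than the air-broadened penumbra isolates the
        # attenuation term: the unattenuated air beam dominates everywhere
        plan = PlanSpec([BeamSpec(0.0, (20.0, 20.0, 20.0), (300.0, 300.0))],
                        60.0, 20.0, 3)
        curve = CalibrationCurve()
        d_w = recompute_on(plan, water_ct, curve, PARALLEL)
        d_a = recompute_on(plan, air_ct, curve, PARALLEL)
        axis = np.s_[10, 5:18, 10]
        assert (d_a.values[axis] >= d_w.values[axis] - 1e-12).all()
        assert d_a.values[10, 17, 10] > d_w.values[10, 17, 10]

    def test_grid_mismatch_rejected(self):
        water = _water((20, 20, 20))
        other = CTVolume(VolumeGrid(np.zeros((10, 10, 10)), (4.0, 4.0, 4.0)),
                         "planCT")
        plan = PlanSpec(equispaced_beams((20.0, 20.0, 20.0), 1), 60.0, 20.0, 3)
        with pytest.raises(ValueError, match="grid"):
            recompute_on(plan, other, CalibrationCurve(), PARALLEL,
                         reference_grid=water)


def test_plan_spec_fractionation_consistency():
    with pytest.raises(ValueError, match="fx"):
        PlanSpec(equispaced_beams((0, 0, 0), 1), 60.0, 2.0, 33)
    imrt = PlanSpec.imrt((0.0, 0.0, 0.0))
    assert imrt.prescription_gy == pytest.approx(59.40)
    assert (imrt.dose_per_fraction_gy, imrt.n_fractions) == (1.8, 33)
    sbrt = PlanSpec.sbrt((0.0, 0.0, 0.0))
    assert (sbrt.prescription_gy, sbrt.n_fractions) == (60.0, 3)
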