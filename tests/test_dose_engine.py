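"""Dose engine contracts: depth-dose shape, linearity, shift equivariance,
influence consistency, range-scaling behaviour."""

import numpy as np
import pytest

from protonrem.dose_engine import (
    DoseCalculator,
    Plan,
    ScenarioSpec,
    compute_plan_dose,
    depth_dose,
    dose_influence_matrix,
)

from .conftest import single_spot_plan


class TestDepthDose:
    def test_zero_beyond_range_plus_falloff(self):
        assert depth_dose(2 * 50.0 + 9.0, 50.0) == 0.0
        assert depth_dose(50.0 + 9.0, 50.0) == 0.0  # exactly at the cutoff

    def test_peak_lies_at_nominal_range(self):
        d = np.linspace(0.0, 80.0, 4001)
        v = depth_dose(d, 50.0)
        assert abs(d[np.argmax(v)] - 50.0) <= 3.0  # within one falloff sigma

    def test_monotone_decreasing_beyond_peak(self):
        d = np.linspace(50.0, 62.0, 500)
        v = depth_dose(d, 50.0)
        assert np.all(np.diff(v) <= 1e-12)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            depth_dose(-1.0, 50.0)
        with pytest.raises(ValueError):
            depth_dose(10.0, -5.0)

    def test_matches_numba_kernel(self):
        from protonrem._kernels import _bragg

        for d in np.linspace(0.0, 70.0, 97):
            assert depth_dose(d, 55.0) == pytest.approx(_bragg(d, 55.0, 3.0), abs=1e-12)


class TestPlanDose:
    def test_zero_weights_zero_dose(self, uniform_anatomy):
        plan = single_spot_plan(weight=0.0)
        dose = compute_plan_dose(plan, uniform_anatomy)
        assert not np.any(dose.values)

    def test_linearity_in_weights(self, uniform_anatomy):
        d1 = compute_plan_dose(single_spot_plan(weight=1.0), uniform_anatomy)
        d2 = compute_plan_dose(single_spot_plan(weight=2.0), uniform_anatomy)
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_negative_weight_rejected(self, uniform_anatomy):
        plan = single_spot_plan(weight=1.0)
        calc = DoseCalculator(plan, uniform_anatomy)
        with pytest.raises(ValueError):
            calc.dose_values(ScenarioSpec(), weights=np.array([-1.0]))

    def test_rbe_factor_scales_dose(self, uniform_anatomy):
        import dataclasses

        plan = single_spot_plan(weight=1.0)
        base = compute_plan_dose(dataclasses.replace(plan, rbe_factor=1.0), uniform_anatomy)
        rbe = compute_plan_dose(plan, uniform_anatomy)
        np.testing.assert_allclose(rbe.values, 1.1 * base.values, rtol=1e-12)

    def test_lateral_shift_equivariance_on_uniform_medium(self, uniform_anatomy):
        """A pure isocenter shift of +k voxels along a lateral axis equals
        translating the nominal dose grid by k voxels (uniform medium)."""
        plan = single_spot_plan(weight=1.0, gantry=0.0)  # beam along +y
        calc = DoseCalculator(plan, uniform_anatomy)
        h = uniform_anatomy.spacing[0]
        k = 2
        nominal = calc.dose_values(ScenarioSpec())
        for axis in (0, 2):  # x and z are lateral for a 0-degree beam
            shift = [0.0, 0.0, 0.0]
            shift[axis] = k * h
            shifted = calc.dose_values(ScenarioSpec(isocenter_shift=tuple(shift)))
            rolled = np.roll(nominal, -k, axis=axis)
            # exclude the wrap-around edge introduced by roll
            sl = [slice(None)] * 3
            sl[axis] = slice(0, nominal.shape[axis] - k)
            np.testing.assert_allclose(
                shifted[tuple(sl)], rolled[tuple(sl)], atol=1e-9
            )

    def test_along_axis_shift_leaves_dose_unchanged(self, uniform_anatomy):
        # rigid translation along the beam axis does not change WEPL
        plan = single_spot_plan(weight=1.0, gantry=0.0)
        calc = DoseCalculator(plan, uniform_anatomy)
        nominal = calc.dose_values(ScenarioSpec())
        axial = calc.dose_values(ScenarioSpec(isocenter_shift=(0.0, 6.0, 0.0)))
        np.testing.assert_allclose(axial, nominal, atol=1e-12)

    def test_density_scale_moves_peak_monotonically(self, uniform_anatomy):
        """Higher density consumes range faster: the peak sits shallower."""
        plan = single_spot_plan(weight=1.0, gantry=0.0, nominal_range=45.0)
        calc = DoseCalculator(plan, uniform_anatomy)
        depths = []
        for scale in (0.9, 1.0, 1.1):
            dose = calc.dose_values(ScenarioSpec(density_scale=scale))
            profile = dose[12, :, 12]  # central axis, beam along +y
            depths.append(np.argmax(profile))
        assert depths[0] >= depths[1] >= depths[2]
        assert depths[0] > depths[2]

    def test_repaint_factor_does_not_change_static_dose(self, uniform_anatomy):
        import dataclasses

        plan = single_spot_plan(weight=1.0)
        beams5 = [dataclasses.replace(b, repaint_factor=5) for b in plan.beams]
        plan5 = dataclasses.replace(plan, beams=beams5)
        a = compute_plan_dose(plan, uniform_anatomy)
        b = compute_plan_dose(plan5, uniform_anatomy)
        np.testing.assert_array_equal(a.values, b.values)


class TestInfluence:
    def test_single_spot_column_equals_dose(self, uniform_anatomy):
        plan = single_spot_plan(weight=1.0)
        A = dose_influence_matrix(plan, uniform_anatomy)
        dose = compute_plan_dose(plan, uniform_anatomy)
        np.testing.assert_allclose(
            np.asarray(A.todense()).ravel(), dose.values.ravel(), atol=1e-12
        )

    def test_matrix_times_weights_matches_direct(self, small_avg):
        from protonrem.planner import make_plan_template

        plan = make_plan_template(
            small_avg, small_avg.masks["itv"], gantry_angles=(0.0, 30.0),
            prescription=30.0, n_fractions=15, setup_margin_mm=4.0,
        )
        calc = DoseCalculator(plan, small_avg)
        rng = np.random.default_rng(5)
        w = rng.uniform(0.0, 2.0, plan.n_spots)
        for spec in (ScenarioSpec(), ScenarioSpec((3.0, -2.0, 1.0), 0.97)):
            A = calc.influence(spec)
            np.testing.assert_allclose(
                A @ w, calc.dose_values(spec, w).ravel(), atol=1e-9
            )

    def test_row_restriction_matches_full(self, small_avg):
        from protonrem.planner import make_plan_template

        plan = make_plan_template(
            small_avg, small_avg.masks["itv"], gantry_angles=(0.0,),
            prescription=30.0, n_fractions=15, setup_margin_mm=4.0,
        )
        calc = DoseCalculator(plan, small_avg)
        rows = np.flatnonzero(small_avg.masks["heart"].ravel())
        A_full = calc.influence(ScenarioSpec())
        A_rows = calc.influence(ScenarioSpec(), rows=rows)
        np.testing.assert_allclose(
            np.asarray(A_rows.todense()),
            np.asarray(A_full.todense())[rows], atol=1e-14,
        )

    def test_zero_plan_zero_matrix(self, uniform_anatomy):
        plan = single_spot_plan(weight=0.0)
        A = dose_influence_matrix(plan, uniform_anatomy)
        # columns exist regardless of weight; applying zero weights gives zero
        assert (A @ plan.weights == 0).all()


def test_plan_pruning_drops_small_weights(uniform_anatomy):
    from protonrem.dose_engine import Beam, Spot

    spots = [
        Spot((0.0, 0.0), 40.0, weight=1.0),
        Spot((6.0, 0.0), 40.0, weight=1e-6),
        Spot((0.0, 6.0), 40.0, weight=0.5),
    ]
    plan = Plan(
        beams=[Beam(0.0, [(40.0, spots)])], prescription_dose=30.0, n_fractions=15
    )
    kept = plan.pruned(1e-3)
    assert kept.n_spots == 2
    assert set(kept.weights) == {1.0, 0.5}


def test_scenario_validation():
    with pytest.raises(ValueError):
        ScenarioSpec(density_scale=0.0)
    with pytest.raises(ValueError):
        Plan(beams=[], prescription_dose=30.0, n_fractions=0)
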