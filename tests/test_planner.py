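"""Optimizer contracts: closed-form toy, monotone trace, non-negativity,
mimic fixed point and validation."""

import numpy as np
import pytest

from protonrem.dose_engine import DoseCalculator, ScenarioSpec
from protonrem.planner import (
    MimicReference,
    ObjectiveSpec,
    OOITerm,
    SolverOptions,
    dose_mimic,
    make_plan_template,
    robust_optimize,
)
from protonrem.scenarios import ScenarioSet, optimization_scenarios

from .conftest import single_spot_plan


def one_voxel_problem(uniform_anatomy):
    """Single spot, target = the voxel where it deposits the most dose."""
    plan = single_spot_plan(weight=1.0)
    calc = DoseCalculator(plan, uniform_anatomy)
    unit = calc.dose_values(ScenarioSpec(), np.array([1.0]))
    target = np.zeros(unit.shape, bool)
    target[np.unravel_index(np.argmax(unit), unit.shape)] = True
    a = unit.max()  # dose per unit weight at the target voxel
    return plan, target, a


def nominal_only_set(su_label=5.0):
    return ScenarioSet([ScenarioSpec()], su_label, 3.0, "optimization")


class TestRobustOptimize:
    def test_closed_form_single_spot_single_voxel(self, uniform_anatomy):
        plan, target, a = one_voxel_problem(uniform_anatomy)
        obj = ObjectiveSpec(target, prescription=30.0, target_weight=10.0)
        res = robust_optimize(
            plan, uniform_anatomy, obj, nominal_only_set(),
            SolverOptions(max_iter=500, tol=0.0,
                          init_weights=np.array([0.05 * 30.0 / a])),
            hotspot_factor=1.0, overdose_weight=1.0, coverage_margin=1.0,
        )
        assert res.weights[0] == pytest.approx(30.0 / a, rel=1e-4)

    def test_trace_monotone_weights_nonnegative(self, small_avg):
        itv = small_avg.masks["itv"]
        plan = make_plan_template(
            small_avg, itv, gantry_angles=(0.0, 30.0), prescription=30.0,
            n_fractions=15, setup_margin_mm=4.0,
        )
        obj = ObjectiveSpec(
            itv, 30.0, 10.0,
            [OOITerm("heart", small_avg.masks["heart"], 1.0)],
        )
        res = robust_optimize(
            plan, small_avg, obj, optimization_scenarios(4.0, 3.0),
            SolverOptions(max_iter=60, tol=1e-9),
        )
        assert np.all(np.diff(res.objective_trace) <= 1e-9)
        assert np.all(res.weights >= 0.0)
        assert 0 <= res.worst_scenario_index < 21

    def test_mirrored_scenarios_tie_on_symmetric_problem(self, uniform_anatomy):
        """Two mirrored lateral shifts on a symmetric single-spot problem
        produce equal worst-case coverage (tie within tolerance)."""
        from protonrem.planner import _Problem, _d98

        plan, target, _ = one_voxel_problem(uniform_anatomy)
        # mirror the target voxel across the beam axis so the problem is
        # exactly symmetric under the +/- lateral shifts
        i, j, k = map(int, np.argwhere(target)[0])
        target = target.copy()
        target[target.shape[0] - 1 - i, j, k] = True
        obj = ObjectiveSpec(target, 30.0, 10.0)
        mirrored = ScenarioSet(
            [ScenarioSpec((4.0, 0.0, 0.0)), ScenarioSpec((-4.0, 0.0, 0.0))],
            4.0, 3.0, "optimization",
        )
        res = robust_optimize(plan, uniform_anatomy, obj, mirrored,
                              SolverOptions(max_iter=100))
        prob = _Problem(plan, uniform_anatomy, obj, mirrored)
        d98s = [_d98(d) for d in prob.target_doses(res.weights)]
        assert d98s[0] == pytest.approx(d98s[1], rel=1e-9)

    def test_empty_target_rejected(self, uniform_anatomy):
        plan = single_spot_plan(weight=1.0)
        empty = np.zeros(uniform_anatomy.shape, bool)
        with pytest.raises(ValueError):
            robust_optimize(
                plan, uniform_anatomy, ObjectiveSpec(empty, 30.0),
                nominal_only_set(),
            )


class TestDoseMimic:
    def test_requires_reduced_setup_uncertainty(self, uniform_anatomy):
        plan, target, a = one_voxel_problem(uniform_anatomy)
        calc = DoseCalculator(plan, uniform_anatomy)
        ref = MimicReference(calc.dose(), None, setup_uncertainty_mm=5.0)
        with pytest.raises(ValueError):
            dose_mimic(
                ref, plan, uniform_anatomy, nominal_only_set(su_label=5.0),
                ObjectiveSpec(target, 30.0),
            )

    def test_fixed_point_when_reference_is_optimal(self, uniform_anatomy):
        plan, target, a = one_voxel_problem(uniform_anatomy)
        w_star = np.array([30.0 / a])
        calc = DoseCalculator(plan, uniform_anatomy)
        ref_dose = calc.dose(weights=w_star)
        ref = MimicReference(ref_dose, None, setup_uncertainty_mm=5.0)
        res = dose_mimic(
            ref, plan, uniform_anatomy, nominal_only_set(su_label=3.0),
            ObjectiveSpec(target, 30.0),
            SolverOptions(max_iter=100, init_weights=w_star),
        )
        # target already at prescription, no OOI terms: nothing moves
        np.testing.assert_allclose(res.weights, w_star, rtol=1e-12)

    def test_mimic_spares_heart_on_fixture(self, small_avg):
        """Regenerating at 3 mm from a 5 mm reference must not raise the
        nominal mean heart dose, and coverage stays above the gate."""
        from protonrem.eval3d import run_3drem

        itv = small_avg.masks["itv"]
        plan = make_plan_template(
            small_avg, itv, gantry_angles=(0.0,), prescription=30.0,
            n_fractions=15, setup_margin_mm=5.0,
        )
        terms = [
            OOITerm("heart", small_avg.masks["heart"], 1.0),
            OOITerm("body", small_avg.masks["body"], 0.15),
        ]
        obj = ObjectiveSpec(itv, 30.0, 10.0, terms)
        ref_res = robust_optimize(
            plan, small_avg, obj, optimization_scenarios(5.0, 3.0),
            SolverOptions(max_iter=120, tol=1e-7),
        )
        r3 = run_3drem(ref_res.plan, small_avg, 5.0, 3.0, itv)
        ref = MimicReference(r3.nominal_dose, r3.ooi, 5.0)
        mim = dose_mimic(
            ref, plan, small_avg, optimization_scenarios(3.0, 3.0), obj,
            SolverOptions(max_iter=120, tol=1e-7, init_weights=ref_res.weights),
        )
        heart = small_avg.masks["heart"]
        calc = DoseCalculator(plan, small_avg)
        mhd_ref = calc.dose_values(ScenarioSpec(), ref_res.weights)[heart].mean()
        mhd_mim = calc.dose_values(ScenarioSpec(), mim.weights)[heart].mean()
        assert mhd_mim <= mhd_ref + 1e-9
        r3m = run_3drem(mim.plan, small_avg, 3.0, 3.0, itv)
        assert r3m.verdict.d98_pct_of_rx > 95.0


def test_max_dose_and_dose_volume_terms(uniform_anatomy):
    """The quadratic OOI objective kinds match direct numpy evaluation."""
    from scipy import sparse

    from protonrem.planner import _ooi_value_grad

    rng = np.random.default_rng(6)
    A = sparse.csr_matrix(rng.uniform(0, 2, (40, 5)))
    w = rng.uniform(0, 3, 5)
    d = A @ w
    qs = 100.0 / 30.0**2

    term = OOITerm("o", np.ones((40, 1, 1), bool), weight=2.0,
                   kind="max-dose", threshold_gy=3.0)
    entry = {"term": term, "A": A, "n": 40, "idx": np.arange(40), "qs": qs}
    val, grad = _ooi_value_grad(entry, w, want_grad=True)
    r = np.maximum(d - 3.0, 0.0)
    assert val == pytest.approx(qs * 2.0 * (r @ r) / 40)
    np.testing.assert_allclose(grad, 2.0 * qs * 2.0 / 40 * (A.T @ r))

    # dose-volume: 25 % of voxels may exceed the threshold before penalties
    term_dv = OOITerm("o", np.ones((40, 1, 1), bool), weight=1.0,
                      kind="dose-volume", threshold_gy=3.0, volume_pct=25.0)
    entry_dv = {"term": term_dv, "A": A, "n": 40, "idx": np.arange(40), "qs": qs}
    val_dv, _ = _ooi_value_grad(entry_dv, w, want_grad=True)
    over = np.sort(d[d > 3.0])
    excess = over[: max(len(over) - 10, 0)] - 3.0  # coolest offenders beyond 25 %
    assert val_dv == pytest.approx(qs * (excess @ excess) / 40)


def test_template_spots_cover_target_depth_extent(small_avg):
    from protonrem.dose_engine import radiological_depth

    itv = small_avg.masks["itv"]
    plan = make_plan_template(
        small_avg, itv, gantry_angles=(0.0,), prescription=30.0,
        n_fractions=15, setup_margin_mm=5.0,
    )
    assert plan.n_spots > 0
    wepl = radiological_depth(
        small_avg.density, small_avg.spacing, small_avg.origin, 0.0
    )
    wt = wepl[itv]
    ranges = [s.nominal_range for s in plan.beams[0].spots]
    assert min(ranges) <= wt.min() + 1e-9
    assert max(ranges) >= wt.max() - 5.0  # within half a layer of the distal edge
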