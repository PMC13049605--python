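"""Delivery timeline, phase assignment, dose warping and accumulation."""

import dataclasses

import numpy as np
import pytest

from protonrem.dose_engine import Beam, Plan, ScenarioSpec, Spot, compute_plan_dose
from protonrem.eval4d import (
    TimingModel,
    accumulate,
    assign_phases,
    deliver_fraction,
    run_4drem,
    simulate_timeline,
    warp_dose,
)
from protonrem.scenarios import FractionErrorModel

from .conftest import grid_of, single_spot_plan


def layer_plan(n_spots=10, repaint=5, n_layers=1):
    layers = []
    for li in range(n_layers):
        spots = [
            Spot((6.0 * i, 0.0), 40.0 + 8.0 * li, weight=1.0) for i in range(n_spots)
        ]
        layers.append((40.0 + 8.0 * li, spots))
    beam = Beam(0.0, layers, repaint_factor=repaint)
    return Plan(beams=[beam], prescription_dose=30.0, n_fractions=15)


class TestTimeline:
    def test_event_count_layers_times_repaints(self):
        tl = simulate_timeline(layer_plan(n_spots=10, repaint=5))
        assert tl.n_events == 50
        assert np.all(np.diff(tl.times_s) > 0)

    def test_total_duration_is_sum_of_components(self):
        timing = TimingModel(spot_duration_s=0.01, layer_switch_s=1.0, beam_switch_s=5.0)
        plan = layer_plan(n_spots=4, repaint=2, n_layers=3)
        tl = simulate_timeline(plan, timing)
        expected = 3 * 2 * 4 * 0.01 + 2 * 1.0  # spots + two layer switches
        assert tl.total_duration_s == pytest.approx(expected)

    def test_each_layer_appears_repaint_times(self):
        tl = simulate_timeline(layer_plan(n_spots=3, repaint=4, n_layers=2))
        for li in range(2):
            reps = set(tl.repaint_index[tl.layer_index == li])
            assert reps == {0, 1, 2, 3}

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            simulate_timeline(layer_plan(), TimingModel(spot_duration_s=0.0))


class TestPhaseAssignment:
    def test_time_zero_is_phase_zero(self):
        tl = simulate_timeline(layer_plan(n_spots=1, repaint=1))
        assert assign_phases(tl, period_s=4.5, start_phase_offset=0.0)[0] == 0

    def test_half_period_is_phase_five(self):
        tl = dataclasses.replace(
            simulate_timeline(layer_plan(n_spots=1, repaint=1)),
            times_s=np.array([2.25]),
        )
        assert assign_phases(tl, period_s=4.5)[0] == 5

    def test_offset_wraps(self):
        tl = dataclasses.replace(
            simulate_timeline(layer_plan(n_spots=1, repaint=1)),
            times_s=np.array([0.0]),
        )
        assert assign_phases(tl, start_phase_offset=0.95)[0] == 9
        assert assign_phases(tl, start_phase_offset=1.05)[0] == 0

    def test_long_uniform_timeline_covers_phases_uniformly(self):
        n = 20000
        tl = dataclasses.replace(
            simulate_timeline(layer_plan(n_spots=1, repaint=1)),
            times_s=np.linspace(0.0, 4.5 * 100, n, endpoint=False),
        )
        phases = assign_phases(tl, period_s=4.5)
        counts = np.bincount(phases, minlength=10)
        # chi-square sanity check against uniformity
        chi2 = ((counts - n / 10.0) ** 2 / (n / 10.0)).sum()
        assert chi2 < 30.0


class TestWarp:
    def test_identity_field_is_exact(self):
        rng = np.random.default_rng(1)
        g = grid_of(rng.uniform(0, 30, (8, 8, 8)))
        dvf = np.zeros((8, 8, 8, 3))
        np.testing.assert_array_equal(warp_dose(g, dvf).values, g.values)

    def test_integer_translation_is_exact_shift(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 30, (9, 9, 9))
        g = grid_of(vals, spacing=3.0)
        dvf = np.zeros((9, 9, 9, 3))
        dvf[..., 0] = 6.0  # +2 voxels: out(x) = dose(x + 2 e_x)
        out = warp_dose(g, dvf).values
        np.testing.assert_allclose(out[:-2], vals[2:], atol=1e-12)

    def test_warp_respects_input_bounds(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 30, (8, 8, 8))
        g = grid_of(vals)
        dvf = rng.uniform(-5, 5, (8, 8, 8, 3))
        out = warp_dose(g, dvf).values
        assert out.min() >= vals.min() - 1e-12
        assert out.max() <= vals.max() + 1e-12


class TestAccumulate:
    def make_fds(self, rng, n=8, scenario=1):
        from protonrem.eval4d import FractionDose

        return [
            FractionDose(f + 1, scenario, grid_of(rng.uniform(0, 2, (5, 5, 5))))
            for f in range(n)
        ]

    def test_identical_fractions_scale_to_course_total(self):
        from protonrem.eval4d import FractionDose

        g = grid_of(np.full((4, 4, 4), 2.0))
        fds = [FractionDose(f + 1, 1, g) for f in range(8)]
        total = accumulate(fds, n_fractions_clinical=15)
        np.testing.assert_allclose(total.values, 2.0 * 15)

    def test_permutation_invariant_and_matches_mean_oracle(self):
        rng = np.random.default_rng(4)
        fds = self.make_fds(rng)
        a = accumulate(fds, 11)
        b = accumulate(list(reversed(fds)), 11)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        expected = np.mean([fd.dose.values for fd in fds], axis=0) * 11
        np.testing.assert_allclose(a.values, expected, atol=1e-12)

    def test_mixed_scenarios_rejected(self):
        rng = np.random.default_rng(5)
        fds = self.make_fds(rng, n=4, scenario=1) + self.make_fds(rng, n=4, scenario=2)
        with pytest.raises(ValueError):
            accumulate(fds, 15)


class TestDeliverFraction:
    def test_static_fraction_equals_plan_dose_over_fractions(self, static_phantom):
        plan = single_spot_plan(weight=1.0, n_fractions=15)
        tl = simulate_timeline(plan)
        fd = deliver_fraction(plan, static_phantom, ScenarioSpec(), tl)
        ref = static_phantom.reference
        static = compute_plan_dose(plan, ref)
        np.testing.assert_allclose(
            fd.dose.values, static.values / 15.0, rtol=1e-9, atol=1e-12
        )

    def test_linear_in_weights(self, static_phantom):
        plan1 = single_spot_plan(weight=1.0)
        plan2 = single_spot_plan(weight=2.0)
        tl = simulate_timeline(plan1)
        f1 = deliver_fraction(plan1, static_phantom, ScenarioSpec(), tl)
        f2 = deliver_fraction(plan2, static_phantom, ScenarioSpec(), tl)
        np.testing.assert_allclose(f2.dose.values, 2.0 * f1.dose.values, rtol=1e-12)


def test_batched_delivery_matches_per_scenario_path(small_phantom):
    """The scenario-batched fraction delivery used by run_4drem is
    numerically identical to delivering each scenario separately."""
    from protonrem.eval4d import _deliver_fraction_batch
    from protonrem.planner import make_plan_template
    from protonrem.scenarios import sample_fraction_errors

    ctv = small_phantom.reference.masks["ctv"]
    plan = make_plan_template(
        small_phantom.reference, ctv, gantry_angles=(0.0, 30.0),
        prescription=30.0, n_fractions=15, setup_margin_mm=4.0,
    )
    rng = np.random.default_rng(0)
    plan = plan.with_weights(rng.uniform(0.1, 1.0, plan.n_spots))
    tl = simulate_timeline(plan)
    table = sample_fraction_errors(FractionErrorModel(), 1, 4, seed=3)
    offsets = np.array([0.0, 0.3, 0.55, 0.8])
    batch = _deliver_fraction_batch(
        plan, small_phantom, [table.specs[s][0] for s in range(4)],
        tl, offsets, 4.5, {}, {},
    )
    for s in range(4):
        fd = deliver_fraction(
            plan, small_phantom, table.specs[s][0], tl,
            start_phase_offset=float(offsets[s]),
        )
        np.testing.assert_allclose(batch[s], fd.dose.values, atol=1e-12)


class TestRun4DREM:
    def test_static_limit_voxelwise_mean_equals_min_equals_static(self, static_phantom):
        plan = single_spot_plan(weight=1.0, n_fractions=15)
        model = FractionErrorModel(
            systematic_sd_mm=0.0, random_sd_mm=0.0, range_levels_pct=(0.0,)
        )
        res = run_4drem(plan, static_phantom, model, seed=3,
                        n_fractions=2, n_scenarios=2)
        static = compute_plan_dose(plan, static_phantom.reference)
        scale = np.abs(static.values).max()
        assert np.abs(res.voxelwise_mean.values - static.values).max() < 1e-6 * scale
        np.testing.assert_allclose(
            res.voxelwise_min.values, res.voxelwise_mean.values, atol=1e-12
        )

    def test_deterministic_under_seed(self, static_phantom):
        plan = single_spot_plan(weight=1.0)
        model = FractionErrorModel()
        a = run_4drem(plan, static_phantom, model, seed=9, n_fractions=2, n_scenarios=3)
        b = run_4drem(plan, static_phantom, model, seed=9, n_fractions=2, n_scenarios=3)
        np.testing.assert_array_equal(a.voxelwise_mean.values, b.voxelwise_mean.values)
        np.testing.assert_array_equal(a.voxelwise_min.values, b.voxelwise_min.values)

    def test_min_below_mean(self, small_phantom):
        plan = single_spot_plan(weight=1.0)
        res = run_4drem(plan, small_phantom, FractionErrorModel(), seed=2,
                        n_fractions=2, n_scenarios=3)
        assert np.all(res.voxelwise_min.values <= res.voxelwise_mean.values + 1e-12)
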