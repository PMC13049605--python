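"""4D robustness evaluation (4DREM): per-fraction delivery with interplay.

Each simulated fraction plays the plan's delivery timeline against the
breathing cycle: every spot event is assigned the respiratory phase active at
its delivery time, its dose is computed on that phase of the week's anatomy
under the fraction's setup/range perturbation, warped to the planning
reference phase through the phantom's known deformation fields, and summed.
Fractions are accumulated with equal weights and scaled to the clinical
course; voxel-wise mean and minimum across the scenario ensemble give the
expected and worst-case delivered dose.

Treatment log files are out of scope; delivery timing is simulated with
configurable per-spot and layer/beam switch durations, which is all the
interplay model needs (timing only places spots within the breathing cycle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import sample_volume
from .dose_engine import DoseCalculator, Plan, ScenarioSpec
from .eval3d import (
    CoverageVerdict,
    OOIMetrics,
    coverage_verdict,
    dose_at_volume,
    dvh,
    ooi_metrics,
    volume_at_dose,
    voxelwise_mean,
    voxelwise_min,
)
from .grid import DoseGrid
from .phantom4d import Phantom4D
from .scenarios import FractionErrorModel, sample_fraction_errors

__all__ = [
    "TimingModel",
    "DeliveryTimeline",
    "FractionDose",
    "FourDREMResult",
    "simulate_timeline",
    "assign_phases",
    "warp_dose",
    "deliver_fraction",
    "accumulate",
    "run_4drem",
]

BREATHING_PERIOD_S = 4.5


@dataclass
class TimingModel:
    spot_duration_s: float = 0.010
    layer_switch_s: float = 1.0
    beam_switch_s: float = 5.0

    def validate(self):
        if min(self.spot_duration_s, self.layer_switch_s, self.beam_switch_s) <= 0:
            raise ValueError("all durations must be positive")


@dataclass
class DeliveryTimeline:
    """Ordered spot events; each energy layer appears repaint_factor times."""

    beam_index: np.ndarray
    layer_index: np.ndarray
    repaint_index: np.ndarray
    spot_index: np.ndarray       # global spot index into the plan weight vector
    times_s: np.ndarray
    total_duration_s: float

    @property
    def n_events(self) -> int:
        return len(self.times_s)


def simulate_timeline(plan: Plan, timing: TimingModel | None = None) -> DeliveryTimeline:
    """Schedule spot events: repaint passes scan a full layer back to back,
    energy-layer switches and beam switches insert dead time."""
    timing = timing or TimingModel()
    timing.validate()
    if plan.n_spots == 0:
        raise ValueError("plan has no spots")
    beams, layers, repaints, spots, times = [], [], [], [], []
    t = 0.0
    gidx = 0
    for bi, beam in enumerate(plan.beams):
        if bi > 0:
            t += timing.beam_switch_s
        for li, (_, layer) in enumerate(beam.energy_layers):
            if li > 0:
                t += timing.layer_switch_s
            layer_gidx = gidx
            for rp in range(beam.repaint_factor):
                for si in range(len(layer)):
                    beams.append(bi)
                    layers.append(li)
                    repaints.append(rp)
                    spots.append(layer_gidx + si)
                    times.append(t)
                    t += timing.spot_duration_s
            gidx += len(layer)
    return DeliveryTimeline(
        np.array(beams), np.array(layers), np.array(repaints),
        np.array(spots), np.array(times), float(t),
    )


def assign_phases(
    timeline: DeliveryTimeline,
    period_s: float = BREATHING_PERIOD_S,
    start_phase_offset: float = 0.0,
    n_phases: int = 10,
) -> np.ndarray:
    """Respiratory phase index of each event:
    ``floor(((t / period + offset) mod 1) * n_phases)``."""
    if period_s <= 0:
        raise ValueError("breathing period must be positive")
    frac = np.mod(timeline.times_s / period_s + start_phase_offset, 1.0)
    return np.minimum((frac * n_phases).astype(np.int64), n_phases - 1)


def warp_dose(dose: DoseGrid, dvf: np.ndarray) -> DoseGrid:
    """Trilinear pull-back of a dose along a displacement field.

    ``dvf`` (mm) lives on the output grid and points into the dose's frame:
    ``out(x) = dose(x + dvf(x))``.  Passing a phase's ``dvf_to_reference``
    therefore maps that phase's dose onto the reference frame.
    """
    coords = _warp_coords(dose.shape, dose.spacing, dvf)
    return dose.copy_with(_warp_values(dose.values, coords))


def _warp_coords(shape, spacing, dvf):
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij"),
        axis=-1,
    )
    return grid + np.asarray(dvf, dtype=np.float64) / np.asarray(spacing)


def _warp_values(values, coords):
    return sample_volume(values, coords, zero_outside=False)


def _support_slices(values, pad):
    """Bounding-box slices of the non-zero support of ``values`` expanded by
    ``pad`` voxels (None if the array is identically zero)."""
    out = []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        nz = np.flatnonzero(np.any(values != 0.0, axis=other))
        if nz.size == 0:
            return None
        out.append(slice(max(nz[0] - pad, 0), min(nz[-1] + pad + 1, values.shape[ax])))
    return tuple(out)


@dataclass
class FractionDose:
    fraction_index: int          # 1-based
    scenario_index: int          # 1-based
    dose: DoseGrid               # on the planning reference phase


def deliver_fraction(
    plan: Plan,
    phantom_week: Phantom4D,
    scenario: ScenarioSpec,
    timeline: DeliveryTimeline,
    start_phase_offset: float = 0.0,
    period_s: float = BREATHING_PERIOD_S,
    fraction_index: int = 1,
    scenario_index: int = 1,
    calculators: dict | None = None,
    warp_coords: dict | None = None,
) -> FractionDose:
    """Simulate one fraction's delivery on a weekly 4D anatomy.

    Spot doses are computed per respiratory phase (as assigned by the
    timeline), warped to the planning reference and summed; the result is one
    clinical fraction (course dose / n_fractions) under the given scenario.
    ``calculators``/``warp_coords`` are optional per-phase caches.
    """
    n_phases = phantom_week.n_phases
    phases = assign_phases(timeline, period_s, start_phase_offset, n_phases)
    w_course = plan.weights
    repaint = np.array([b.repaint_factor for b in plan.beams], dtype=np.float64)
    ev_w = w_course[timeline.spot_index] / (
        plan.n_fractions * repaint[timeline.beam_index]
    )
    per_phase = np.zeros((n_phases, plan.n_spots))
    np.add.at(per_phase, (phases, timeline.spot_index), ev_w)

    ref = phantom_week.phases[phantom_week.reference_phase_index]
    out = np.zeros(ref.shape, dtype=np.float64)
    h = phantom_week.voxel_spacing
    for p in range(n_phases):
        wp = per_phase[p]
        if not wp.any():
            continue
        if calculators is not None and p in calculators:
            calc = calculators[p]
        else:
            calc = DoseCalculator(plan, phantom_week.phases[p])
            if calculators is not None:
                calculators[p] = calc
        dose_p = calc.dose_values(scenario, wp)
        dvf = phantom_week.phases[p].dvf_to_reference
        if np.any(dvf):
            if warp_coords is not None and p in warp_coords:
                coords, pad = warp_coords[p]
            else:
                coords = _warp_coords(ref.shape, h, dvf)
                pad = int(np.ceil(np.abs(dvf).max() / min(h))) + 1
                if warp_coords is not None:
                    warp_coords[p] = (coords, pad)
            # pull back only where the warped dose can be non-zero: the dose
            # support expanded by the largest displacement
            sl = _support_slices(dose_p, pad)
            if sl is not None:
                out[sl] += _warp_values(dose_p, coords[sl])
        else:
            out += dose_p
    grid = DoseGrid(out, h, phantom_week.origin)
    return FractionDose(fraction_index, scenario_index, grid)


def accumulate(fraction_doses: list[FractionDose], n_fractions_clinical: int) -> DoseGrid:
    """Equal-weight mean over simulated fractions, scaled to the clinical
    course total."""
    if not fraction_doses:
        raise ValueError("no fraction doses to accumulate")
    scen = {fd.scenario_index for fd in fraction_doses}
    if len(scen) != 1:
        raise ValueError("cannot accumulate fractions from different scenarios")
    mean = voxelwise_mean([fd.dose for fd in fraction_doses])
    return mean.copy_with(mean.values * n_fractions_clinical)


def _deliver_fraction_batch(
    plan, phantom_week, specs, timeline, offsets, period_s,
    calculators, warp_coords,
):
    """All scenarios of one fraction in a single pass per (phase, beam).

    Numerically equivalent to calling ``deliver_fraction`` per scenario (the
    batched kernel shares the WEPL loads and band searches); returns one
    reference-frame dose array per scenario.
    """
    from ._kernels import deposit_spots_multi

    n_phases = phantom_week.n_phases
    C = len(specs)
    w_course = plan.weights
    repaint = np.array([b.repaint_factor for b in plan.beams], dtype=np.float64)
    ev_w = w_course[timeline.spot_index] / (
        plan.n_fractions * repaint[timeline.beam_index]
    )
    per_phase = np.zeros((C, n_phases, plan.n_spots))
    for c in range(C):
        ph = assign_phases(timeline, period_s, float(offsets[c]), n_phases)
        np.add.at(per_phase[c], (ph, timeline.spot_index), ev_w)

    rho = np.array([s.density_scale for s in specs], dtype=np.float64)
    rho_vals, rho_group = np.unique(rho, return_inverse=True)
    rho_group = np.ascontiguousarray(rho_group.astype(np.int64))
    shifts = np.array([s.isocenter_shift for s in specs], dtype=np.float64)

    ref = phantom_week.phases[phantom_week.reference_phase_index]
    h = phantom_week.voxel_spacing
    outs = [np.zeros(ref.shape, dtype=np.float64) for _ in range(C)]
    for p in range(n_phases):
        Wp = per_phase[:, p, :]
        if not Wp.any():
            continue
        if p in calculators:
            calc = calculators[p]
        else:
            calc = DoseCalculator(plan, phantom_week.phases[p])
            calculators[p] = calc
        buf = np.zeros(ref.shape + (C,), dtype=np.float64)
        for bd, sl in zip(calc._beams, calc._slices):
            Wb = np.ascontiguousarray(Wp[:, sl])
            if not Wb.any():
                continue
            d1 = np.ascontiguousarray(shifts @ bd["e1"])
            d2 = np.ascontiguousarray(shifts[:, 2])
            deposit_spots_multi(
                buf, bd["l1_sorted"], bd["l1_order"], bd["zc"], bd["wepl"],
                rho, rho_group, len(rho_vals), d1, d2,
                bd["p1"], bd["p2"], bd["rng"], bd["sig"], Wb,
                calc.falloff_sigma, calc.medium,
            )
        buf *= plan.rbe_factor
        dvf = phantom_week.phases[p].dvf_to_reference
        if np.any(dvf):
            if p in warp_coords:
                coords, pad = warp_coords[p]
            else:
                coords = _warp_coords(ref.shape, h, dvf)
                pad = int(np.ceil(np.abs(dvf).max() / min(h))) + 1
                warp_coords[p] = (coords, pad)
            for c in range(C):
                dose_p = np.ascontiguousarray(buf[..., c])
                sl3 = _support_slices(dose_p, pad)
                if sl3 is not None:
                    outs[c][sl3] += _warp_values(dose_p, coords[sl3])
        else:
            for c in range(C):
                outs[c] += buf[..., c]
    return outs


@dataclass
class FourDREMResult:
    voxelwise_mean: DoseGrid
    voxelwise_min: DoseGrid
    verdict: CoverageVerdict          # CTV coverage of the voxel-wise minimum
    ooi: OOIMetrics                   # OOI metrics on the voxel-wise mean
    per_scenario: pd.DataFrame
    scenario_doses: list[DoseGrid]


def run_4drem(
    plan: Plan,
    phantom: Phantom4D,
    error_model: FractionErrorModel | None = None,
    seed: int = 0,
    n_fractions: int = 8,
    n_scenarios: int = 14,
    timing: TimingModel | None = None,
    period_s: float = BREATHING_PERIOD_S,
    ctv_mask: np.ndarray | None = None,
    ooi_masks: dict | None = None,
) -> FourDREMResult:
    """Longitudinal robustness evaluation: ``n_fractions`` simulated fractions
    times ``n_scenarios`` independent error scenarios on the weekly anatomies.

    Coverage is gated on the CTV (reference phase) of the voxel-wise minimum;
    OOI metrics are taken on the voxel-wise mean.  Fraction f uses weekly
    variant f; if the phantom has no weekly variants, the planning anatomy is
    reused (a static-course degenerate useful for consistency checks).
    """
    error_model = error_model or FractionErrorModel()
    table = sample_fraction_errors(error_model, n_fractions, n_scenarios, seed)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 909091])
    offsets = rng.uniform(0.0, 1.0, size=(n_scenarios, n_fractions))
    timeline = simulate_timeline(plan, timing)

    ref = phantom.reference
    scen_sum = [np.zeros(ref.shape, dtype=np.float64) for _ in range(n_scenarios)]
    for f in range(1, n_fractions + 1):
        if phantom.weekly_variants:
            week = phantom.weekly_variants[(f - 1) % len(phantom.weekly_variants)]
        else:
            week = phantom
        calcs: dict = {}
        coords: dict = {}
        fraction_doses = _deliver_fraction_batch(
            plan, week, [table.specs[s][f - 1] for s in range(n_scenarios)],
            timeline, offsets[:, f - 1], period_s, calcs, coords,
        )
        for s in range(n_scenarios):
            scen_sum[s] += fraction_doses[s]
    scale = plan.n_fractions / n_fractions
    scenario_doses = [
        DoseGrid(sv * scale, phantom.voxel_spacing, phantom.origin) for sv in scen_sum
    ]
    vmean = voxelwise_mean(scenario_doses)
    vmin = voxelwise_min(scenario_doses)
    ctv = ctv_mask if ctv_mask is not None else ref.masks["ctv"]
    verdict = coverage_verdict(vmin, ctv, plan.prescription_dose, "ctv")
    masks = ooi_masks if ooi_masks is not None else ref.masks
    ooi = ooi_metrics(vmean, masks, plan.prescription_dose)
    rows = []
    rx = plan.prescription_dose
    for s, dg in enumerate(scenario_doses):
        hh = dvh(dg, ctv, "ctv")
        d98 = 100.0 * dose_at_volume(hh, 98.0) / rx
        v95, _ = volume_at_dose(hh, 0.95 * rx)
        heart = masks.get("heart")
        rows.append(
            {
                "scenario": s + 1,
                "range_level_pct": table.range_levels_pct[s],
                "ctv_d98_pct": d98,
                "ctv_v95_pct": v95,
                "mhd_gy": float(dg.values[heart].mean()) if heart is not None and heart.any() else np.nan,
            }
        )
    return FourDREMResult(vmean, vmin, verdict, ooi, pd.DataFrame(rows), scenario_doses)
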