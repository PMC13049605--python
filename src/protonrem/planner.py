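"""Robust spot-weight optimization and voxel-based dose mimicking.

``robust_optimize`` performs worst-case robust optimization: target underdose
is penalized on the voxel-wise *minimum* dose across the optimization
scenario set (and overdose on the voxel-wise maximum), which is exactly the
quantity the clinical voxel-wise-minimum coverage gate evaluates;
organ-of-interest (OOI) terms act on the nominal scenario.  The scenario with
the lowest target coverage (D98) is identified and reported with the result.
The solver is projected gradient descent with Armijo backtracking, so the
objective trace is monotone non-increasing and weights stay non-negative.

``dose_mimic`` regenerates a plan at a *reduced* setup uncertainty from a
reference plan: one-sided quadratic penalties keep OOI voxel doses at or
below the reference dose and worst-case target voxels at or above the
prescription, while the objective's OOI mean-dose terms act as an active
sparing pressure.  Relaxing the worst-case coverage demand (smaller setup
shifts) therefore lets the optimizer trade the freed margin for OOI sparing,
which is the mechanism under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dose_engine import DoseCalculator, Plan, ScenarioSpec, Spot, Beam, beam_unit_vectors, radiological_depth
from .eval3d import OOIMetrics
from .grid import DoseGrid
from .scenarios import ScenarioSet

__all__ = [
    "OOITerm",
    "ObjectiveSpec",
    "SolverOptions",
    "OptimizationResult",
    "MimicReference",
    "robust_optimize",
    "dose_mimic",
    "make_plan_template",
]


@dataclass
class OOITerm:
    name: str
    mask: np.ndarray
    weight: float = 1.0
    kind: str = "mean-dose"          # "mean-dose" | "max-dose" | "dose-volume"
    threshold_gy: float | None = None
    volume_pct: float | None = None

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("objective weights must be non-negative")
        if self.kind not in ("mean-dose", "max-dose", "dose-volume"):
            raise ValueError(f"unknown objective kind {self.kind!r}")


@dataclass
class ObjectiveSpec:
    target_mask: np.ndarray
    prescription: float
    target_weight: float = 10.0
    ooi_terms: list[OOITerm] = field(default_factory=list)

    def __post_init__(self):
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if self.target_weight < 0:
            raise ValueError("target_weight must be non-negative")


@dataclass
class SolverOptions:
    max_iter: int = 300
    tol: float = 1e-6
    armijo_c: float = 1e-4
    min_step: float = 1e-18
    init_weights: np.ndarray | None = None


@dataclass
class OptimizationResult:
    weights: np.ndarray
    objective_trace: np.ndarray
    worst_scenario_index: int
    converged: bool
    n_iterations: int
    plan: Plan


@dataclass
class MimicReference:
    """Reference dose and quality metrics a mimicked plan must not degrade."""

    nominal_dose: DoseGrid
    ooi: OOIMetrics | None
    setup_uncertainty_mm: float


def _d98(dose_vec: np.ndarray) -> float:
    n = dose_vec.size
    k = max(int(np.floor(0.98 * n)), 1)
    return float(np.partition(dose_vec, n - k)[n - k])


class _Problem:
    """Precomputed influence slices shared by both optimizers."""

    def __init__(self, plan, anatomy, objective, scenario_set, falloff_sigma=3.0):
        if not np.asarray(objective.target_mask, bool).any():
            raise ValueError("target mask is empty")
        self.calc = DoseCalculator(plan, anatomy, falloff_sigma)
        self.rx = objective.prescription
        self.tw = objective.target_weight
        # dimensionless term scalings: quadratic residuals in % of prescription,
        # mean doses as fractions of prescription
        self.quad_scale = 100.0 / self.rx**2
        self.lin_scale = 1.0 / self.rx
        tmask = np.asarray(objective.target_mask, bool).ravel()
        self.t_idx = np.flatnonzero(tmask)
        self.n_t = self.t_idx.size

        self.A_t = [
            self.calc.influence(spec, rows=self.t_idx).tocsr() for spec in scenario_set
        ]
        if not self.A_t:
            raise ValueError("scenario set is empty")
        if (self.A_t[0] @ np.ones(self.calc.n_spots)).sum() == 0:
            raise ValueError("plan template has no influence on the target")

        nominal = ScenarioSpec()
        self.terms = []
        for term in objective.ooi_terms:
            idx = np.flatnonzero(np.asarray(term.mask, bool).ravel())
            if idx.size == 0:
                continue
            A_o = self.calc.influence(nominal, rows=idx).tocsr()
            entry = {"term": term, "A": A_o, "n": idx.size, "idx": idx,
                     "qs": self.quad_scale}
            if term.kind == "mean-dose":
                entry["grad"] = (
                    term.weight * self.lin_scale / idx.size
                    * np.asarray(A_o.sum(axis=0)).ravel()
                )
            self.terms.append(entry)

    def target_doses(self, w):
        return [A @ w for A in self.A_t]

    def worst_index(self, target_doses):
        d98s = [_d98(d) for d in target_doses]
        return int(np.argmin(d98s))


def _ooi_value_grad(entry, w, want_grad):
    """Objective value (and optional gradient) of one OOI term."""
    term = entry["term"]
    A, n = entry["A"], entry["n"]
    if term.kind == "mean-dose":
        # entry["grad"] already carries weight / n_voxels
        val = float(entry["grad"] @ w)
        return val, (entry["grad"] if want_grad else None)
    qs = entry["qs"]
    d = A @ w
    if term.kind == "max-dose":
        thr = term.threshold_gy or 0.0
        r = np.maximum(d - thr, 0.0)
        val = qs * term.weight * float(r @ r) / n
        g = (2.0 * qs * term.weight / n) * (A.T @ r) if want_grad else None
        return val, g
    # dose-volume: penalize voxels above the threshold beyond the allowed volume
    thr = term.threshold_gy or 0.0
    allowed = int(np.floor((term.volume_pct or 0.0) / 100.0 * n))
    over = d > thr
    n_over = int(np.count_nonzero(over))
    if n_over <= allowed:
        return 0.0, (np.zeros_like(w) if want_grad else None)
    # penalize the coolest offenders (the ones cheapest to pull below threshold)
    excess = d[over]
    order = np.argsort(excess)
    pick = np.flatnonzero(over)[order[: n_over - allowed]]
    r = d[pick] - thr
    val = qs * term.weight * float(r @ r) / n
    if not want_grad:
        return val, None
    rr = np.zeros(n)
    rr[pick] = r
    return val, (2.0 * qs * term.weight / n) * (A.T @ rr)


def _worst_case_target(problem, low, cap, tw, overdose_weight):
    """Voxel-wise worst-case target term: underdose is penalized on the
    voxel-wise minimum dose across the scenario set (each voxel's residual
    attributed to the scenario realizing its minimum), overdose on the
    voxel-wise maximum.  This optimizes exactly the quantity the clinical
    gate evaluates and gives a stable descent direction."""
    qs, n_t = problem.quad_scale, problem.n_t

    def target_terms(tds, want_grad):
        D = np.stack(tds)
        dmin = D.min(axis=0)
        dmax = D.max(axis=0)
        ru = np.maximum(low - dmin, 0.0)
        ro = np.maximum(dmax - cap, 0.0)
        val = qs * tw * (float(ru @ ru) + overdose_weight * float(ro @ ro)) / n_t
        if not want_grad:
            return val, None
        smin = D.argmin(axis=0)
        smax = D.argmax(axis=0)
        g = np.zeros(problem.calc.n_spots)
        for s_i, A in enumerate(problem.A_t):
            r = np.zeros(n_t)
            mu = (smin == s_i) & (ru > 0.0)
            if mu.any():
                r[mu] = -ru[mu]
            mo = (smax == s_i) & (ro > 0.0)
            if mo.any():
                r[mo] += overdose_weight * ro[mo]
            if mu.any() or mo.any():
                g += A.T @ r
        return val, (2.0 * qs * tw / n_t) * g

    return target_terms


def _run_descent(problem, target_terms, opts):
    """Projected gradient descent with Armijo backtracking on the composite
    worst-case objective.  ``target_terms(tds, want_grad)`` evaluates the
    robust target term over the per-scenario target doses (with scenario
    attribution folded into its gradient), so the recorded trace is monotone
    and the backtracking line search is well behaved."""

    def objective(w):
        tds = problem.target_doses(w)
        val, _ = target_terms(tds, want_grad=False)
        for entry in problem.terms:
            v, _ = _ooi_value_grad(entry, w, want_grad=False)
            val += v
        return val, 0

    def gradient(w, _worst):
        tds = problem.target_doses(w)
        _, g = target_terms(tds, want_grad=True)
        for entry in problem.terms:
            _, go = _ooi_value_grad(entry, w, want_grad=True)
            g = g + go
        return g

    if opts.init_weights is not None:
        w = np.asarray(opts.init_weights, dtype=np.float64).copy()
    else:
        w = np.ones(problem.calc.n_spots)
        nom_target = problem.A_t[problem.worst_index(problem.target_doses(w))] @ w
        mean = nom_target.mean()
        if mean <= 0:
            raise ValueError("plan template has no influence on the target")
        w *= problem.rx / mean
    w = np.maximum(w, 0.0)

    f, worst = objective(w)
    trace = [f]
    step = 1.0
    converged = False
    for it in range(opts.max_iter):
        g = gradient(w, worst)
        gnorm2 = float(g @ g)
        if gnorm2 == 0.0:
            converged = True
            break
        step = min(step * 2.0, 1e12)
        accepted = False
        while step > opts.min_step:
            w_new = np.maximum(w - step * g, 0.0)
            f_new, worst_new = objective(w_new)
            decrease = float(g @ (w - w_new))
            if f_new <= f - opts.armijo_c * decrease and f_new <= f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        rel = (f - f_new) / max(abs(f), 1e-30)
        w, f, worst = w_new, f_new, worst_new
        trace.append(f)
        if rel < opts.tol:
            converged = True
            break
    return w, np.array(trace), worst, converged, len(trace) - 1


def robust_optimize(
    plan_template: Plan,
    anatomy,
    objective: ObjectiveSpec,
    scenario_set: ScenarioSet,
    opts: SolverOptions | None = None,
    hotspot_factor: float = 1.07,
    overdose_weight: float = 0.25,
    coverage_margin: float = 1.02,
) -> OptimizationResult:
    """Minimax robust optimization of spot weights.

    The target term is an asymmetric quadratic on the worst scenario (lowest
    target D98) of ``scenario_set``: underdose below ``coverage_margin * Rx``
    is penalized with full weight, overdose only beyond ``hotspot_factor *
    Rx`` and with reduced weight — the clinical min-dose/max-dose pairing.
    The slight overcoverage margin mirrors prescription practice: the
    voxel-wise minimum across the evaluation scenarios is less favorable than
    any single optimized scenario, so single-scenario coverage must land
    above the gate.  OOI terms act on the nominal scenario.
    """
    opts = opts or SolverOptions()
    problem = _Problem(plan_template, anatomy, objective, scenario_set)
    rx, tw, n_t = problem.rx, problem.tw, problem.n_t
    cap = hotspot_factor * rx
    low = coverage_margin * rx
    qs = problem.quad_scale

    target_terms = _worst_case_target(problem, low, cap, tw, overdose_weight)
    w, trace, _, conv, n_it = _run_descent(problem, target_terms, opts)
    worst = problem.worst_index(problem.target_doses(w))  # lowest-coverage scenario
    return OptimizationResult(w, trace, worst, conv, n_it, plan_template.with_weights(w))


def dose_mimic(
    reference: MimicReference,
    plan_template: Plan,
    anatomy,
    reduced_scenarios: ScenarioSet,
    objective: ObjectiveSpec,
    opts: SolverOptions | None = None,
    exceed_weight: float = 20.0,
) -> OptimizationResult:
    """Voxel-based dose-mimicking re-optimization at reduced setup uncertainty.

    Minimizes (i) a one-sided quadratic penalty for OOI voxel doses exceeding
    the reference nominal dose, (ii) a one-sided quadratic penalty for
    worst-scenario target voxels below the prescription, and (iii) the
    objective's OOI mean-dose terms (sparing pressure).
    """
    if reduced_scenarios.setup_uncertainty_mm >= reference.setup_uncertainty_mm:
        raise ValueError(
            "dose mimicking requires a setup uncertainty smaller than the "
            f"reference plan's ({reference.setup_uncertainty_mm} mm)"
        )
    opts = opts or SolverOptions()
    problem = _Problem(plan_template, anatomy, objective, reduced_scenarios)
    rx, tw, n_t = problem.rx, problem.tw, problem.n_t
    qs = problem.quad_scale

    ref_vals = np.asarray(reference.nominal_dose.values, dtype=np.float64).ravel()
    exceed = []
    for entry in problem.terms:
        exceed.append(
            {
                "A": entry["A"],
                "ref": ref_vals[entry["idx"]],
                "n": entry["n"],
                "w": exceed_weight * entry["term"].weight,
            }
        )

    # worst-case coverage term: one-sided underdose below the prescription
    # on the voxel-wise minimum over the reduced scenario set
    target_terms = _worst_case_target(problem, rx, np.inf, tw, 0.0)
    base_terms = problem.terms

    def objective_fn(w):
        tds = problem.target_doses(w)
        val, _ = target_terms(tds, want_grad=False)
        for e in exceed:
            r = np.maximum(e["A"] @ w - e["ref"], 0.0)
            val += qs * e["w"] * float(r @ r) / e["n"]
        for entry in base_terms:
            v, _ = _ooi_value_grad(entry, w, want_grad=False)
            val += v
        return val, 0

    def gradient_fn(w, _worst):
        tds = problem.target_doses(w)
        _, g = target_terms(tds, want_grad=True)
        for e in exceed:
            r = np.maximum(e["A"] @ w - e["ref"], 0.0)
            g = g + (2.0 * qs * e["w"] / e["n"]) * (e["A"].T @ r)
        for entry in base_terms:
            _, go = _ooi_value_grad(entry, w, want_grad=True)
            g = g + go
        return g

    if opts.init_weights is not None:
        w = np.asarray(opts.init_weights, dtype=np.float64).copy()
    else:
        tpl_w = plan_template.weights
        w = tpl_w if tpl_w.any() else np.ones(problem.calc.n_spots)
    w = np.maximum(w, 0.0)
    f, worst = objective_fn(w)
    trace = [f]
    step = 1.0
    converged = False
    n_it = 0
    for it in range(opts.max_iter):
        g = gradient_fn(w, worst)
        if float(g @ g) == 0.0:
            converged = True
            break
        step = min(step * 2.0, 1e12)
        accepted = False
        while step > opts.min_step:
            w_new = np.maximum(w - step * g, 0.0)
            f_new, worst_new = objective_fn(w_new)
            decrease = float(g @ (w - w_new))
            if f_new <= f - opts.armijo_c * decrease and f_new <= f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        rel = (f - f_new) / max(abs(f), 1e-30)
        w, f, worst = w_new, f_new, worst_new
        trace.append(f)
        n_it = it + 1
        if rel < opts.tol:
            converged = True
            break
    worst_cov = problem.worst_index(problem.target_doses(w))
    return OptimizationResult(
        w, np.array(trace), worst_cov, converged, n_it, plan_template.with_weights(w)
    )


# ---------------------------------------------------------------------------
# spot placement


def make_plan_template(
    anatomy,
    target_mask: np.ndarray,
    gantry_angles=(330.0, 0.0, 30.0),
    prescription: float = 30.0,
    n_fractions: int = 15,
    setup_margin_mm: float = 5.0,
    sigma_lateral: float = 6.0,
    lateral_spacing: float | None = None,
    layer_spacing: float = 8.0,
    range_uncertainty_pct: float = 3.0,
    falloff_sigma: float = 3.0,
    repaint_factor: int = 5,
    rbe_factor: float = 1.1,
) -> Plan:
    """Place spots so Bragg peaks tile the target (plus margins) for each beam.

    Lateral spot spacing defaults to one sigma; the lateral hull is the
    target's beam's-eye-view projection dilated by the setup margin, and the
    depth extent is padded by the range-uncertainty excursion plus the distal
    falloff width.  All weights start at 1.
    """
    target_mask = np.asarray(target_mask, bool)
    if not target_mask.any():
        raise ValueError("target mask is empty")
    spacing = lateral_spacing or sigma_lateral
    density = np.asarray(anatomy.density, dtype=np.float64)
    vox = anatomy.spacing
    origin = anatomy.origin
    idx = np.argwhere(target_mask)
    world = origin + idx * np.asarray(vox)
    iso = tuple(world.mean(axis=0))

    beams = []
    for g in gantry_angles:
        e1, _, _ = beam_unit_vectors(g)
        wepl = radiological_depth(density, vox, origin, g)
        l1 = (world[:, 0] - iso[0]) * e1[0] + (world[:, 1] - iso[1]) * e1[1]
        l2 = world[:, 2] - iso[2]
        wt = wepl[target_mask]

        margin = setup_margin_mm + 0.5 * sigma_lateral
        r_pad = range_uncertainty_pct / 100.0 * wt.max() + falloff_sigma

        def cells(vals):
            lo = int(np.floor((vals.min() - margin) / spacing))
            hi = int(np.ceil((vals.max() + margin) / spacing))
            return lo, hi

        lo1, hi1 = cells(l1)
        lo2, hi2 = cells(l2)
        n1, n2 = hi1 - lo1 + 1, hi2 - lo2 + 1
        occ = np.zeros((n1, n2), dtype=bool)
        wmin = np.full((n1, n2), np.inf)
        wmax = np.full((n1, n2), -np.inf)
        c1 = np.clip(np.round(l1 / spacing).astype(int) - lo1, 0, n1 - 1)
        c2 = np.clip(np.round(l2 / spacing).astype(int) - lo2, 0, n2 - 1)
        occ[c1, c2] = True
        np.minimum.at(wmin, (c1, c2), wt)
        np.maximum.at(wmax, (c1, c2), wt)

        rad = int(np.ceil(margin / spacing))
        size = 2 * rad + 1
        occ_d = ndimage.binary_dilation(occ, structure=np.ones((size, size), bool))
        wmin_d = ndimage.minimum_filter(wmin, size=size, mode="constant", cval=np.inf)
        wmax_d = ndimage.maximum_filter(wmax, size=size, mode="constant", cval=-np.inf)

        r_lo = max(wt.min() - r_pad, layer_spacing / 2.0)
        r_hi = wt.max() + r_pad
        n_layers = max(int(np.ceil((r_hi - r_lo) / layer_spacing)) + 1, 1)
        layer_ranges = r_lo + np.arange(n_layers) * layer_spacing

        layers = []
        half = layer_spacing / 2.0
        for R in layer_ranges:
            spots = []
            for i1 in range(n1):
                for i2 in range(n2):
                    if not occ_d[i1, i2]:
                        continue
                    if R + half < wmin_d[i1, i2] - r_pad or R - half > wmax_d[i1, i2] + r_pad:
                        continue
                    spots.append(
                        Spot(
                            lateral_position=((lo1 + i1) * spacing, (lo2 + i2) * spacing),
                            nominal_range=float(R),
                            weight=1.0,
                            sigma_lateral=sigma_lateral,
                        )
                    )
            if spots:
                layers.append((float(R), spots))
        beams.append(Beam(gantry_angle=float(g), energy_layers=layers, repaint_factor=repaint_factor))
    return Plan(
        beams=beams,
        prescription_dose=prescription,
        n_fractions=n_fractions,
        rbe_factor=rbe_factor,
        isocenter=iso,
    )
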