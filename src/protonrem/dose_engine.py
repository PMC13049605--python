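"""Analytic pencil-beam-scanning proton dose model.

A deliberately simple, fully deterministic engine standing in for a clinical
Monte Carlo dose calculation: each spot deposits an isotropic lateral Gaussian
(truncated at 3 sigma) times a peaked depth-dose curve evaluated in
water-equivalent depth (WEPL).  The engine supports exactly the perturbations
the robustness machinery needs:

* rigid setup shifts — the patient displaced relative to the beam.  The
  lateral spot pattern moves by the shift's in-plane components; the WEPL of
  an anatomy voxel is invariant under rigid translation, so the along-axis
  component leaves the dose unchanged, mirroring real proton behaviour.
* density (range) scaling — a multiplier on the WEPL integrand, so a 3 %
  range uncertainty maps to density scales {0.97, 1.00, 1.03}.

Dose is scored only in material voxels (density > 0): vacuum absorbs no
energy, so air outside the body receives no dose.

Beams are coplanar: the gantry rotates about the longitudinal (z) axis, with
0 degrees entering anteriorly.  Dose is linear in the spot weights; weights
are calibrated so that a plan's dose grid is the *total course* dose in
Gy(RBE) (physical dose times the constant RBE factor).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

from ._kernels import (
    FALLOFF_CUTOFF_SIGMA,
    LATERAL_CUTOFF_SIGMA,
    _BUILDUP_FLOOR,
    deposit_spots,
    sample_volume,
    spot_columns,
)
from .grid import DoseGrid

__all__ = [
    "Spot",
    "Beam",
    "Plan",
    "ScenarioSpec",
    "depth_dose",
    "beam_unit_vectors",
    "radiological_depth",
    "DoseCalculator",
    "compute_plan_dose",
    "dose_influence_matrix",
]


@dataclass
class Spot:
    lateral_position: tuple[float, float]  # (l1, l2) mm in beam coordinates
    nominal_range: float                   # mm water-equivalent
    weight: float = 0.0                    # MU surrogate, >= 0
    sigma_lateral: float = 6.0             # mm

    def __post_init__(self):
        if self.sigma_lateral <= 0:
            raise ValueError("sigma_lateral must be positive")
        if self.nominal_range <= 0:
            raise ValueError("nominal_range must be positive")


@dataclass
class Beam:
    gantry_angle: float                      # degrees, about z, 0 = anterior
    energy_layers: list[tuple[float, list[Spot]]]
    repaint_factor: int = 5

    def __post_init__(self):
        if self.repaint_factor < 1:
            raise ValueError("repaint_factor must be >= 1")

    @property
    def spots(self) -> list[Spot]:
        return [s for _, layer in self.energy_layers for s in layer]


@dataclass
class Plan:
    beams: list[Beam]
    prescription_dose: float        # Gy(RBE), total course
    n_fractions: int
    rbe_factor: float = 1.1
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.rbe_factor <= 0:
            raise ValueError("rbe_factor must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")

    @property
    def n_spots(self) -> int:
        return sum(len(b.spots) for b in self.beams)

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for b in self.beams for s in b.spots], dtype=np.float64)

    def with_weights(self, weights) -> "Plan":
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (self.n_spots,):
            raise ValueError("weight vector length mismatch")
        beams = []
        i = 0
        for b in self.beams:
            layers = []
            for rng_mm, layer in b.energy_layers:
                spots = []
                for s in layer:
                    spots.append(replace(s, weight=float(w[i])))
                    i += 1
                layers.append((rng_mm, spots))
            beams.append(replace(b, energy_layers=layers))
        return replace(self, beams=beams)

    def pruned(self, min_relative_weight: float = 1e-3) -> "Plan":
        """Deliverability filter: drop spots whose weight falls below
        ``min_relative_weight`` times the plan's largest weight (a
        minimum-MU surrogate) along with any emptied energy layers."""
        w = self.weights
        if not w.any():
            return self
        thr = min_relative_weight * w.max()
        beams = []
        for b in self.beams:
            layers = []
            for rng_mm, layer in b.energy_layers:
                spots = [replace(s) for s in layer if s.weight >= thr]
                if spots:
                    layers.append((rng_mm, spots))
            beams.append(replace(b, energy_layers=layers))
        return replace(self, beams=beams)


@dataclass
class ScenarioSpec:
    """One perturbation: a rigid setup shift (mm) plus a density scale."""

    isocenter_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    density_scale: float = 1.0

    def __post_init__(self):
        if self.density_scale <= 0:
            raise ValueError("density_scale must be positive")


NOMINAL = ScenarioSpec()


def depth_dose(depth, nominal_range, falloff_sigma=3.0):
    """Depth-dose per unit weight: cubic build-up to a peak at the nominal
    range, truncated-Gaussian distal falloff reaching zero at
    ``nominal_range + 3 * falloff_sigma``.  Vectorized in ``depth``.
    """
    depth = np.asarray(depth, dtype=np.float64)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    if nominal_range <= 0:
        raise ValueError("nominal_range must be positive")
    x = depth / nominal_range
    build = _BUILDUP_FLOOR + (1.0 - _BUILDUP_FLOOR) * x**3
    edge = np.exp(-0.5 * FALLOFF_CUTOFF_SIGMA**2)
    t = (depth - nominal_range) / falloff_sigma
    tail = (np.exp(-0.5 * t**2) - edge) / (1.0 - edge)
    out = np.where(depth <= nominal_range, build, np.maximum(tail, 0.0))
    return out if out.shape else float(out)


def beam_unit_vectors(gantry_deg: float):
    """(e1, e2, u): lateral axes and propagation direction of a coplanar beam."""
    g = np.deg2rad(gantry_deg)
    u = np.array([np.sin(g), np.cos(g), 0.0])
    e1 = np.array([np.cos(g), -np.sin(g), 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    return e1, e2, u


def radiological_depth(density, spacing, origin, gantry_deg) -> np.ndarray:
    """Water-equivalent depth of every voxel along a beam direction.

    The density is resampled onto a beam-aligned grid, integrated cumulatively
    along the propagation axis (midpoint rule), and the result sampled back at
    the voxel centers.  For axis-aligned beams the resampling grids coincide
    with the voxel grid and the computation is exact.
    """
    density = np.asarray(density, dtype=np.float64)
    nx, ny, nz = density.shape
    h = float(spacing[0])
    e1, _, u = beam_unit_vectors(gantry_deg)
    cx = origin[0] + (nx - 1) / 2.0 * spacing[0]
    cy = origin[1] + (ny - 1) / 2.0 * spacing[1]

    corners = np.array(
        [
            (origin[0] + dx * (nx - 1) * spacing[0] - cx,
             origin[1] + dy * (ny - 1) * spacing[1] - cy)
            for dx in (0, 1)
            for dy in (0, 1)
        ]
    )
    a_vals = corners @ e1[:2]
    s_vals = corners @ u[:2]
    amin, amax = a_vals.min(), a_vals.max()
    smin, smax = s_vals.min(), s_vals.max()
    na = int(np.round((amax - amin) / h)) + 1
    ns = int(np.round((smax - smin) / h)) + 1

    a = amin + np.arange(na) * h
    s = smin + np.arange(ns) * h
    # beam-frame sample points in world xy (z stays the grid z axis)
    px = cx + a[:, None] * e1[0] + s[None, :] * u[0]
    py = cy + a[:, None] * e1[1] + s[None, :] * u[1]
    ix = (px - origin[0]) / spacing[0]
    iy = (py - origin[1]) / spacing[1]
    iz = np.arange(nz, dtype=np.float64)
    coords = np.empty((na, ns, nz, 3))
    coords[..., 0] = ix[..., None]
    coords[..., 1] = iy[..., None]
    coords[..., 2] = iz[None, None, :]
    rho = sample_volume(density, coords, zero_outside=True)
    wbf = (np.cumsum(rho, axis=1) - 0.5 * rho) * h

    # back to the voxel grid
    gx = origin[0] + np.arange(nx) * spacing[0] - cx
    gy = origin[1] + np.arange(ny) * spacing[1] - cy
    va = gx[:, None] * e1[0] + gy[None, :] * e1[1]
    vs = gx[:, None] * u[0] + gy[None, :] * u[1]
    back = np.empty((nx, ny, nz, 3))
    back[..., 0] = ((va - amin) / h)[..., None]
    back[..., 1] = ((vs - smin) / h)[..., None]
    back[..., 2] = iz[None, None, :]
    return sample_volume(wbf, back, zero_outside=False)


class DoseCalculator:
    """Caches per-beam geometry and WEPL for one (plan template, anatomy) pair.

    All heavy lifting — scenario doses and influence matrices — goes through
    this object so that repeated evaluations (optimization, scenario sweeps,
    fraction simulation) reuse the radiological-depth fields.
    """

    def __init__(self, plan: Plan, anatomy, falloff_sigma=3.0, isocenter=None):
        self.plan = plan
        self.falloff_sigma = float(falloff_sigma)
        self.density = np.ascontiguousarray(anatomy.density, dtype=np.float64)
        self.spacing = tuple(anatomy.spacing)
        self.origin = tuple(anatomy.origin)
        self.shape = self.density.shape
        self.iso = np.asarray(
            plan.isocenter if isocenter is None else isocenter, dtype=np.float64
        )
        self.medium = np.ascontiguousarray((self.density > 1e-3).astype(np.uint8))

        nx, ny, nz = self.shape
        gx = self.origin[0] + np.arange(nx) * self.spacing[0]
        gy = self.origin[1] + np.arange(ny) * self.spacing[1]
        gz = self.origin[2] + np.arange(nz) * self.spacing[2]
        self._beams = []
        # WEPL depends only on (anatomy, gantry angle); cache it on the
        # anatomy object so plans sharing an anatomy reuse the fields
        cache = getattr(anatomy, "_wepl_cache", None)
        if cache is None:
            cache = {}
            try:
                object.__setattr__(anatomy, "_wepl_cache", cache)
            except (AttributeError, TypeError):
                cache = None
        for b in plan.beams:
            e1, _, _ = beam_unit_vectors(b.gantry_angle)
            l1 = (gx[:, None] - self.iso[0]) * e1[0] + (gy[None, :] - self.iso[1]) * e1[1]
            flat = np.ascontiguousarray(l1).ravel()
            order = np.argsort(flat, kind="stable")
            zc = gz - self.iso[2]
            key = round(float(b.gantry_angle), 6)
            if cache is not None and key in cache:
                wepl = cache[key]
            else:
                wepl = radiological_depth(
                    self.density, self.spacing, self.origin, b.gantry_angle
                )
                if cache is not None:
                    cache[key] = wepl
            spots = b.spots
            self._beams.append(
                {
                    "e1": e1,
                    "l1_sorted": np.ascontiguousarray(flat[order]),
                    "l1_order": np.ascontiguousarray(order.astype(np.int64)),
                    "zc": np.ascontiguousarray(zc),
                    "wepl": np.ascontiguousarray(wepl),
                    "p1": np.array([s.lateral_position[0] for s in spots]),
                    "p2": np.array([s.lateral_position[1] for s in spots]),
                    "rng": np.array([s.nominal_range for s in spots]),
                    "sig": np.array([s.sigma_lateral for s in spots]),
                    "n": len(spots),
                }
            )
        self._slices = []
        i = 0
        for bd in self._beams:
            self._slices.append(slice(i, i + bd["n"]))
            i += bd["n"]
        self.n_spots = i

    # -- dose ---------------------------------------------------------------

    def dose_values(self, scenario: ScenarioSpec = NOMINAL, weights=None) -> np.ndarray:
        """Total-course dose array in Gy(RBE) for a scenario."""
        w = self.plan.weights if weights is None else np.asarray(weights, np.float64)
        if w.shape != (self.n_spots,):
            raise ValueError("weight vector length mismatch")
        if np.any(w < 0):
            raise ValueError("spot weights must be non-negative")
        shift = np.asarray(scenario.isocenter_shift, dtype=np.float64)
        dose = np.zeros(self.shape, dtype=np.float64)
        for bd, sl in zip(self._beams, self._slices):
            ws = w[sl]
            nz = np.flatnonzero(ws)
            if nz.size == 0:
                continue
            d1 = float(shift @ bd["e1"])
            d2 = float(shift[2])
            deposit_spots(
                dose, bd["l1_sorted"], bd["l1_order"], bd["zc"], bd["wepl"],
                scenario.density_scale, d1, d2,
                np.ascontiguousarray(bd["p1"][nz]), np.ascontiguousarray(bd["p2"][nz]),
                np.ascontiguousarray(bd["rng"][nz]), np.ascontiguousarray(ws[nz]),
                np.ascontiguousarray(bd["sig"][nz]), self.falloff_sigma,
                self.medium,
            )
        dose *= self.plan.rbe_factor
        return dose

    def dose(self, scenario: ScenarioSpec = NOMINAL, weights=None) -> DoseGrid:
        return DoseGrid(self.dose_values(scenario, weights), self.spacing, self.origin)

    # -- influence ----------------------------------------------------------

    def influence(self, scenario: ScenarioSpec = NOMINAL, rows=None) -> sparse.csc_matrix:
        """Sparse (n_rows x n_spots) matrix of per-unit-weight dose in Gy(RBE).

        With ``rows=None`` all voxels are included (flat C order), so that
        ``dose_values().ravel() == influence @ weights`` to numerical
        precision.  ``rows`` may be a flat voxel-index array (or boolean
        mask); the matrix is then restricted to those voxels in the given
        order, which is how the optimizer keeps its subproblems small.
        """
        shift = np.asarray(scenario.isocenter_shift, dtype=np.float64)
        nvox = int(np.prod(self.shape))
        if rows is None:
            row_idx = None
            n_rows = nvox
            row_map = np.arange(nvox, dtype=np.int64)
        else:
            rows = np.asarray(rows)
            row_idx = np.flatnonzero(rows.ravel()) if rows.dtype == bool else rows.ravel()
            n_rows = row_idx.size
            row_map = np.full(nvox, -1, dtype=np.int64)
            row_map[row_idx] = np.arange(n_rows, dtype=np.int64)
        h = self.spacing[0]
        cols = []
        for bd in self._beams:
            if bd["n"] == 0:
                cols.append(sparse.csc_matrix((n_rows, 0)))
                continue
            cut = LATERAL_CUTOFF_SIGMA * bd["sig"].max()
            band = int(2 * np.ceil(cut * 1.5 / h)) + 3
            zwin = int(2 * np.ceil(cut / self.spacing[2])) + 3
            cap = bd["n"] * min(
                self.shape[0] * self.shape[1], band * max(self.shape[:2])
            ) * min(zwin, self.shape[2])
            cap = min(cap, bd["n"] * max(n_rows, 1))
            d1 = float(shift @ bd["e1"])
            d2 = float(shift[2])
            n = -1
            while n < 0:
                idx = np.empty(cap, dtype=np.int64)
                val = np.empty(cap, dtype=np.float64)
                indptr = np.zeros(bd["n"] + 1, dtype=np.int64)
                n = spot_columns(
                    bd["l1_sorted"], bd["l1_order"], bd["zc"], bd["wepl"],
                    scenario.density_scale, d1, d2,
                    bd["p1"], bd["p2"], bd["rng"], bd["sig"],
                    self.falloff_sigma, self.medium, row_map, idx, val, indptr,
                )
                cap *= 2
            cols.append(
                sparse.csc_matrix(
                    (val[:n] * self.plan.rbe_factor, idx[:n], indptr),
                    shape=(n_rows, bd["n"]),
                )
            )
        return sparse.hstack(cols, format="csc")


def compute_plan_dose(plan: Plan, anatomy, scenario: ScenarioSpec = NOMINAL,
                      falloff_sigma=3.0) -> DoseGrid:
    """Total-course dose of a plan on an anatomy under one scenario."""
    return DoseCalculator(plan, anatomy, falloff_sigma).dose(scenario)


def dose_influence_matrix(plan: Plan, anatomy, scenario: ScenarioSpec = NOMINAL,
                          falloff_sigma=3.0) -> sparse.csc_matrix:
    """Per-spot influence matrix (voxels x spots); see DoseCalculator.influence."""
    return DoseCalculator(plan, anatomy, falloff_sigma).influence(scenario)
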