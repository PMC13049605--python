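"""DVH metrics, scenario aggregation and the 3D robustness evaluation (3DREM).

The 3DREM stage evaluates a plan on the planning (average) anatomy over the
28-scenario evaluation set, aggregates the per-scenario doses into the
voxel-wise minimum distribution, and applies the clinical coverage gate to the
target: D98 (as % of prescription) must exceed 95 and V95 must exceed 98 in
the voxel-wise minimum dose.  Organ-of-interest (OOI) metrics are reported on
the nominal dose.

DVHs are exact voxel-sample DVHs (no binning).  D-at-volume uses the floor
convention — the minimum dose of the hottest floor(v% * n) voxels — which is
conservative for coverage gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_engine import DoseCalculator, Plan, ScenarioSpec
from .grid import DoseGrid
from .phantom4d import OOI_NAMES

__all__ = [
    "DVH",
    "CoverageVerdict",
    "OOIMetrics",
    "voxelwise_min",
    "voxelwise_mean",
    "dvh",
    "dose_at_volume",
    "volume_at_dose",
    "coverage_verdict",
    "ooi_metrics",
    "run_3drem",
    "ThreeDREMResult",
]


@dataclass
class DVH:
    structure_name: str
    samples: np.ndarray       # per-voxel doses, sorted descending, Gy(RBE)
    voxel_volume_cm3: float

    @property
    def n_voxels(self) -> int:
        return len(self.samples)


@dataclass
class CoverageVerdict:
    d98_pct_of_rx: float
    v95_pct: float
    passed: bool


@dataclass
class OOIMetrics:
    """Mean OOI doses plus the lung/breast relative-volume metrics."""

    mean_dose: dict[str, float]      # Gy(RBE) per structure
    vx_pct: dict[str, float]         # % of structure volume
    vx_cm3: dict[str, float]         # absolute volume


def _check_geometry(doses):
    if len(doses) == 0:
        raise ValueError("need at least one dose grid")
    first = doses[0]
    for d in doses[1:]:
        if not first.same_geometry(d):
            raise ValueError("dose grids have mismatching geometry")


def voxelwise_min(doses: list[DoseGrid]) -> DoseGrid:
    """Per-voxel minimum across scenario doses — the worst-case distribution."""
    _check_geometry(doses)
    out = doses[0].values.copy()
    for d in doses[1:]:
        np.minimum(out, d.values, out=out)
    return doses[0].copy_with(out)


def voxelwise_mean(doses: list[DoseGrid]) -> DoseGrid:
    """Per-voxel arithmetic mean across scenario doses."""
    _check_geometry(doses)
    out = doses[0].values.astype(np.float64).copy()
    for d in doses[1:]:
        out += d.values
    return doses[0].copy_with(out / len(doses))


def dvh(dose: DoseGrid, mask: np.ndarray, structure_name: str = "structure") -> DVH:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask shape does not match dose grid")
    if not mask.any():
        raise ValueError(f"empty mask for structure {structure_name!r}")
    samples = np.sort(dose.values[mask])[::-1]
    return DVH(structure_name, samples, dose.voxel_volume_cm3)


def dose_at_volume(d: DVH, volume_pct: float) -> float:
    """Minimum dose received by the hottest ``volume_pct`` of the structure
    (floor convention, no interpolation)."""
    if not (0 < volume_pct <= 100):
        raise ValueError("volume_pct must be in (0, 100]")
    k = int(np.floor(volume_pct / 100.0 * d.n_voxels))
    k = max(k, 1)
    return float(d.samples[k - 1])


def volume_at_dose(d: DVH, dose_threshold: float) -> tuple[float, float]:
    """(percent of structure volume, absolute cm^3) receiving >= threshold."""
    if dose_threshold < 0:
        raise ValueError("dose threshold must be non-negative")
    count = int(np.count_nonzero(d.samples >= dose_threshold))
    return 100.0 * count / d.n_voxels, count * d.voxel_volume_cm3


def coverage_verdict(dose: DoseGrid, target_mask, prescription: float,
                     structure_name: str = "target") -> CoverageVerdict:
    """Clinical coverage gate: D98 > 95 % of prescription and V95 > 98 %."""
    h = dvh(dose, target_mask, structure_name)
    d98 = 100.0 * dose_at_volume(h, 98.0) / prescription
    v95, _ = volume_at_dose(h, 0.95 * prescription)
    return CoverageVerdict(d98, v95, bool(d98 > 95.0 and v95 > 98.0))


def ooi_metrics(dose: DoseGrid, masks: dict[str, np.ndarray], prescription: float,
                lung_v_pct: float = 5.0, breast_v_pct: float = 4.0) -> OOIMetrics:
    """Mean dose of every OOI; lung V5 and breast V4 (thresholds as % of the
    prescription dose), in both % of structure volume and cm^3."""
    means, vpct, vcm3 = {}, {}, {}
    for name in OOI_NAMES:
        mask = masks.get(name)
        if mask is None or not mask.any():
            continue
        h = dvh(dose, mask, name)
        means[name] = float(h.samples.mean())
        if name == "lungs":
            thr = lung_v_pct / 100.0 * prescription
        elif name.startswith("breast"):
            thr = breast_v_pct / 100.0 * prescription
        else:
            continue
        p, v = volume_at_dose(h, thr)
        vpct[name], vcm3[name] = p, v
    return OOIMetrics(means, vpct, vcm3)


@dataclass
class ThreeDREMResult:
    voxelwise_min: DoseGrid
    verdict: CoverageVerdict
    per_scenario: pd.DataFrame
    nominal_dose: DoseGrid
    ooi: OOIMetrics


def run_3drem(
    plan: Plan,
    anatomy,
    su_mm: float,
    ru_pct: float,
    target_mask: np.ndarray,
    ooi_masks: dict[str, np.ndarray] | None = None,
    calculator: DoseCalculator | None = None,
) -> ThreeDREMResult:
    """Voxel-wise-minimum robustness evaluation on the planning anatomy.

    Computes all evaluation-scenario doses (28 for positive uncertainties; the
    degenerate ``su_mm = 0`` case evaluates the nominal scenario only),
    aggregates the voxel-wise minimum, gates target coverage on it, and
    reports OOI metrics on the nominal dose.
    """
    from .scenarios import evaluation_scenarios  # local import avoids a cycle

    calc = calculator or DoseCalculator(plan, anatomy)
    if su_mm > 0:
        scen_set = evaluation_scenarios(su_mm, ru_pct)
        specs = list(scen_set.scenarios)
    else:
        specs = [ScenarioSpec()]
    nominal = calc.dose()
    doses = [calc.dose(s) for s in specs]
    vmin = voxelwise_min(doses)
    rx = plan.prescription_dose
    verdict = coverage_verdict(vmin, target_mask, rx)
    rows = []
    for spec, dg in zip(specs, doses):
        h = dvh(dg, target_mask, "target")
        d98 = 100.0 * dose_at_volume(h, 98.0) / rx
        v95, _ = volume_at_dose(h, 0.95 * rx)
        rows.append(
            {
                "dx_mm": spec.isocenter_shift[0],
                "dy_mm": spec.isocenter_shift[1],
                "dz_mm": spec.isocenter_shift[2],
                "density_scale": spec.density_scale,
                "target_d98_pct": d98,
                "target_v95_pct": v95,
            }
        )
    masks = ooi_masks if ooi_masks is not None else getattr(anatomy, "masks", {})
    ooi = ooi_metrics(nominal, masks, rx)
    return ThreeDREMResult(vmin, verdict, pd.DataFrame(rows), nominal, ooi)
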