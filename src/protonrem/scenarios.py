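"""Setup/range uncertainty scenario enumeration and per-fraction error sampling.

Three scenario families drive the pipeline:

* optimization — 7 isocenter shifts (none, +/- along each axis) x 3 density
  scales (1-ru, 1, 1+ru): 21 scenarios, the worst-case set used by robust
  optimization;
* evaluation — 14 shifts (+/- along each axis and each body diagonal) x 2
  density scales (1-ru, 1+ru): 28 scenarios, the voxel-wise minimum
  robustness-evaluation set;
* fraction — random systematic + per-fraction setup errors (van Herk style)
  with systematic range levels, for longitudinal 4D evaluation.

Enumeration order is deterministic: nominal first, axes in x, y, z order with
the negative shift before the positive, diagonals in lexicographic sign order,
density scales nested innermost from low to high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_engine import ScenarioSpec

__all__ = [
    "ScenarioSet",
    "FractionErrorModel",
    "FractionScenarioTable",
    "optimization_scenarios",
    "evaluation_scenarios",
    "sample_fraction_errors",
]

# van Herk margin recipe M = 2.5 Sigma + 0.7 sigma; with Sigma = sigma a total
# magnitude M maps to component SDs of M / 3.2
_VAN_HERK_DIVISOR = 2.5 + 0.7


@dataclass
class ScenarioSet:
    scenarios: list[ScenarioSpec]
    setup_uncertainty_mm: float
    range_uncertainty_pct: float
    kind: str  # "optimization" | "evaluation" | "fraction"

    def __len__(self):
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    def __getitem__(self, i):
        return self.scenarios[i]


def _density_scales(ru_pct: float, include_nominal: bool) -> list[float]:
    if ru_pct == 0:
        return [1.0]
    lo, hi = 1.0 - ru_pct / 100.0, 1.0 + ru_pct / 100.0
    return [lo, 1.0, hi] if include_nominal else [lo, hi]


def optimization_scenarios(su_mm: float, ru_pct: float) -> ScenarioSet:
    """The 7 x 3 = 21 worst-case optimization scenarios (7 shifts if ru = 0)."""
    if su_mm <= 0:
        raise ValueError("setup uncertainty must be positive")
    if ru_pct < 0:
        raise ValueError("range uncertainty must be non-negative")
    shifts = [(0.0, 0.0, 0.0)]
    for axis in range(3):
        for sign in (-1.0, 1.0):
            v = [0.0, 0.0, 0.0]
            v[axis] = sign * su_mm
            shifts.append(tuple(v))
    scales = _density_scales(ru_pct, include_nominal=True)
    specs = [
        ScenarioSpec(isocenter_shift=s, density_scale=d) for s in shifts for d in scales
    ]
    return ScenarioSet(specs, float(su_mm), float(ru_pct), "optimization")


def evaluation_scenarios(
    su_mm: float, ru_pct: float, diagonal_convention: str = "norm"
) -> ScenarioSet:
    """The 14 x 2 = 28 voxel-wise-minimum evaluation scenarios.

    ``diagonal_convention``: "norm" places the 8 body-diagonal shifts on the
    setup-uncertainty sphere (direction (+/-1, +/-1, +/-1)/sqrt(3)); "component"
    gives each component the full magnitude instead.
    """
    if su_mm <= 0:
        raise ValueError("setup uncertainty must be positive")
    if ru_pct <= 0:
        raise ValueError("range uncertainty must be positive")
    if diagonal_convention not in ("norm", "component"):
        raise ValueError("diagonal_convention must be 'norm' or 'component'")
    shifts = []
    for axis in range(3):
        for sign in (-1.0, 1.0):
            v = [0.0, 0.0, 0.0]
            v[axis] = sign * su_mm
            shifts.append(tuple(v))
    comp = su_mm / np.sqrt(3.0) if diagonal_convention == "norm" else su_mm
    for sx in (-1.0, 1.0):
        for sy in (-1.0, 1.0):
            for sz in (-1.0, 1.0):
                shifts.append((sx * comp, sy * comp, sz * comp))
    scales = _density_scales(ru_pct, include_nominal=False)
    specs = [
        ScenarioSpec(isocenter_shift=s, density_scale=d) for s in shifts for d in scales
    ]
    return ScenarioSet(specs, float(su_mm), float(ru_pct), "evaluation")


@dataclass
class FractionErrorModel:
    """Residual (post-correction) geometric errors applied per fraction.

    The total setup magnitude is decomposed van Herk style into equal
    systematic and random component SDs unless explicit SDs are given.
    Systematic range errors take one of ``range_levels_pct`` per scenario.
    """

    total_setup_mm: float = 2.0
    systematic_sd_mm: float | None = None
    random_sd_mm: float | None = None
    range_levels_pct: tuple[float, ...] = (-3.0, 0.0, 3.0)

    def component_sds(self) -> tuple[float, float]:
        default = self.total_setup_mm / _VAN_HERK_DIVISOR
        sys_sd = default if self.systematic_sd_mm is None else self.systematic_sd_mm
        rnd_sd = default if self.random_sd_mm is None else self.random_sd_mm
        return float(sys_sd), float(rnd_sd)


@dataclass
class FractionScenarioTable:
    """Per-(scenario, fraction) perturbations for longitudinal evaluation."""

    specs: list[list[ScenarioSpec]]        # [scenario][fraction]
    systematic_shifts: np.ndarray          # (n_scenarios, 3) mm
    range_levels_pct: np.ndarray           # (n_scenarios,)

    @property
    def n_scenarios(self):
        return len(self.specs)

    @property
    def n_fractions(self):
        return len(self.specs[0]) if self.specs else 0


def _balanced_levels(levels, n):
    """Assign range levels to n scenarios as evenly as possible, extremes
    favoured when the count does not divide (e.g. 14 -> 5 / 4 / 5)."""
    levels = list(levels)
    k = len(levels)
    base, extra = divmod(n, k)
    counts = [base] * k
    order = sorted(range(k), key=lambda i: (-abs(levels[i]), levels[i]))
    for i in range(extra):
        counts[order[i % k]] += 1
    out = []
    for lv, c in zip(levels, counts):
        out.extend([lv] * c)
    return np.array(out[:n], dtype=np.float64)


def sample_fraction_errors(
    model: FractionErrorModel,
    n_fractions: int = 8,
    n_scenarios: int = 14,
    seed: int = 0,
) -> FractionScenarioTable:
    """Draw the per-scenario systematic and per-fraction random setup errors.

    Each scenario carries one systematic shift (fixed across its fractions)
    plus independent per-fraction random shifts, both isotropic zero-mean
    Gaussians, and one systematic range level.  Reproducible under ``seed``.
    """
    if n_fractions < 1 or n_scenarios < 1:
        raise ValueError("n_fractions and n_scenarios must be >= 1")
    sys_sd, rnd_sd = model.component_sds()
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 424243])
    systematic = rng.normal(0.0, sys_sd, size=(n_scenarios, 3)) if sys_sd > 0 else np.zeros((n_scenarios, 3))
    random = rng.normal(0.0, rnd_sd, size=(n_scenarios, n_fractions, 3)) if rnd_sd > 0 else np.zeros((n_scenarios, n_fractions, 3))
    levels = _balanced_levels(model.range_levels_pct, n_scenarios)
    specs = []
    for s in range(n_scenarios):
        row = []
        for f in range(n_fractions):
            shift = systematic[s] + random[s, f]
            row.append(
                ScenarioSpec(
                    isocenter_shift=tuple(shift),
                    density_scale=1.0 + levels[s] / 100.0,
                )
            )
        specs.append(row)
    return FractionScenarioTable(specs, systematic, levels)
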