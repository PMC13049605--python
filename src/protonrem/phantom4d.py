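"""Synthetic 4D thorax phantom: 10-phase breathing anatomy with known motion.

The phantom emulates the imaging inputs of a mediastinal proton-therapy
workflow: a 10-phase respiratory 4DCT of a thorax-like geometry (body, lungs,
heart, left/right breast, thyroid, esophagus) with a clinical target volume
(CTV) in the mediastinum, plus weekly anatomy snapshots over the treatment
course.  Breathing is modelled as a single smooth spatial envelope times a
sinusoidal phase factor, largest in the caudal mediastinum, so every
deformation field is analytically known and exactly consistent across phases.

Displacement-field convention
-----------------------------
``AnatomyPhase.dvf_to_reference`` is stored on the *reference* (end-of-exhale)
grid and points reference -> phase: a reference point ``x`` corresponds to
``x + dvf(x)`` in that phase.  This is the fixed-image-equals-reference
convention of deformable registration, and it is exactly the field needed to
pull a phase dose back onto the reference frame (see ``eval4d.warp_dose``).
The matching phase -> reference inverse is used internally to construct the
phase images and is accurate to well below 0.1 voxel by fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._kernels import sample_volume
from .grid import centered_origin

__all__ = [
    "PhantomConfig",
    "AnatomyPhase",
    "Phantom4D",
    "MotionStats",
    "generate_phantom",
    "compute_motion_stats",
    "build_itv",
    "make_average_ct",
    "sample_weekly_anatomy",
]

OOI_NAMES = ("heart", "lungs", "breast_l", "breast_r", "thyroid", "esophagus")
STRUCTURE_NAMES = ("body", "ctv") + OOI_NAMES


@dataclass
class PhantomConfig:
    """Geometry, densities and motion/variation magnitudes of the phantom.

    All positions are world coordinates in mm with the grid centered on the
    origin; densities are relative stopping-power surrogates (water = 1).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 3.0

    body_radii: tuple[float, float, float] = (60.0, 56.0, 64.0)
    lung_offset: tuple[float, float, float] = (32.0, 0.0, 2.0)  # mirrored in x
    lung_radii: tuple[float, float, float] = (20.0, 28.0, 42.0)
    heart_center: tuple[float, float, float] = (8.0, 10.0, -20.0)
    heart_radius: float = 16.0
    ctv_center: tuple[float, float, float] = (0.0, -6.0, 8.0)
    ctv_radii: tuple[float, float, float] = (12.0, 10.0, 14.0)
    breast_offset: tuple[float, float, float] = (30.0, -42.0, -6.0)  # mirrored in x
    breast_radius: float = 15.0
    thyroid_center: tuple[float, float, float] = (0.0, -6.0, 46.0)
    thyroid_radius: float = 7.0
    esophagus_xy: tuple[float, float] = (0.0, 14.0)
    esophagus_radius: float = 5.0

    body_density: float = 1.0
    lung_density: float = 0.26
    heart_density: float = 1.05
    breast_density: float = 0.95

    n_phases: int = 10
    reference_phase: int = 5  # end-of-exhale by convention

    target_peak_motion_mm: float = 10.0
    motion_direction: tuple[float, float, float] = (0.0, 0.35, 0.94)
    motion_envelope_offset_mm: tuple[float, float, float] = (0.0, 6.0, -16.0)
    motion_envelope_sigma_mm: tuple[float, float, float] = (14.0, 14.0, 16.0)

    n_weeks: int = 8
    weekly_variation_mm: float = 2.0
    weekly_density_drift: float = 0.0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if not (0 <= self.reference_phase < self.n_phases):
            raise ValueError("reference_phase out of range")
        if self.target_peak_motion_mm < 0 or self.weekly_variation_mm < 0:
            raise ValueError("motion magnitudes must be non-negative")


@dataclass
class AnatomyPhase:
    """One respiratory phase: density, structure masks and its DVF."""

    density: np.ndarray                    # (nx, ny, nz) float32
    masks: dict[str, np.ndarray]           # name -> bool array
    dvf_to_reference: np.ndarray           # (nx, ny, nz, 3) mm, see module docstring
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @property
    def shape(self):
        return self.density.shape


@dataclass
class MotionStats:
    mean_motion_mm: float
    point_max_motion_mm: float


@dataclass
class Phantom4D:
    """10-phase anatomy plus weekly snapshots, with analytically known motion."""

    phases: list[AnatomyPhase]
    reference_phase_index: int
    weekly_variants: list["Phantom4D"]
    voxel_spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    rng_seed: int
    config: PhantomConfig
    # internal ground truth used to build weekly variants cheaply
    _amplitude: np.ndarray = field(default=None, repr=False)   # (nx,ny,nz) mm
    _direction: np.ndarray = field(default=None, repr=False)   # unit 3-vector
    _phase_factors: np.ndarray = field(default=None, repr=False)
    _phase_inverses: list = field(default=None, repr=False)    # index units

    @property
    def reference(self) -> AnatomyPhase:
        return self.phases[self.reference_phase_index]

    @property
    def n_phases(self) -> int:
        return len(self.phases)


# ---------------------------------------------------------------------------
# geometry rasterization


def _coords(config: PhantomConfig):
    shape = tuple(int(n) for n in config.grid_shape)
    spacing = (config.spacing_mm,) * 3
    origin = centered_origin(shape, spacing)
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    return shape, spacing, origin, axes


def _ellipsoid(axes, center, radii):
    x, y, z = axes
    q = (
        ((x[:, None, None] - center[0]) / radii[0]) ** 2
        + ((y[None, :, None] - center[1]) / radii[1]) ** 2
        + ((z[None, None, :] - center[2]) / radii[2]) ** 2
    )
    return q <= 1.0


def _rasterize(config: PhantomConfig):
    """Reference-phase density and masks.  Overlaps resolved so structure
    masks are pairwise disjoint (CTV has priority, then heart, lungs, ...)."""
    shape, spacing, origin, axes = _coords(config)
    c = config
    body = _ellipsoid(axes, (0.0, 0.0, 0.0), c.body_radii)
    ctv = _ellipsoid(axes, c.ctv_center, c.ctv_radii) & body
    heart = _ellipsoid(axes, c.heart_center, (c.heart_radius,) * 3) & body & ~ctv
    lox, loy, loz = c.lung_offset
    lungs = (
        _ellipsoid(axes, (lox, loy, loz), c.lung_radii)
        | _ellipsoid(axes, (-lox, loy, loz), c.lung_radii)
    ) & body & ~ctv & ~heart
    bx, by, bz = c.breast_offset
    taken = ctv | heart | lungs
    breast_l = _ellipsoid(axes, (bx, by, bz), (c.breast_radius,) * 3) & body & ~taken
    breast_r = _ellipsoid(axes, (-bx, by, bz), (c.breast_radius,) * 3) & body & ~taken
    thyroid = (
        _ellipsoid(axes, c.thyroid_center, (c.thyroid_radius,) * 3) & body & ~taken
    )
    ex, ey = c.esophagus_xy
    x, y = axes[0], axes[1]
    tube = (
        ((x[:, None, None] - ex) ** 2 + (y[None, :, None] - ey) ** 2)
        <= c.esophagus_radius**2
    ) & body
    esophagus = tube & ~(taken | thyroid)

    if not ctv.any():
        raise ValueError("phantom configuration produced an empty CTV")

    density = np.zeros(shape, dtype=np.float32)
    density[body] = c.body_density
    density[lungs] = c.lung_density
    density[heart] = c.heart_density
    density[breast_l | breast_r] = c.breast_density
    density[ctv] = c.body_density

    masks = {
        "body": body,
        "ctv": ctv,
        "heart": heart,
        "lungs": lungs,
        "breast_l": breast_l,
        "breast_r": breast_r,
        "thyroid": thyroid,
        "esophagus": esophagus,
    }
    return density, masks, spacing, origin, axes


# ---------------------------------------------------------------------------
# motion model


def _phase_factor(config: PhantomConfig) -> np.ndarray:
    """Breathing state per phase, 0 at the end-of-exhale reference, 1 at peak."""
    p = np.arange(config.n_phases)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (p - config.reference_phase) / config.n_phases))


def _motion_envelope(config: PhantomConfig, axes, ctv_mask) -> np.ndarray:
    """Per-voxel motion amplitude (mm), rescaled so that the realized
    point-max over the CTV equals ``target_peak_motion_mm``."""
    if config.target_peak_motion_mm == 0:
        return np.zeros(tuple(len(a) for a in axes), dtype=np.float64)
    cx, cy, cz = (
        config.ctv_center[a] + config.motion_envelope_offset_mm[a] for a in range(3)
    )
    sx, sy, sz = config.motion_envelope_sigma_mm
    x, y, z = axes
    q = (
        ((x[:, None, None] - cx) / sx) ** 2
        + ((y[None, :, None] - cy) / sy) ** 2
        + ((z[None, None, :] - cz) / sz) ** 2
    )
    env = np.exp(-0.5 * q)
    peak = env[ctv_mask].max()
    return env * (config.target_peak_motion_mm / peak)


def _invert_forward(disp_vox, support, max_iter=60, tol_vox=0.01, init=None):
    """Inverse displacement (index units) of the forward map x -> x + disp(x).

    Fixed-point iteration ``u <- -disp(y + u)`` restricted to voxels where the
    field is non-negligible; converges because the forward map is constructed
    with Jacobian norm < 1.  ``init`` warm-starts the iteration (used for
    weekly variants, whose fields differ from the planning phantom's by a
    small bounded perturbation).
    """
    shape = disp_vox.shape[:3]
    inv = np.zeros_like(disp_vox)
    mag = np.linalg.norm(disp_vox, axis=-1)
    if support is None:
        # a point can have a displaced preimage if it lies within the forward
        # support expanded by the largest displacement
        reach = int(np.ceil(mag.max())) + 1
        act = ndimage.binary_dilation(mag > tol_vox, iterations=reach)
    else:
        act = support
    idx = np.argwhere(act)
    if idx.size == 0:
        return inv
    base = idx.astype(np.float64)
    u = init[act].astype(np.float64) if init is not None else np.zeros_like(base)
    comps = [np.ascontiguousarray(disp_vox[..., a]) for a in range(3)]
    for _ in range(max_iter):
        pts = base + u
        new = np.stack(
            [-sample_volume(comps[a], pts, zero_outside=False) for a in range(3)],
            axis=-1,
        )
        delta = np.abs(new - u).max() if u.size else 0.0
        u = new
        if delta < tol_vox:
            break
    inv[act] = u
    return inv


def _build_phase(ref_density, ref_masks, forward_mm, spacing, origin,
                 init_inv=None, return_inverse=False):
    """Construct one phase by resampling the reference through the inverse of
    the forward (reference -> phase) displacement."""
    h = spacing[0]
    disp_vox = forward_mm / h
    if not np.any(disp_vox):
        phase = AnatomyPhase(
            density=ref_density.copy(),
            masks={k: v.copy() for k, v in ref_masks.items()},
            dvf_to_reference=np.asarray(forward_mm, dtype=np.float32).copy(),
            spacing=spacing,
            origin=origin,
        )
        return (phase, np.zeros_like(disp_vox)) if return_inverse else phase
    inv_vox = _invert_forward(disp_vox.astype(np.float64), None, init=init_inv)
    shape = ref_density.shape
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij"),
        axis=-1,
    )
    src = grid + inv_vox
    density = sample_volume(ref_density, src, zero_outside=True).astype(np.float32)
    masks = {}
    for name, m in ref_masks.items():
        # linear interpolation of the indicator, threshold 0.5, ties included
        masks[name] = sample_volume(m.astype(np.float64), src, zero_outside=True) >= 0.5
    phase = AnatomyPhase(
        density=density,
        masks=masks,
        dvf_to_reference=np.asarray(forward_mm, dtype=np.float32),
        spacing=spacing,
        origin=origin,
    )
    return (phase, inv_vox) if return_inverse else phase


# ---------------------------------------------------------------------------
# public operations


def generate_phantom(config: PhantomConfig, seed: int) -> Phantom4D:
    """Build the planning phantom (10 phases) and its weekly variants.

    Deterministic for a fixed ``(config, seed)``.
    """
    config.validate()
    density, masks, spacing, origin, axes = _rasterize(config)
    amp = _motion_envelope(config, axes, masks["ctv"])
    direction = np.asarray(config.motion_direction, dtype=np.float64)
    nrm = np.linalg.norm(direction)
    direction = direction / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
    factors = _phase_factor(config)

    phases = []
    inverses = []
    for p in range(config.n_phases):
        fwd = amp[..., None] * (direction * factors[p])[None, None, None, :]
        phase, inv = _build_phase(density, masks, fwd, spacing, origin,
                                  return_inverse=True)
        phases.append(phase)
        inverses.append(inv)

    phantom = Phantom4D(
        phases=phases,
        reference_phase_index=config.reference_phase,
        weekly_variants=[],
        voxel_spacing=spacing,
        origin=origin,
        rng_seed=int(seed),
        config=config,
        _amplitude=amp,
        _direction=direction,
        _phase_factors=factors,
    )
    phantom._phase_inverses = inverses
    phantom.weekly_variants = [
        sample_weekly_anatomy(phantom, week, seed)
        for week in range(1, config.n_weeks + 1)
    ]
    return phantom


def sample_weekly_anatomy(phantom: Phantom4D, week: int, seed: int) -> Phantom4D:
    """Weekly anatomy snapshot: a smooth random systematic deformation of
    bounded magnitude, composed with the same breathing model.

    The phase DVFs of the snapshot point from the *planning* reference phase,
    which is what longitudinal dose accumulation needs.
    """
    cfg = phantom.config
    if not (1 <= week <= max(cfg.n_weeks, 1)):
        raise ValueError(f"week must be in 1..{max(cfg.n_weeks, 1)}, got {week}")
    ref = phantom.reference
    shape = ref.shape
    spacing = phantom.voxel_spacing

    if cfg.weekly_variation_mm > 0:
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(week)])
        raw = rng.standard_normal(shape + (3,))
        smooth = np.stack(
            [ndimage.gaussian_filter(raw[..., a], sigma=5.0) for a in range(3)],
            axis=-1,
        )
        mag = np.linalg.norm(smooth, axis=-1).max()
        scale = cfg.weekly_variation_mm * rng.uniform(0.5, 1.0) / max(mag, 1e-12)
        weekly = smooth * scale
    else:
        weekly = np.zeros(shape + (3,))

    density = ref.density
    if cfg.weekly_density_drift > 0:
        rng2 = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7919 + int(week)])
        drift = ndimage.gaussian_filter(rng2.standard_normal(shape), sigma=6.0)
        drift /= max(np.abs(drift).max(), 1e-12)
        density = (density * (1.0 + cfg.weekly_density_drift * drift)).astype(np.float32)
        density[~ref.masks["body"]] = 0.0

    amp3 = phantom._amplitude[..., None] * phantom._direction[None, None, None, :]
    inits = getattr(phantom, "_phase_inverses", None)
    phases = []
    if not np.any(weekly) and density is ref.density:
        # no anatomical change this week: the snapshot is the planning 4DCT
        phases = [
            AnatomyPhase(
                density=ph.density.copy(),
                masks={k: v.copy() for k, v in ph.masks.items()},
                dvf_to_reference=ph.dvf_to_reference.copy(),
                spacing=ph.spacing,
                origin=ph.origin,
            )
            for ph in phantom.phases
        ]
    else:
        for p in range(cfg.n_phases):
            fwd = weekly + amp3 * phantom._phase_factors[p]
            init = inits[p] if inits is not None else None
            phases.append(
                _build_phase(density, ref.masks, fwd, spacing, phantom.origin,
                             init_inv=init)
            )
    return Phantom4D(
        phases=phases,
        reference_phase_index=cfg.reference_phase,
        weekly_variants=[],
        voxel_spacing=spacing,
        origin=phantom.origin,
        rng_seed=int(seed),
        config=cfg,
        _amplitude=phantom._amplitude,
        _direction=phantom._direction,
        _phase_factors=phantom._phase_factors,
    )


def compute_motion_stats(phantom: Phantom4D, structure: str = "ctv") -> MotionStats:
    """Mean and point-max of each target voxel's peak displacement magnitude."""
    if phantom.n_phases < 2:
        raise ValueError("motion statistics require at least 2 phases")
    target = phantom.reference.masks.get(structure)
    if target is None or not target.any():
        raise ValueError(f"empty or missing target mask {structure!r}")
    peak = np.zeros(np.count_nonzero(target), dtype=np.float64)
    for phase in phantom.phases:
        vec = phase.dvf_to_reference[target].astype(np.float64)
        np.maximum(peak, np.linalg.norm(vec, axis=-1), out=peak)
    return MotionStats(float(peak.mean()), float(peak.max()))


def build_itv(phantom: Phantom4D) -> np.ndarray:
    """Internal target volume: envelope of the CTV across all breathing phases
    on the common grid."""
    itv = None
    for phase in phantom.phases:
        ctv = phase.masks.get("ctv")
        if ctv is None:
            raise ValueError("every phase must carry a CTV mask")
        itv = ctv.copy() if itv is None else (itv | ctv)
    if itv is None or not itv.any():
        raise ValueError("ITV is empty")
    return itv


def make_average_ct(phantom: Phantom4D) -> AnatomyPhase:
    """Average anatomy on the reference grid: each phase warped to the
    reference through its DVF, then averaged voxel-wise with equal weights.

    Masks come from the reference phase, plus the ITV.
    """
    ref = phantom.reference
    shape = ref.shape
    h = phantom.voxel_spacing[0]
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij"),
        axis=-1,
    )
    acc = np.zeros(shape, dtype=np.float64)
    for phase in phantom.phases:
        src = grid + phase.dvf_to_reference.astype(np.float64) / h
        acc += sample_volume(phase.density, src, zero_outside=True)
    avg = (acc / phantom.n_phases).astype(np.float32)
    masks = {k: v.copy() for k, v in ref.masks.items()}
    masks["itv"] = build_itv(phantom)
    zero = np.zeros(shape + (3,), dtype=np.float32)
    return AnatomyPhase(
        density=avg,
        masks=masks,
        dvf_to_reference=zero,
        spacing=phantom.voxel_spacing,
        origin=phantom.origin,
    )
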