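import numpy as np
import pytest

from protonrem.dose_engine import Beam, Plan, Spot
from protonrem.grid import DoseGrid, centered_origin
from protonrem.phantom4d import (
    AnatomyPhase,
    PhantomConfig,
    generate_phantom,
    make_average_ct,
)

# compact phantom geometry used across the suite: same topology as the
# default thorax, scaled to a 32^3 grid so tests stay fast
SMALL = dict(
    grid_shape=(32, 32, 32),
    spacing_mm=3.0,
    body_radii=(44.0, 42.0, 46.0),
    lung_offset=(24.0, 0.0, 2.0),
    lung_radii=(14.0, 20.0, 30.0),
    heart_center=(6.0, 8.0, -14.0),
    heart_radius=12.0,
    ctv_center=(0.0, -4.0, 6.0),
    ctv_radii=(9.0, 8.0, 10.0),
    breast_offset=(22.0, -30.0, -4.0),
    breast_radius=10.0,
    thyroid_center=(0.0, -4.0, 32.0),
    thyroid_radius=5.0,
)


def small_config(**overrides) -> PhantomConfig:
    kw = dict(SMALL)
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    """Moving phantom, no weekly variants (for speed)."""
    return generate_phantom(small_config(target_peak_motion_mm=8.0, n_weeks=0), seed=7)


@pytest.fixture(scope="session")
def static_phantom():
    return generate_phantom(small_config(target_peak_motion_mm=0.0, n_weeks=0), seed=7)


@pytest.fixture(scope="session")
def small_avg(small_phantom):
    return make_average_ct(small_phantom)


@pytest.fixture(scope="session")
def uniform_anatomy():
    """Unit-density medium filling the whole grid (no air)."""
    shape = (24, 24, 24)
    spacing = (3.0, 3.0, 3.0)
    origin = centered_origin(shape, spacing)
    density = np.ones(shape, dtype=np.float32)
    masks = {"body": np.ones(shape, bool)}
    return AnatomyPhase(
        density=density,
        masks=masks,
        dvf_to_reference=np.zeros(shape + (3,), dtype=np.float32),
        spacing=spacing,
        origin=origin,
    )


def single_spot_plan(weight=1.0, gantry=0.0, nominal_range=40.0, sigma=6.0,
                     lateral=(0.0, 0.0), prescription=30.0, n_fractions=15):
    spot = Spot(lateral_position=lateral, nominal_range=nominal_range,
                weight=weight, sigma_lateral=sigma)
    beam = Beam(gantry_angle=gantry, energy_layers=[(nominal_range, [spot])],
                repaint_factor=1)
    return Plan(beams=[beam], prescription_dose=prescription,
                n_fractions=n_fractions, rbe_factor=1.1)


def grid_of(values, spacing=3.0):
    values = np.asarray(values, dtype=np.float64)
    return DoseGrid(values, (spacing,) * 3, centered_origin(values.shape, (spacing,) * 3))
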