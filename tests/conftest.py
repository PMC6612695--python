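"""Shared fixtures: calibrated physics and one moderate-statistics
collimated field (R10_S5_FS4) reused across transport, tally and
evaluation tests."""

import pytest

from pbscatter.evaluate import fold_quadrants
from pbscatter.geometry import PhantomGrid, TargetSpec, build_scene
from pbscatter.planning import make_plan
from pbscatter.stopping import default_physics
from pbscatter.tally import finalize
from pbscatter.transport import TransportSettings, run_field


@pytest.fixture(scope="session")
def physics():
    return default_physics()


@pytest.fixture(scope="session")
def fast_settings():
    return TransportSettings(max_step_water=0.2)


@pytest.fixture(scope="session")
def r10_case(physics, fast_settings):
    """Planned and simulated R10_S5_FS4 field at moderate statistics."""
    target = TargetSpec(10, 5, 4)
    grid = PhantomGrid.for_target(target, voxel_size=0.2)
    scene = build_scene(target, grid=grid)
    plan = make_plan(target, scene, physics, seed=5, settings=fast_settings,
                     n_calibration=12000, n_per_layer=2500)
    tally = run_field(plan, scene, 40000, seed=6, batches=8,
                      physics=physics, settings=fast_settings)
    dose, letd = finalize(fold_quadrants(tally))
    return {
        "target": target, "scene": scene, "plan": plan, "tally": tally,
        "dose": dose, "letd": letd,
    }
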