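"""User-facing condensed-history transport: scene packing, single-history
tracing and full-field runs.

The numerical work happens in :mod:`pbscatter.kernel`; this module turns
:class:`~pbscatter.geometry.Scene` / physics objects into the flat arrays
the kernel consumes and wraps the results in tally containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernel
from .geometry import Scene
from .materials import ABS, AIR, BRASS, WATER
from .stopping import ProtonPhysics, default_physics

__all__ = ["ProtonState", "TransportSettings", "ScenePack", "pack_scene",
           "step_records", "transport_history", "run_field"]

KERNEL_E0 = 0.1  # MeV, kernel table lower edge
KERNEL_DE = 0.1  # MeV, kernel table spacing
KERNEL_NE = 3000

MATERIAL_ORDER = (WATER, AIR, ABS, BRASS)


@dataclass
class ProtonState:
    """Snapshot of a proton during transport."""

    position: np.ndarray  # cm
    direction: np.ndarray  # unit vector
    energy: float  # MeV
    weight: float = 1.0
    scattered: bool = False
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy < 0 or self.weight <= 0:
            raise ValueError("energy must be >= 0 and weight > 0")


@dataclass(frozen=True)
class TransportSettings:
    """Step caps and physics toggles.

    Default per-material step caps: 1 mm in water and brass, 5 mm in air,
    2 mm in ABS; the 5%-of-residual-range cap applies on top.
    """

    max_step_water: float = 0.1
    max_step_air: float = 0.5
    max_step_abs: float = 0.2
    max_step_brass: float = 0.1
    scattering: bool = True
    straggling: bool = True
    air_energy_loss: bool = True

    def max_steps(self) -> np.ndarray:
        return np.array(
            [self.max_step_water, self.max_step_air,
             self.max_step_abs, self.max_step_brass]
        )


@dataclass(frozen=True)
class ScenePack:
    """Flat-array view of scene + physics for the kernel."""

    sf: np.ndarray  # scene floats, see kernel._material_at
    coll_present: int
    s_tab: np.ndarray  # (4, ne) stopping powers MeV/cm
    r_tab: np.ndarray  # (4, ne) CSDA ranges cm
    max_step: np.ndarray
    hcoef: np.ndarray  # Highland coefficient per material
    bohr: np.ndarray  # straggling variance per cm
    inv_lambda: np.ndarray  # nuclear removal per cm
    grid_pars: tuple  # (gx0, gy0, dvox, nx, ny, nz)
    scene: Scene = field(repr=False, default=None)


def pack_scene(
    scene: Scene,
    physics: ProtonPhysics | None = None,
    settings: TransportSettings | None = None,
) -> ScenePack:
    """Flatten a scene and calibrated physics into kernel arrays.

    The Highland log-correction is evaluated once per material on a
    characteristic slab thickness (absorber and collimator: their physical
    thickness; air: the summed air path; water: the target range), which
    makes the accumulated scattering variance independent of the step size.
    """
    physics = physics or default_physics()
    settings = settings or TransportSettings()
    mats = physics.materials
    energies = KERNEL_E0 + KERNEL_DE * np.arange(KERNEL_NE)
    s_tab = np.empty((4, KERNEL_NE))
    r_tab = np.empty((4, KERNEL_NE))
    loge = np.log(physics.table.energies)
    for i, name in enumerate(MATERIAL_ORDER):
        s_tab[i] = np.exp(
            np.interp(np.log(energies), loge, np.log(physics.table.stopping_powers[name]))
        )
        r_tab[i] = np.exp(
            np.interp(np.log(energies), loge, np.log(physics.table.csda_ranges[name]))
        )
    air_path = (
        (scene.z_absorber_entry - scene.z_source)
        + (scene.z_collimator_entry - scene.z_absorber_exit)
        + (0.0 - scene.z_collimator_exit)
    )
    char = {
        WATER: max(scene.target.range_R, 0.5),
        AIR: max(air_path, 0.1),
        ABS: scene.sra.absorber_thickness,
        BRASS: scene.sra.collimator_thickness,
    }
    hcoef = np.empty(4)
    bohr = np.empty(4)
    inv_lambda = np.empty(4)
    for i, name in enumerate(MATERIAL_ORDER):
        m = mats[name]
        x0 = m.radiation_length_cm
        corr = max(1.0 + np.log10(char[name] / x0) / 9.0, 0.0)
        hcoef[i] = 14.1 * corr / np.sqrt(x0)
        bohr[i] = 0.1569 * m.Z_over_A * m.density
        inv_lambda[i] = m.density / m.nuclear_interaction_length
    g = scene.grid
    sf = np.array(
        [scene.z_source, scene.z_absorber_entry, scene.z_absorber_exit,
         scene.z_collimator_entry, scene.z_collimator_exit, scene.z_water_max,
         scene.sra.aperture_half_x, scene.sra.aperture_half_y,
         scene.lateral_bound]
    )
    return ScenePack(
        sf=sf,
        coll_present=1 if scene.collimator_present else 0,
        s_tab=s_tab,
        r_tab=r_tab,
        max_step=settings.max_steps(),
        hcoef=hcoef,
        bohr=bohr,
        inv_lambda=inv_lambda,
        grid_pars=(g.x_min, g.y_min, g.voxel_size, g.nx, g.ny, g.nz),
        scene=scene,
    )


def _flags(settings: TransportSettings) -> tuple[int, int, int]:
    return (
        1 if settings.scattering else 0,
        1 if settings.straggling else 0,
        1 if settings.air_energy_loss else 0,
    )


def transport_history(
    state: ProtonState,
    pack: ScenePack,
    rng_seed: int = 0,
    primary_index: int = 0,
    settings: TransportSettings | None = None,
    max_records: int = 200000,
    phantom_is_water: bool = True,
):
    """Transport a single history, returning the terminal state, the energy
    ledger and the full step/voxel records.

    Deterministic given (rng_seed, primary_index).  Returns a dict with
    keys ``state``, ``ledger``, ``steps`` (record array of step segments),
    ``voxel_records`` (voxel, eps, letd, channel) and the per-channel tally
    arrays of this single history.
    """
    settings = settings or TransportSettings()
    gx0, gy0, dvox, nx, ny, nz = pack.grid_pars
    nvoxels = nx * ny * nz
    eps_t = np.zeros((1, 2, nvoxels))
    epsL_t = np.zeros((1, 2, nvoxels))
    rec_step = np.zeros((max_records, 12))
    rec_vox = np.zeros(max_records, dtype=np.int64)
    rec_val = np.zeros(max_records)
    rec_L = np.zeros(max_records)
    rec_ch = np.zeros(max_records, dtype=np.int8)
    sc, st, al = _flags(settings)
    rng = np.uint64(kernel.primary_stream(rng_seed, primary_index))
    out = kernel.transport_one(
        state.position[0], state.position[1], state.position[2],
        state.direction[0], state.direction[1], state.direction[2],
        state.energy, state.weight,
        pack.sf, pack.coll_present, 1 if phantom_is_water else 0,
        KERNEL_E0, 1.0 / KERNEL_DE, pack.s_tab, pack.r_tab,
        pack.max_step, pack.hcoef, pack.bohr, pack.inv_lambda,
        sc, st, al,
        gx0, gy0, dvox, nx, ny, nz,
        eps_t, epsL_t, 0, rng,
        rec_step, rec_vox, rec_val, rec_L, rec_ch, 1,
    )
    (deposited, removed, escaped, e_enter, dep_phantom,
     scattered, steps, nvox, nstep, _clip, _rng) = out
    if steps >= kernel.MAX_STEPS:
        raise RuntimeError("runaway history: step limit exceeded")
    ledger = {
        "initial": state.weight * state.energy,
        "deposited": deposited,
        "removed": removed,
        "escaped": escaped,
        "entered_phantom": e_enter,
        "deposited_phantom": dep_phantom,
    }
    return {
        "ledger": ledger,
        "scattered": bool(scattered),
        "n_steps": int(steps),
        "steps": rec_step[:nstep],
        "voxel_records": (
            rec_vox[:nvox], rec_val[:nvox], rec_L[:nvox], rec_ch[:nvox]
        ),
        "eps": eps_t[0],
        "epsL": epsL_t[0],
    }


def step_records(history: dict):
    """Structured view of the raw step records of one history."""
    r = history["steps"]
    return {
        "p0": r[:, 0:3],
        "p1": r[:, 3:6],
        "e_before": r[:, 6],
        "e_after": r[:, 7],
        "deposit": r[:, 8],
        "material": r[:, 9].astype(int),
        "scattered": r[:, 10].astype(bool),
        "weight": r[:, 11],
    }


def run_field(
    plan,
    scene: Scene,
    n_primaries: int,
    seed: int,
    batches: int = 8,
    physics: ProtonPhysics | None = None,
    settings: TransportSettings | None = None,
):
    """Simulate a full plan into a batched tally grid.

    Primaries are assigned to spots by stratified sampling proportional to
    spot weight; tallies are later scaled by ``plan.total_protons /
    n_primaries`` so the grid represents the planned proton count.  Fully
    reproducible given (seed, n_primaries, batches).
    """
    from .tally import TallyGrid  # local import to avoid a cycle

    if len(plan.spots) == 0:
        raise ValueError("plan has no spots")
    if not (n_primaries >= batches >= 2):
        raise ValueError("need n_primaries >= batches >= 2")
    physics = physics or default_physics()
    settings = settings or TransportSettings()
    pack = pack_scene(scene, physics, settings)
    gx0, gy0, dvox, nx, ny, nz = pack.grid_pars
    nvoxels = nx * ny * nz
    eps_t = np.zeros((batches, 2, nvoxels))
    epsL_t = np.zeros((batches, 2, nvoxels))
    sx, sy, se, sp, sa, w = plan.kernel_spot_arrays()
    cumw = np.cumsum(w)
    sc, st, al = _flags(settings)
    ledger = kernel.run_primaries(
        n_primaries, seed, batches,
        sx, sy, se, sp, sa, cumw,
        plan.z_iso, plan.sad_x, plan.sad_y, plan.energy_dispersion,
        pack.sf, pack.coll_present, 1,
        KERNEL_E0, 1.0 / KERNEL_DE, pack.s_tab, pack.r_tab,
        pack.max_step, pack.hcoef, pack.bohr, pack.inv_lambda,
        sc, st, al,
        gx0, gy0, dvox, nx, ny, nz,
        eps_t, epsL_t,
    )
    names = ("initial", "deposited", "removed", "escaped",
             "entered_phantom", "deposited_phantom")
    return TallyGrid(
        eps=eps_t,
        epsL=epsL_t,
        grid=scene.grid,
        n_primaries=n_primaries,
        seed=seed,
        batches=batches,
        proton_scale=plan.total_protons / n_primaries,
        ledger=dict(zip(names, ledger)),
    )
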