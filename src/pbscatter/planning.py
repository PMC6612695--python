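"""Spot-scanning plan construction: energy layers, spot maps, SOBP weights.

A plan delivers a physical dose of 2 Gy to a rectangular target (range R,
SOBP width S, square field FS).  Layers are spaced 5 mm in residual water
range from R down to R - S (clipped at the applicator's 0.5 cm minimum
range); each layer's energy solves the calibrated residual-range relation.
Spot positions form a square 5 mm grid extending one spacing beyond the
field edge; the spot weight profile is uniform within a layer — the brass
collimator, not spot weighting, shapes the penumbra.

Layer weights are fitted by nonnegative least squares so that the
superposed per-layer depth doses of the actual collimated delivery form a
flat plateau over the SOBP span; the absolute proton count is then
rescaled by a short calibration simulation so that the mean unscattered
dose over the central 80% of the target box equals the prescription.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from . import kernel
from .geometry import Scene, TargetSpec, Z_ISO
from .source import BeamSourceModel
from .stopping import ProtonPhysics, default_physics
from .transport import KERNEL_DE, KERNEL_E0, TransportSettings, pack_scene

__all__ = ["Spot", "Plan", "make_layers", "make_spot_map", "sobp_weights",
           "depth_dose_matrix", "make_plan"]

GY_PER_MEV_G = 1.602176634e-10  # Gy per MeV/g
MIN_RANGE = 0.5  # cm, minimum deliverable residual range of the applicator
LAYER_SPACING = 0.5  # cm water
SPOT_SPACING = 0.5  # cm at the isocenter plane
PRESCRIPTION = 2.0  # Gy


@dataclass(frozen=True)
class Spot:
    """One scanned spot: position at the isocenter plane, energy, protons."""

    x_iso: float  # cm
    y_iso: float  # cm
    energy: float  # MeV
    weight: float  # protons

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("spot weight must be >= 0")
        if abs(self.x_iso) > 10.0 or abs(self.y_iso) > 10.0:
            raise ValueError("spot outside the 20 x 20 cm^2 scan area")


@dataclass
class Plan:
    """A deliverable plan: layers, spots, aperture and normalization."""

    target: TargetSpec
    layers: list  # (energy MeV, residual range cm)
    spots: list  # Spot
    aperture: tuple  # (half_x, half_y) cm
    total_protons: float
    prescription: float = PRESCRIPTION
    # per-layer source sigmas and source geometry, for the kernel
    layer_sigmas: dict = field(default_factory=dict)  # energy -> (pos, ang)
    sad_x: float = 200.0
    sad_y: float = 240.0
    energy_dispersion: float = 0.006
    z_iso: float = Z_ISO

    def kernel_spot_arrays(self):
        """Flat spot arrays for the transport kernel."""
        n = len(self.spots)
        sx = np.empty(n)
        sy = np.empty(n)
        se = np.empty(n)
        sp = np.empty(n)
        sa = np.empty(n)
        w = np.empty(n)
        for i, s in enumerate(self.spots):
            sx[i] = s.x_iso
            sy[i] = s.y_iso
            se[i] = s.energy
            sp[i], sa[i] = self.layer_sigmas[s.energy]
            w[i] = s.weight
        return sx, sy, se, sp, sa, w

    def scale_weights(self, factor: float) -> None:
        self.spots = [
            Spot(s.x_iso, s.y_iso, s.energy, s.weight * factor) for s in self.spots
        ]
        self.total_protons *= factor

    def to_file(self, path) -> None:
        """Serialize the plan to a documented JSON text file."""
        doc = {
            "target": {"range_R": self.target.range_R, "sobp_S": self.target.sobp_S,
                       "field_FS": self.target.field_FS, "label": self.target.label},
            "prescription_Gy": self.prescription,
            "aperture_half_cm": list(self.aperture),
            "total_protons": self.total_protons,
            "sad_cm": [self.sad_x, self.sad_y],
            "energy_dispersion": self.energy_dispersion,
            "layers": [
                {"energy_MeV": e, "residual_range_cm": r,
                 "sigma_pos_cm": self.layer_sigmas[e][0],
                 "sigma_ang_rad": self.layer_sigmas[e][1]}
                for e, r in self.layers
            ],
            "spots": [
                {"x_cm": s.x_iso, "y_cm": s.y_iso, "energy_MeV": s.energy,
                 "protons": s.weight}
                for s in self.spots
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_file(cls, path) -> "Plan":
        doc = json.loads(Path(path).read_text())
        t = doc["target"]
        target = TargetSpec(t["range_R"], t["sobp_S"], t["field_FS"])
        layers = [(l["energy_MeV"], l["residual_range_cm"]) for l in doc["layers"]]
        sigmas = {l["energy_MeV"]: (l["sigma_pos_cm"], l["sigma_ang_rad"])
                  for l in doc["layers"]}
        spots = [Spot(s["x_cm"], s["y_cm"], s["energy_MeV"], s["protons"])
                 for s in doc["spots"]]
        return cls(
            target=target, layers=layers, spots=spots,
            aperture=tuple(doc["aperture_half_cm"]),
            total_protons=doc["total_protons"],
            prescription=doc["prescription_Gy"],
            layer_sigmas=sigmas,
            sad_x=doc["sad_cm"][0], sad_y=doc["sad_cm"][1],
            energy_dispersion=doc["energy_dispersion"],
        )


def make_layers(
    target: TargetSpec,
    physics: ProtonPhysics | None = None,
    spacing: float = LAYER_SPACING,
) -> list:
    """Energy layers as (energy MeV, residual range cm), deepest first.

    Residual ranges descend from R to R - S in `spacing` steps; ranges
    below the applicator minimum (0.5 cm) are clipped to it.
    """
    physics = physics or default_physics()
    n = int(round(target.sobp_S / spacing))
    ranges = [target.range_R - k * spacing for k in range(n + 1)]
    ranges = sorted({max(r, MIN_RANGE) for r in ranges}, reverse=True)
    return [(physics.energy_for_residual_range(r), r) for r in ranges]


def make_spot_map(target: TargetSpec, spacing: float = SPOT_SPACING) -> np.ndarray:
    """Square spot grid at the isocenter plane: centred, `spacing` pitch,
    extending one spacing beyond the field edge on each side.  Returns an
    (n, 2) array of (x, y) positions in cm, identical for all layers."""
    half = target.field_FS / 2.0 + spacing
    n_side = int(round(2 * half / spacing)) + 1
    coords = -half + spacing * np.arange(n_side)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def depth_dose_matrix(
    layers: list,
    scene: Scene,
    physics: ProtonPhysics | None = None,
    source: BeamSourceModel | None = None,
    n_per_layer: int = 4000,
    seed: int = 12345,
    dz_bin: float = 0.1,
    settings: TransportSettings | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Broad-beam depth-dose of each layer from a fast pencil pre-simulation.

    Column k holds the laterally integrated depth dose of layer k in
    MeV cm^2/g per proton on a `dz_bin` depth grid, so that a uniform
    fluence `phi` protons/cm^2 gives dose(z) = phi * column (water,
    rho = 1).  Returns (z_centers, matrix)."""
    physics = physics or default_physics()
    source = source or BeamSourceModel()
    settings = settings or TransportSettings()
    pack = pack_scene(scene, physics, settings)
    nbin = int(np.ceil(scene.z_water_max / dz_bin))
    mat = np.zeros((nbin, len(layers)))
    sc = 1 if settings.scattering else 0
    st = 1 if settings.straggling else 0
    al = 1 if settings.air_energy_loss else 0
    for k, (energy, _r) in enumerate(layers):
        dose_z = np.zeros(nbin)
        kernel.pencil_depth_dose(
            n_per_layer, seed + k, energy, source.energy_dispersion,
            pack.sf, KERNEL_E0, 1.0 / KERNEL_DE, pack.s_tab, pack.r_tab,
            pack.max_step, pack.hcoef, pack.bohr, pack.inv_lambda,
            sc, st, al, dz_bin, dose_z,
        )
        mat[:, k] = dose_z / (n_per_layer * dz_bin)  # MeV/cm per proton, rho=1
    z = (np.arange(nbin) + 0.5) * dz_bin
    return z, mat


def sobp_weights(
    layers: list,
    z: np.ndarray,
    ddm: np.ndarray,
    target: TargetSpec,
    prescription: float = PRESCRIPTION,
    margin: float = 0.2,
    column_to_gy: float = GY_PER_MEV_G,
    target_profile: np.ndarray | None = None,
) -> np.ndarray:
    """Nonnegative least-squares layer weights producing a flat
    `prescription` plateau over the SOBP span.

    ``column_to_gy`` converts one matrix column unit to Gy per unit weight:
    for the broad-beam pencil matrix (MeV cm^2/g per proton) the default
    yields fluences in protons/cm^2; for the collimated matrix (already Gy
    per proton) pass 1 to obtain protons per layer.  The fit grid spans
    [R - S + margin, R - margin] cm (single-layer plans match the peak
    instead).  ``target_profile`` (same grid as the matrix rows) replaces
    the flat prescription as the fit target, which lets a calibration pass
    pre-compensate lateral-disequilibrium tilt of small collimated fields.
    Raises if the fitted system is degenerate.
    """
    if len(layers) == 1:
        peak = float(ddm[:, 0].max())
        if peak <= 0:
            raise ValueError("empty depth-dose column for single layer")
        return np.array([prescription / (column_to_gy * peak)])
    lo = target.proximal_depth + margin
    hi = target.range_R - margin
    sel = (z >= lo) & (z <= hi)
    if sel.sum() < len(layers):
        sel = (z >= lo - margin) & (z <= hi + margin)
    a = ddm[sel] * column_to_gy
    if target_profile is None:
        b = np.full(sel.sum(), prescription)
    else:
        b = np.asarray(target_profile)[sel]
    if not np.isfinite(a).all() or a.max() == 0:
        raise ValueError(
            "degenerate depth-dose matrix; layer ranges: "
            + ", ".join(f"{r:.2f}" for _e, r in layers)
        )
    w, _res = nnls(a, b)
    return w


def sobp_flatness(z, ddm, weights, target, margin: float = 0.2) -> float:
    """(max - min)/mean of the fitted SOBP over the fit grid."""
    lo = target.proximal_depth + margin
    hi = target.range_R - margin
    sel = (z >= lo) & (z <= hi)
    prof = ddm[sel] @ weights
    return float((prof.max() - prof.min()) / prof.mean())


def _spots_from_fluences(layers, positions, fluences, source, scene, physics):
    sigmas = {}
    spots = []
    for (energy, _r), phi in zip(layers, fluences):
        sigmas[energy] = source.calibrate(energy, scene, physics)
        protons = phi * SPOT_SPACING**2
        if protons <= 0:
            continue
        for x, y in positions:
            spots.append(Spot(float(x), float(y), float(energy), float(protons)))
    return spots, sigmas


def axis_column_profile(dose_values, grid, target, half_max: float = 0.5):
    """Depth profile of the dose averaged over a narrow axis-centred
    column, |x|,|y| <= min(half_max, 0.8 * FS/2)."""
    half = max(min(half_max, 0.8 * target.field_FS / 2.0), grid.voxel_size)
    mx = np.abs(grid.x_centers()) <= half
    my = np.abs(grid.y_centers()) <= half
    return dose_values[np.ix_(mx, my)].mean(axis=(0, 1))


def make_plan(
    target: TargetSpec,
    scene: Scene,
    physics: ProtonPhysics | None = None,
    source: BeamSourceModel | None = None,
    calibrate_dose: bool = True,
    n_calibration: int = 20000,
    seed: int = 777,
    settings: TransportSettings | None = None,
    n_per_layer: int = 4000,
) -> Plan:
    """Build the full plan for one target in its scene.

    Layer weights start from a nonnegative least-squares fit on the
    broad-beam pencil depth-dose matrix.  Because small collimated fields
    lose lateral scatter equilibrium, the broad-beam weights leave the
    central-axis SOBP tilted; with ``calibrate_dose`` a short simulation
    of the collimated delivery measures the axis-column profile, the fit
    is repeated against the correspondingly corrected target profile, and
    a final short run scales the proton count so the axis-column mean
    unscattered dose over the SOBP core equals the prescription.
    """
    physics = physics or default_physics()
    source = source or BeamSourceModel()
    layers = make_layers(target, physics)
    positions = make_spot_map(target)
    z, ddm = depth_dose_matrix(
        layers, scene, physics, source, n_per_layer=n_per_layer,
        seed=seed, settings=settings,
    )
    fluences = sobp_weights(layers, z, ddm, target)
    spots, sigmas = _spots_from_fluences(
        layers, positions, fluences, source, scene, physics)

    def build(spot_list):
        return Plan(
            target=target,
            layers=layers,
            spots=spot_list,
            aperture=scene.aperture,
            total_protons=float(sum(s.weight for s in spot_list)),
            layer_sigmas=sigmas,
            sad_x=source.scan_magnet_distance_x,
            sad_y=source.scan_magnet_distance_y,
            energy_dispersion=source.energy_dispersion,
        )

    plan = build(spots)
    if not calibrate_dose:
        return plan

    from .tally import finalize
    from .transport import run_field

    def measured_axis_profile(p, run_seed):
        tally = run_field(p, scene, n_calibration, seed=run_seed,
                          batches=2, physics=physics, settings=settings)
        dose, _ = finalize(tally)
        prof = axis_column_profile(dose.values["US"], scene.grid, target)
        # light smoothing against single-bin noise
        kern = np.array([0.25, 0.5, 0.25])
        return np.convolve(prof, kern, mode="same"), tally

    prof, _ = measured_axis_profile(plan, seed + 1)
    zg = scene.grid.z_centers()
    correction = np.interp(z, zg, np.divide(
        plan.prescription, prof, out=np.ones_like(prof), where=prof > 0))
    correction = np.clip(correction, 0.5, 2.0)
    fluences = sobp_weights(
        layers, z, ddm, target,
        target_profile=plan.prescription * correction,
    )
    spots, sigmas = _spots_from_fluences(
        layers, positions, fluences, source, scene, physics)
    plan = build(spots)
    prof, _ = measured_axis_profile(plan, seed + 2)
    sel = _sobp_core(zg, target)
    mean_us = float(prof[sel].mean())
    if mean_us <= 0:
        raise ValueError("calibration run produced no target dose")
    plan.scale_weights(plan.prescription / mean_us)
    return plan


def _sobp_core(z, target, core: float = 0.8):
    if target.sobp_S > 0:
        lo = target.proximal_depth + (1 - core) / 2 * target.sobp_S
        hi = target.range_R - (1 - core) / 2 * target.sobp_S
    else:
        lo, hi = target.range_R - 0.4, target.range_R - 0.1
    return (z >= lo) & (z <= hi)
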