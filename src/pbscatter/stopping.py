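"""Single-proton physics: stopping power, CSDA range, scattering, straggling.

Electronic stopping powers come from the Bethe formula without shell or
density corrections (adequate for therapeutic protons above ~1 MeV), with
the maximum energy transfer approximated by its non-relativistic-recoil
limit ``2 m_e c^2 beta^2 gamma^2``.  CSDA ranges are the cumulative
integral of the reciprocal stopping power on a logarithmic energy grid.

The 4-cm ABS energy absorber is characterised by a single water-equivalent
thickness (WET) calibration constant, fitted by least squares to the three
published range-energy anchor pairs of the applicator:
74.9 MeV -> 0.5 cm, 142.5 MeV -> 10 cm and 192.4 MeV -> 20 cm residual
range in water.  The ABS bulk density used in transport is then adjusted so
that a proton crossing the physical 4-cm slab loses the same energy as in
that WET of water at the 142.5 MeV reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .materials import ABS, WATER, Material, MaterialLibrary, load_materials

__all__ = [
    "StoppingTable",
    "ProtonPhysics",
    "build_stopping_table",
    "bethe_stopping_power",
    "default_physics",
    "highland_angle",
    "straggling_sigma",
]

# physical constants (MeV unless noted)
PROTON_MASS = 938.27208816  # proton rest energy, MeV
ELECTRON_MASS = 0.51099895  # electron rest energy, MeV
K_BETHE = 0.307075  # 4 pi N_A r_e^2 m_e c^2, MeV cm^2 / mol
BOHR_COEFF = 0.1569  # Bohr straggling, MeV^2 cm^2 / g
HIGHLAND_CONST = 14.1  # MeV
RANGE_ANCHORS = ((74.9, 0.5), (142.5, 10.0), (192.4, 20.0))  # (MeV, cm water)

E_MIN = 0.1  # MeV, lower edge of the tables
E_MAX = 300.0  # MeV, upper edge
N_GRID = 400


def beta_squared(energy: float | np.ndarray) -> float | np.ndarray:
    """beta^2 of a proton with kinetic energy in MeV."""
    gamma = 1.0 + np.asarray(energy, dtype=float) / PROTON_MASS
    return 1.0 - 1.0 / (gamma * gamma)


def momentum_velocity(energy: float | np.ndarray) -> float | np.ndarray:
    """p*v = (pc)^2 / E_total in MeV, the Highland-formula denominator."""
    e = np.asarray(energy, dtype=float)
    pc2 = e * e + 2.0 * e * PROTON_MASS
    return pc2 / (e + PROTON_MASS)


def bethe_stopping_power(energy, material: Material):
    """Electronic stopping power in MeV/cm from the uncorrected Bethe formula.

    Valid above ~0.5 MeV; at the 0.1 MeV table edge the formula is still
    positive for the materials used here.
    """
    e = np.asarray(energy, dtype=float)
    gamma = 1.0 + e / PROTON_MASS
    b2 = 1.0 - 1.0 / (gamma * gamma)
    b2g2 = b2 * gamma * gamma
    i_mev = material.mean_excitation_energy * 1e-6
    arg = 2.0 * ELECTRON_MASS * b2g2 / i_mev
    val = (
        K_BETHE
        * material.Z_over_A
        * material.density
        / b2
        * (np.log(arg) - b2)
    )
    return val if val.shape else float(val)


@dataclass(frozen=True)
class StoppingTable:
    """Tabulated stopping powers and CSDA ranges on a log energy grid.

    ``stopping_powers[name]`` is in MeV/cm for the bulk density of the
    material; ``csda_ranges[name]`` in cm.  Interpolation is log-log linear.
    """

    energies: np.ndarray  # MeV, strictly increasing
    stopping_powers: dict  # name -> MeV/cm
    csda_ranges: dict  # name -> cm
    materials: MaterialLibrary

    def _check(self, energy: float, what: str) -> None:
        if not (self.energies[0] <= energy <= self.energies[-1]):
            raise ValueError(
                f"{what}: energy {energy} MeV outside table range "
                f"[{self.energies[0]}, {self.energies[-1]}] MeV"
            )

    def stopping_power(self, energy: float, material: str = WATER) -> float:
        """S(E) in MeV/cm by log-log interpolation."""
        self._check(energy, "stopping_power")
        logs = np.log(self.stopping_powers[material])
        return float(np.exp(np.interp(np.log(energy), np.log(self.energies), logs)))

    def csda_range(self, energy: float, material: str = WATER) -> float:
        """CSDA range in cm; 0 at zero energy by convention."""
        if energy == 0.0:
            return 0.0
        self._check(energy, "csda_range")
        logr = np.log(self.csda_ranges[material])
        return float(np.exp(np.interp(np.log(energy), np.log(self.energies), logr)))

    def energy_from_range(self, rng: float, material: str = WATER) -> float:
        """Inverse of :meth:`csda_range` (cm -> MeV)."""
        r = self.csda_ranges[material]
        if not (r[0] <= rng <= r[-1]):
            raise ValueError(
                f"energy_from_range: range {rng} cm outside table "
                f"[{r[0]:.3g}, {r[-1]:.3g}] cm"
            )
        return float(
            np.exp(np.interp(np.log(rng), np.log(r), np.log(self.energies)))
        )


def _csda_from_stopping(energies: np.ndarray, stopping: np.ndarray) -> np.ndarray:
    """Cumulative integral of 1/S on the grid, seeded with E0/S(E0)."""
    inv = 1.0 / stopping
    seed = energies[0] * inv[0]
    increments = np.diff(energies) * 0.5 * (inv[1:] + inv[:-1])
    return seed + np.concatenate([[0.0], np.cumsum(increments)])


def build_stopping_table(
    materials: MaterialLibrary | None = None,
    n_grid: int = N_GRID,
    e_min: float = E_MIN,
    e_max: float = E_MAX,
) -> StoppingTable:
    """Build the stopping/range table and fill each material's
    water-equivalence ratio (mass-stopping ratio to water at 100 MeV)."""
    if materials is None:
        materials = load_materials()
    energies = np.geomspace(e_min, e_max, n_grid)
    stopping = {}
    ranges = {}
    for name, mat in materials.items():
        s = np.asarray(bethe_stopping_power(energies, mat))
        # Below the Bethe maximum (sub-MeV for high-I materials) the
        # uncorrected formula turns over and can go negative; extend with a
        # velocity-proportional power law instead.  Protons below 1 MeV are
        # stopped locally in transport, so only table well-posedness matters.
        peak = int(np.argmax(s))
        if peak > 0:
            s[:peak] = s[peak] * (energies[:peak] / energies[peak]) ** 0.45
        stopping[name] = s
        ranges[name] = _csda_from_stopping(energies, s)
    s_w100 = float(np.interp(100.0, energies, stopping[WATER]))
    lib = MaterialLibrary()
    for name, mat in materials.items():
        s100 = float(np.interp(100.0, energies, stopping[name]))
        wer = (s100 / mat.density) / s_w100  # water density is 1 g/cm^3
        object.__setattr__(mat, "water_equivalence_ratio", wer)
        lib[name] = mat
    return StoppingTable(
        energies=energies, stopping_powers=stopping, csda_ranges=ranges, materials=lib
    )


def residual_range_water(
    energy: float, absorber_wet: float, table: StoppingTable
) -> float:
    """Residual CSDA range in water (cm) after a slab of the given
    water-equivalent thickness, floored at zero."""
    if absorber_wet < 0:
        raise ValueError("absorber_wet must be >= 0")
    return max(table.csda_range(energy, WATER) - absorber_wet, 0.0)


def calibrate_absorber_wet(
    table: StoppingTable, anchors=RANGE_ANCHORS
) -> float:
    """Least-squares fit of the single absorber WET constant to the
    (energy, residual range) anchor pairs: the minimiser of
    sum_i (R_w(E_i) - WET - r_i)^2 is the mean of R_w(E_i) - r_i."""
    diffs = [table.csda_range(e, WATER) - r for e, r in anchors]
    return float(np.mean(diffs))


def _abs_wet_at(
    table: StoppingTable, density: float, energy: float, thickness: float
) -> float:
    """WET of a `thickness` cm ABS slab of given density at one energy."""
    mass_range = {  # g/cm^2 grid for ABS at its tabulated density
        "r": np.asarray(table.csda_ranges[ABS]) * table.materials[ABS].density
    }
    r_in = float(
        np.exp(
            np.interp(
                np.log(energy), np.log(table.energies), np.log(mass_range["r"])
            )
        )
    )
    r_out = r_in - thickness * density
    if r_out <= mass_range["r"][0]:
        return table.csda_range(energy, WATER)  # proton stops inside the slab
    e_out = float(
        np.exp(
            np.interp(np.log(r_out), np.log(mass_range["r"]), np.log(table.energies))
        )
    )
    return table.csda_range(energy, WATER) - table.csda_range(e_out, WATER)


@dataclass(frozen=True)
class ProtonPhysics:
    """Calibrated physics bundle: materials (with fitted ABS density),
    stopping/range tables and the absorber WET constant."""

    table: StoppingTable
    materials: MaterialLibrary
    absorber_wet: float  # cm water, for the 4-cm ABS slab
    absorber_thickness: float = 4.0  # cm

    def residual_range_water(self, energy: float, absorber_wet: float | None = None) -> float:
        wet = self.absorber_wet if absorber_wet is None else absorber_wet
        return residual_range_water(energy, wet, self.table)

    def energy_for_residual_range(self, residual: float) -> float:
        """Energy whose range in water is `residual` + absorber WET."""
        return self.table.energy_from_range(residual + self.absorber_wet, WATER)


def calibrate_physics(materials: MaterialLibrary | None = None) -> ProtonPhysics:
    """Full calibration chain: stopping table, absorber WET least-squares
    fit, and ABS density adjustment to realise that WET at 142.5 MeV."""
    table = build_stopping_table(materials)
    wet = calibrate_absorber_wet(table)
    thickness = 4.0
    ref_energy = 142.5

    def mismatch(rho: float) -> float:
        return _abs_wet_at(table, rho, ref_energy, thickness) - wet

    rho = brentq(mismatch, 0.5, 2.0, xtol=1e-10)
    lib = MaterialLibrary(table.materials)
    lib[ABS] = lib[ABS].with_density(rho)
    # rebuild so the ABS column reflects the calibrated density
    table = build_stopping_table(lib)
    return ProtonPhysics(table=table, materials=table.materials, absorber_wet=wet)


@lru_cache(maxsize=1)
def default_physics() -> ProtonPhysics:
    """Calibrated physics with the built-in material set (cached)."""
    return calibrate_physics()


def highland_angle(
    energy: float,
    path: float,
    material: Material,
    char_thickness: float | None = None,
) -> float:
    """Projected multiple-Coulomb-scattering angle sigma (radians) from
    Highland's parameterisation.

    The logarithmic correction is evaluated on ``char_thickness`` (the total
    traversed thickness of the material slab) rather than on ``path``, so
    that splitting a slab into sub-steps leaves the accumulated variance
    unchanged.  With ``char_thickness=None`` the step length itself is used.
    """
    if path <= 0:
        raise ValueError("path must be positive")
    if energy <= 1.0:
        raise ValueError("energy must exceed 1 MeV")
    x0 = material.radiation_length_cm
    t_char = path if char_thickness is None else char_thickness
    pv = momentum_velocity(energy)
    corr = 1.0 + (1.0 / 9.0) * np.log10(t_char / x0)
    return float(HIGHLAND_CONST / pv * np.sqrt(path / x0) * max(corr, 0.0))


def straggling_sigma(
    energy_in: float, energy_out: float, path: float, material: Material
) -> float:
    """Bohr (Gaussian) energy-straggling sigma in MeV for one step."""
    if energy_in < energy_out:
        raise ValueError("energy_in must be >= energy_out")
    if path < 0:
        raise ValueError("path must be >= 0")
    return float(
        np.sqrt(BOHR_COEFF * material.Z_over_A * material.density * path)
    )
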