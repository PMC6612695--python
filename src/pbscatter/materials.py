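"""Material definitions for the collimated proton nozzle and water phantom.

The model needs four materials: the water phantom, air gaps, the ABS
(acrylonitrile-butadiene-styrene) energy absorber, and the brass patient
collimator.  Each material carries the bulk constants that drive proton
transport: density, mean excitation energy (the I-value of the Bethe
stopping-power formula), Z/A, radiation length (multiple Coulomb
scattering), and a nuclear interaction mass length (primary-proton removal).

Definitions ship as a documented YAML file (``data/materials.yaml``) and can
be overridden by path.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["Material", "MaterialLibrary", "load_materials"]

#: canonical material names used throughout the package
WATER = "water"
AIR = "air"
ABS = "abs_plastic"
BRASS = "brass"


@dataclass(frozen=True)
class Material:
    """Bulk material constants for proton transport.

    Attributes
    ----------
    name:
        Label, e.g. ``"water"`` or ``"brass"``.
    density:
        Bulk density in g/cm^3.
    mean_excitation_energy:
        I-value in eV entering the Bethe formula.
    Z_over_A:
        Ratio of atomic number to atomic mass in mol/g, mass-averaged.
    radiation_length:
        X0 in g/cm^2 (mass radiation length).
    nuclear_interaction_length:
        Mass length in g/cm^2 for exponential removal of primaries by
        nonelastic nuclear reactions.
    water_equivalence_ratio:
        Energy-independent mass-stopping ratio relative to water, evaluated
        at a 100 MeV reference energy.  Exactly 1 for water; filled in by
        :func:`pbscatter.stopping.build_stopping_table`.
    """

    name: str
    density: float
    mean_excitation_energy: float
    Z_over_A: float
    radiation_length: float
    nuclear_interaction_length: float = 85.0
    water_equivalence_ratio: float = field(default=float("nan"))
    composition: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.mean_excitation_energy <= 0:
            raise ValueError(f"{self.name}: mean excitation energy must be positive")
        if self.radiation_length <= 0:
            raise ValueError(f"{self.name}: radiation length must be positive")
        if self.Z_over_A <= 0:
            raise ValueError(f"{self.name}: Z/A must be positive")

    @property
    def radiation_length_cm(self) -> float:
        """Radiation length in cm for this bulk density."""
        return self.radiation_length / self.density

    def with_density(self, density: float) -> "Material":
        """Return a copy with a different bulk density (used to calibrate ABS)."""
        return replace(self, density=density)


class MaterialLibrary(dict):
    """Mapping ``name -> Material`` with attribute-style access to the four
    canonical materials."""

    @property
    def water(self) -> Material:
        return self[WATER]

    @property
    def air(self) -> Material:
        return self[AIR]

    @property
    def abs_plastic(self) -> Material:
        return self[ABS]

    @property
    def brass(self) -> Material:
        return self[BRASS]


def load_materials(path: str | Path | None = None) -> MaterialLibrary:
    """Load material definitions from YAML.

    Parameters
    ----------
    path:
        Optional path to a user YAML file with the same schema as the
        built-in ``data/materials.yaml``; ``None`` loads the built-in set.
    """
    if path is None:
        text = (
            importlib.resources.files("pbscatter").joinpath("data/materials.yaml")
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    lib = MaterialLibrary()
    for name, fields in raw.items():
        lib[name] = Material(
            name=name,
            density=float(fields["density"]),
            mean_excitation_energy=float(fields["mean_excitation_energy"]),
            Z_over_A=float(fields["Z_over_A"]),
            radiation_length=float(fields["radiation_length"]),
            nuclear_interaction_length=float(
                fields.get("nuclear_interaction_length", 85.0)
            ),
            composition=str(fields.get("composition", "")),
        )
    missing = {WATER, AIR, ABS, BRASS} - set(lib)
    if missing:
        raise ValueError(f"material file lacks required materials: {sorted(missing)}")
    return lib
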