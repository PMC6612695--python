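"""Scene geometry: energy absorber, brass collimator, air gaps, water phantom.

Coordinates are right-handed with +z along the beam and the origin at the
centre of the water surface; all lengths at module interfaces are cm.  The
collimator's downstream (exit) face sits 9 cm upstream of the isocenter,
the water surface 6 cm downstream of that face, and the isocenter 3 cm deep
in water.  Voxel intervals are half-open, ``[i*d, (i+1)*d)``, zero-based; a
boundary point belongs to the downstream region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SRAConfig",
    "TargetSpec",
    "PhantomGrid",
    "Scene",
    "build_scene",
    "locate",
    "aperture_for_target",
]

# default effective source (scanning magnet) distances upstream of isocenter
SCAN_MAGNET_X = 200.0  # cm
SCAN_MAGNET_Y = 240.0  # cm

ISOCENTER_DEPTH = 3.0  # cm in water
COLLIMATOR_EXIT_TO_SURFACE = 6.0  # cm
Z_ISO = ISOCENTER_DEPTH  # isocenter z in scene coordinates

CANONICAL_RANGES = (5.0, 10.0, 15.0, 20.0)
CANONICAL_SOBPS = (5.0, 10.0)
CANONICAL_FIELDS = (2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class SRAConfig:
    """Short-range applicator layout: 4-cm ABS absorber + brass collimator."""

    collimator_thickness: float  # cm, 2 or 4
    absorber_thickness: float = 4.0  # cm
    aperture_half_x: float = 10.0  # cm
    aperture_half_y: float = 10.0  # cm
    collimator_exit_to_isocenter: float = 9.0  # cm
    collimator_exit_to_water_surface: float = COLLIMATOR_EXIT_TO_SURFACE  # cm
    isocenter_depth: float = ISOCENTER_DEPTH  # cm
    absorber_collimator_gap: float = 1.0  # cm air between absorber exit and collimator

    def __post_init__(self) -> None:
        if self.collimator_thickness not in (2.0, 4.0):
            raise ValueError("collimator thickness must be 2 or 4 cm")
        if not (0.0 < self.aperture_half_x <= 10.0 and 0.0 < self.aperture_half_y <= 10.0):
            raise ValueError("aperture half-widths must lie in (0, 10] cm")
        if not math.isclose(
            self.collimator_exit_to_isocenter,
            self.collimator_exit_to_water_surface + self.isocenter_depth,
        ):
            raise ValueError(
                "collimator_exit_to_isocenter must equal "
                "collimator_exit_to_water_surface + isocenter_depth"
            )


@dataclass(frozen=True)
class TargetSpec:
    """Rectangular water-phantom target: range R, SOBP width S, square field FS."""

    range_R: float  # cm water, distal edge depth
    sobp_S: float  # cm water, SOBP extent
    field_FS: float  # cm, side of the square field at the proximal plane

    def __post_init__(self) -> None:
        if self.range_R <= 0 or self.sobp_S < 0 or self.field_FS <= 0:
            raise ValueError("target dimensions must be positive")

    @property
    def label(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:g}"

        return f"R{fmt(self.range_R)}_S{fmt(self.sobp_S)}_FS{fmt(self.field_FS)}"

    @property
    def proximal_depth(self) -> float:
        """Depth of the proximal target edge; an SOBP wider than the range
        reaches the surface (the delivered proximal layers are then clipped
        by the applicator's minimum residual range)."""
        return max(self.range_R - self.sobp_S, 0.0)

    @property
    def center_depth(self) -> float:
        """Mid-depth of the SOBP box, the target-center evaluation depth."""
        return 0.5 * (self.range_R + self.proximal_depth)


def collimator_thickness_for(target: TargetSpec) -> float:
    """2-cm collimator up to a 10-cm maximum range, 4-cm above it."""
    return 2.0 if target.range_R <= 10.0 else 4.0


@dataclass(frozen=True)
class PhantomGrid:
    """Voxelised water phantom; z = 0 at the surface, +z along the beam.

    Lateral voxel counts are odd so that x = y = 0 is a voxel centre.
    """

    voxel_size: float  # cm, isotropic
    nx: int
    ny: int
    nz: int

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.nx % 2 == 0 or self.ny % 2 == 0:
            raise ValueError("lateral voxel counts must be odd (centred grid)")

    @property
    def x_min(self) -> float:
        return -0.5 * self.nx * self.voxel_size

    @property
    def y_min(self) -> float:
        return -0.5 * self.ny * self.voxel_size

    @property
    def z_max(self) -> float:
        return self.nz * self.voxel_size

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def voxel_mass(self) -> float:
        """Mass of one water voxel in g (density 1 g/cm^3)."""
        return self.voxel_size**3

    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.voxel_size

    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.ny) + 0.5) * self.voxel_size

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.voxel_size

    def index_of(self, x: float, y: float, z: float) -> tuple[int, int, int]:
        """Voxel containing the point (half-open intervals)."""
        ix = int(math.floor((x - self.x_min) / self.voxel_size))
        iy = int(math.floor((y - self.y_min) / self.voxel_size))
        iz = int(math.floor(z / self.voxel_size))
        return ix, iy, iz

    @classmethod
    def for_target(
        cls,
        target: TargetSpec,
        voxel_size: float = 0.1,
        lateral_margin: float = 3.0,
        distal_margin: float = 1.0,
    ) -> "PhantomGrid":
        half = target.field_FS / 2.0 + lateral_margin
        n_lat = 2 * int(math.ceil(half / voxel_size)) + 1
        nz = int(math.ceil((target.range_R + distal_margin) / voxel_size))
        return cls(voxel_size=voxel_size, nx=n_lat, ny=n_lat, nz=nz)


@dataclass(frozen=True)
class Scene:
    """Ordered material stations along z plus the collimator aperture."""

    target: TargetSpec
    sra: SRAConfig
    grid: PhantomGrid
    z_source: float  # primaries start here
    z_absorber_entry: float
    z_absorber_exit: float
    z_collimator_entry: float
    z_collimator_exit: float
    z_water_max: float
    lateral_bound: float = field(default=25.0)  # |x|,|y| beyond which protons leave
    collimator_present: bool = True

    @property
    def aperture(self) -> tuple[float, float]:
        return (self.sra.aperture_half_x, self.sra.aperture_half_y)


def aperture_for_target(
    target: TargetSpec,
    scan_magnet_distance_x: float = SCAN_MAGNET_X,
    scan_magnet_distance_y: float = SCAN_MAGNET_Y,
) -> tuple[float, float]:
    """Aperture half-widths that put the 50% geometric penumbra point of the
    field edge on the proximal target plane.

    The edge ray runs from the effective source (the scanning magnet, on
    axis) through the collimator exit edge to x = FS/2 at the proximal
    plane; back-projection gives the half-width per axis.  Infinite magnet
    distance reduces to aperture = FS/2.
    """
    if target.field_FS > 20.0:
        raise ValueError("field exceeds the 20 x 20 cm^2 applicator maximum")
    z_exit = -COLLIMATOR_EXIT_TO_SURFACE
    z_prox = target.proximal_depth
    half = target.field_FS / 2.0

    def back_project(sad: float) -> float:
        if math.isinf(sad):
            return half
        z_mag = Z_ISO - sad
        return half * (z_exit - z_mag) / (z_prox - z_mag)

    return (back_project(scan_magnet_distance_x), back_project(scan_magnet_distance_y))


def build_scene(
    target: TargetSpec,
    grid: PhantomGrid | None = None,
    voxel_size: float = 0.1,
    collimator_thickness: float | None = None,
    scan_magnet_distance_x: float = SCAN_MAGNET_X,
    scan_magnet_distance_y: float = SCAN_MAGNET_Y,
    collimator_present: bool = True,
) -> Scene:
    """Assemble the scene for one rectangular target.

    Selects the collimator thickness from the target range (2 cm up to
    R = 10 cm, 4 cm above), back-projects the aperture, and stacks
    absorber, air gaps, collimator and phantom along z.
    """
    if grid is None:
        grid = PhantomGrid.for_target(target, voxel_size=voxel_size)
    thickness = (
        collimator_thickness_for(target)
        if collimator_thickness is None
        else collimator_thickness
    )
    ax, ay = aperture_for_target(
        target, scan_magnet_distance_x, scan_magnet_distance_y
    )
    sra = SRAConfig(
        collimator_thickness=thickness, aperture_half_x=ax, aperture_half_y=ay
    )
    z_c1 = -sra.collimator_exit_to_water_surface
    z_c0 = z_c1 - thickness
    z_a1 = z_c0 - sra.absorber_collimator_gap
    z_a0 = z_a1 - sra.absorber_thickness
    return Scene(
        target=target,
        sra=sra,
        grid=grid,
        z_source=z_a0 - 0.5,
        z_absorber_entry=z_a0,
        z_absorber_exit=z_a1,
        z_collimator_entry=z_c0,
        z_collimator_exit=z_c1,
        z_water_max=grid.z_max,
        collimator_present=collimator_present,
    )


def locate(scene: Scene, point) -> str:
    """Region label at a point: ``absorber | air | collimator | aperture-air
    | water | outside``.  Half-open along z: a boundary point belongs to the
    downstream region."""
    x, y, z = point
    if abs(x) > scene.lateral_bound or abs(y) > scene.lateral_bound:
        return "outside"
    if z < scene.z_source or z >= scene.z_water_max:
        return "outside"
    if z < scene.z_absorber_entry:
        return "air"
    if z < scene.z_absorber_exit:
        return "absorber"
    if z < scene.z_collimator_entry:
        return "air"
    if z < scene.z_collimator_exit:
        if not scene.collimator_present:
            return "aperture-air"
        if abs(x) < scene.sra.aperture_half_x and abs(y) < scene.sra.aperture_half_y:
            return "aperture-air"
        return "collimator"
    if z < 0.0:
        return "air"
    return "water"


def canonical_targets() -> list[TargetSpec]:
    """The full 4 x 2 x 4 sweep of ranges, SOBP widths and field sizes."""
    return [
        TargetSpec(r, s, f)
        for r in CANONICAL_RANGES
        for s in CANONICAL_SOBPS
        for f in CANONICAL_FIELDS
    ]
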