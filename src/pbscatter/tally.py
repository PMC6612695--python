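"""Per-voxel, per-channel tallies and their conversion to dose and LET_d.

Channels separate collimator-scattered (S) from unscattered (US) protons;
the merged channel S+US is their sum.  Each voxel accumulates the deposited
energy eps and the product eps * L, where L is the unrestricted electronic
stopping power of water (keV/um) at the mid-step energy; the dose-averaged
LET is the ratio of the two sums:

    LET_d = (sum_steps L * eps) / (sum_steps eps)

so the merged channel obeys the exact mixture identity
LET_d(S+US) * (eps_S + eps_US) = LET_d(S) * eps_S + LET_d(US) * eps_US.

Tallies are partitioned into batches (primary index mod n_batches) for
statistical-uncertainty estimates; batch partitions sum to the totals
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kernel
from .geometry import PhantomGrid, TargetSpec

__all__ = ["TallyGrid", "DoseGrid", "LetdGrid", "score_step", "finalize",
           "target_box_mean", "save_tally", "load_tally", "profile_frame"]

GY_PER_MEV_G = 1.602176634e-10  # Gy per MeV/g

CH_US = 0
CH_S = 1
CHANNELS = ("US", "S", "S+US")


@dataclass
class TallyGrid:
    """Raw per-batch, per-channel sums of eps and eps*L.

    ``eps`` and ``epsL`` have shape (n_batches, 2, n_voxels) with channel
    axis ordered (US, S); flat voxel index is ``(ix*ny + iy)*nz + iz``.
    """

    eps: np.ndarray  # MeV
    epsL: np.ndarray  # MeV * keV/um
    grid: PhantomGrid
    n_primaries: int
    seed: int
    batches: int
    proton_scale: float = 1.0  # planned protons represented per simulated one
    ledger: dict = field(default_factory=dict)

    def eps_sum(self, channel: str) -> np.ndarray:
        return self._chan(self.eps, channel)

    def epsL_sum(self, channel: str) -> np.ndarray:
        return self._chan(self.epsL, channel)

    def _chan(self, arr: np.ndarray, channel: str) -> np.ndarray:
        tot = arr.sum(axis=0)
        if channel == "US":
            return tot[CH_US]
        if channel == "S":
            return tot[CH_S]
        if channel == "S+US":
            return tot[CH_US] + tot[CH_S]
        raise KeyError(channel)


@dataclass
class DoseGrid:
    """Absolute dose per channel in Gy, shape (nx, ny, nz) per channel."""

    grid: PhantomGrid
    values: dict  # channel -> Gy array
    rel_err: dict  # channel -> batch-based relative standard error

    def at(self, channel: str, ix: int, iy: int, iz: int) -> float:
        return float(self.values[channel][ix, iy, iz])


@dataclass
class LetdGrid:
    """Dose-averaged LET per channel in keV/um; NaN where no energy was
    deposited in the channel."""

    grid: PhantomGrid
    values: dict

    def at(self, channel: str, ix: int, iy: int, iz: int) -> float:
        return float(self.values[channel][ix, iy, iz])


def score_step(
    tally: TallyGrid,
    p0,
    p1,
    eps: float,
    letd: float,
    scattered: bool,
    batch: int = 0,
) -> None:
    """Score one step segment into the tally, splitting the deposit across
    voxels by exact path fraction.  Segments outside the grid are clipped.

    This is the same routine the transport kernel uses; exposed for tests
    and for replaying recorded step logs.
    """
    g = tally.grid
    dummy_i = np.zeros(0, dtype=np.int64)
    dummy_f = np.zeros(0)
    dummy_b = np.zeros(0, dtype=np.int8)
    kernel._score_segment(
        float(p0[0]), float(p0[1]), float(p0[2]),
        float(p1[0]), float(p1[1]), float(p1[2]),
        float(eps), float(letd), 1 if scattered else 0, batch,
        g.x_min, g.y_min, g.voxel_size, g.nx, g.ny, g.nz,
        tally.eps, tally.epsL,
        dummy_i, dummy_f, dummy_f, dummy_b, 0, 0,
    )


def finalize(tally: TallyGrid) -> tuple[DoseGrid, LetdGrid]:
    """Convert raw sums to absolute dose (Gy) and LET_d (keV/um) grids.

    dose[c] = eps_sum[c] * (MeV -> J) / voxel mass, scaled to the planned
    proton count; LET_d[c] = epsL_sum[c]/eps_sum[c] where energy was
    deposited, NaN elsewhere.  The merged channel divides summed
    numerators by summed denominators, never averages the channel values.
    """
    g = tally.grid
    shape = g.shape
    conv = GY_PER_MEV_G / g.voxel_mass * tally.proton_scale
    dose_vals = {}
    rel_err = {}
    letd_vals = {}
    nb = tally.eps.shape[0]
    for channel in CHANNELS:
        eps = tally.eps_sum(channel)
        epsl = tally.epsL_sum(channel)
        dose_vals[channel] = (eps * conv).reshape(shape)
        if channel == "S+US":
            # bitwise channel additivity: D^S + D^US = D^(S+US) per voxel
            dose_vals[channel] = dose_vals["S"] + dose_vals["US"]
        with np.errstate(invalid="ignore", divide="ignore"):
            letd = np.where(eps > 0, epsl / np.where(eps > 0, eps, 1.0), np.nan)
        letd_vals[channel] = letd.reshape(shape)
        # batch-based relative standard error of the mean
        if channel == "S+US":
            per_batch = tally.eps.sum(axis=1)
        elif channel == "US":
            per_batch = tally.eps[:, CH_US]
        else:
            per_batch = tally.eps[:, CH_S]
        mean = per_batch.mean(axis=0)
        if nb > 1:
            sem = per_batch.std(axis=0, ddof=1) / np.sqrt(nb)
        else:
            sem = np.full_like(mean, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(mean > 0, sem / np.where(mean > 0, mean, 1.0), np.nan)
        rel_err[channel] = rel.reshape(shape)
    return DoseGrid(grid=g, values=dose_vals, rel_err=rel_err), LetdGrid(
        grid=g, values=letd_vals
    )


def target_box_mean(
    dose: DoseGrid, target: TargetSpec, channel: str = "US", core: float = 0.8
) -> float:
    """Mean dose over the central `core` fraction (per axis) of the target
    box, used for prescription normalization."""
    g = dose.grid
    half = core * target.field_FS / 2.0
    x = g.x_centers()
    y = g.y_centers()
    z = g.z_centers()
    if target.sobp_S > 0:
        z_lo = target.proximal_depth + (1 - core) / 2 * target.sobp_S
        z_hi = target.range_R - (1 - core) / 2 * target.sobp_S
    else:
        z_lo, z_hi = target.range_R - 0.4, target.range_R - 0.1
    mx = np.abs(x) <= half
    my = np.abs(y) <= half
    mz = (z >= z_lo) & (z <= z_hi)
    if not (mx.any() and my.any() and mz.any()):
        raise ValueError("target core box contains no voxel centres")
    sub = dose.values[channel][np.ix_(mx, my, mz)]
    return float(sub.mean())


def save_tally(tally: TallyGrid, stem) -> None:
    """Write a tally as a text header (YAML) plus a flat little-endian
    float64 binary holding eps then epsL."""
    stem = Path(stem)
    g = tally.grid
    header = {
        "format": "pbscatter-tally-v1",
        "shape": list(g.shape),
        "voxel_size_cm": g.voxel_size,
        "origin_cm": [g.x_min, g.y_min, 0.0],
        "batches": tally.batches,
        "channels": ["US", "S"],
        "units": {"eps": "MeV", "epsL": "MeV*keV/um"},
        "n_primaries": tally.n_primaries,
        "seed": tally.seed,
        "proton_scale": tally.proton_scale,
        "ledger": {k: float(v) for k, v in tally.ledger.items()},
        "byte_order": "little",
        "dtype": "float64",
    }
    stem.with_suffix(".header.yaml").write_text(yaml.safe_dump(header))
    with open(stem.with_suffix(".bin"), "wb") as fh:
        fh.write(tally.eps.astype("<f8").tobytes())
        fh.write(tally.epsL.astype("<f8").tobytes())


def load_tally(stem) -> TallyGrid:
    stem = Path(stem)
    header = yaml.safe_load(stem.with_suffix(".header.yaml").read_text())
    if header.get("format") != "pbscatter-tally-v1":
        raise ValueError("not a pbscatter tally header")
    nx, ny, nz = header["shape"]
    nb = header["batches"]
    grid = PhantomGrid(voxel_size=header["voxel_size_cm"], nx=nx, ny=ny, nz=nz)
    n = nb * 2 * nx * ny * nz
    raw = np.fromfile(stem.with_suffix(".bin"), dtype="<f8")
    eps = raw[:n].reshape(nb, 2, nx * ny * nz)
    epsL = raw[n:].reshape(nb, 2, nx * ny * nz)
    return TallyGrid(
        eps=eps, epsL=epsL, grid=grid,
        n_primaries=header["n_primaries"], seed=header["seed"],
        batches=nb, proton_scale=header["proton_scale"],
        ledger=header.get("ledger", {}),
    )


def profile_frame(
    dose: DoseGrid, letd: LetdGrid, axis: str = "x", y: float = 0.0, z: float = 0.5
) -> pd.DataFrame:
    """Line profile along one axis at fixed positions on the other two,
    as a tidy DataFrame (one column per channel for dose and LET_d)."""
    g = dose.grid
    if axis == "x":
        iy = g.index_of(0.0, y, z)[1]
        iz = g.index_of(0.0, y, z)[2]
        coord = g.x_centers()
        pick = lambda a: a[:, iy, iz]  # noqa: E731
    elif axis == "z":
        ix, iy, _ = g.index_of(y, 0.0, 0.0)
        coord = g.z_centers()
        pick = lambda a: a[ix, iy, :]  # noqa: E731
    else:
        raise ValueError("axis must be 'x' or 'z'")
    data = {axis: coord}
    for ch in CHANNELS:
        tag = ch.replace("+", "")
        data[f"dose_{tag}_Gy"] = pick(dose.values[ch])
        data[f"letd_{tag}_keV_um"] = pick(letd.values[ch])
    return pd.DataFrame(data)
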