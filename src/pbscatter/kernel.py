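"""Numba condensed-history transport kernel.

All performance-critical transport lives here as nopython-compiled
functions; :mod:`pbscatter.transport` provides the user-facing wrappers.

Conventions baked into the kernel:

* materials are indexed 0=water, 1=air, 2=ABS, 3=brass;
* step length = min(per-material cap, distance to the next boundary,
  5% of the residual range), with the residual-range cap floored at
  0.5 mm so end-of-range histories terminate in a bounded step count;
* energy loss is evaluated at the mid-step energy, plus Gaussian (Bohr)
  straggling, floored at zero;
* the position advances along the pre-deflection direction and the
  Highland deflection is applied afterwards (small-angle convention);
* nuclear interactions remove statistical weight continuously,
  ``w *= exp(-l/lambda)``, and the removed weight deposits nothing;
* a proton becomes "collimator-scattered" the first time it takes a step
  in brass; the flag never resets;
* protons below 1 MeV deposit their remaining energy locally and stop.

Randomness is a counter-based splitmix64 stream per primary index, so any
primary's history depends only on (seed, primary index), not on execution
order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# material indices
M_WATER = 0
M_AIR = 1
M_ABS = 2
M_BRASS = 3

E_CUTOFF = 1.0  # MeV: below this the proton is stopped and absorbed locally
PROTON_MASS = 938.27208816
BOUNDARY_NUDGE = 1e-7  # cm pushed past a crossed boundary
MAX_STEPS = 100000

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MUL1 = np.uint64(0xBF58476D1CE4E5B9)
_MUL2 = np.uint64(0x94D049BB133111EB)


@njit(cache=True, fastmath=True, inline="always")
def _mix64(z):
    z = np.uint64(z) + _GAMMA
    z = (z ^ (z >> np.uint64(30))) * _MUL1
    z = (z ^ (z >> np.uint64(27))) * _MUL2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, fastmath=True, inline="always")
def primary_stream(seed, index):
    """Initial splitmix64 state for one primary: depends only on
    (seed, index)."""
    s = np.uint64(seed) * _MUL1 + np.uint64(index) * _GAMMA
    return _mix64(_mix64(s))


@njit(cache=True, fastmath=True, inline="always")
def _next_u64(state):
    state = np.uint64(state) + _GAMMA
    return _mix64(state), state


@njit(cache=True, fastmath=True, inline="always")
def _uniform(state):
    v, state = _next_u64(state)
    return (v >> np.uint64(11)) * 1.1102230246251565e-16, state


@njit(cache=True, fastmath=True, inline="always")
def _normal(state):
    u1, state = _uniform(state)
    u2, state = _uniform(state)
    if u1 < 1e-300:
        u1 = 1e-300
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2), state


@njit(cache=True, fastmath=True, inline="always")
def _normal2(state):
    """Two independent standard normals from one Box-Muller pair."""
    u1, state = _uniform(state)
    u2, state = _uniform(state)
    if u1 < 1e-300:
        u1 = 1e-300
    r = np.sqrt(-2.0 * np.log(u1))
    a = 6.283185307179586 * u2
    return r * np.cos(a), r * np.sin(a), state


@njit(cache=True, fastmath=True, inline="always")
def _lookup(e0, inv_de, table, energy):
    """Linear interpolation on the uniform kernel energy grid."""
    f = (energy - e0) * inv_de
    if f <= 0.0:
        return table[0]
    n = table.shape[0]
    i = int(f)
    if i >= n - 1:
        return table[n - 1]
    w = f - i
    return table[i] * (1.0 - w) + table[i + 1] * w


@njit(cache=True, fastmath=True, inline="always")
def _pv(energy):
    return (energy * energy + 2.0 * energy * PROTON_MASS) / (energy + PROTON_MASS)


@njit(cache=True, fastmath=True, inline="always")
def _material_at(x, y, z, sf, coll_present, phantom_is_water):
    """Material index at a point, or -1 outside the scene.

    sf = (z_src, za0, za1, zc0, zc1, z_wmax, ax, ay, lat_bound)
    """
    if abs(x) > sf[8] or abs(y) > sf[8]:
        return -1
    if z < sf[0] or z >= sf[5]:
        return -1
    if z < sf[1]:
        return M_AIR
    if z < sf[2]:
        return M_ABS
    if z < sf[3]:
        return M_AIR
    if z < sf[4]:
        if coll_present == 0:
            return M_AIR
        if abs(x) < sf[6] and abs(y) < sf[7]:
            return M_AIR
        return M_BRASS
    if z < 0.0:
        return M_AIR
    if phantom_is_water == 0:
        return M_AIR
    return M_WATER


@njit(cache=True, fastmath=True, inline="always")
def _boundary_distance(x, y, z, dx, dy, dz, sf, coll_present):
    """Distance along the direction to the next geometric boundary."""
    t_min = 1e30
    # z planes, ordered upstream -> downstream
    if dz > 1e-12:
        for zp in (sf[1], sf[2], sf[3], sf[4], 0.0, sf[5]):
            if zp > z + 1e-12:
                t = (zp - z) / dz
                if t < t_min:
                    t_min = t
                break
    elif dz < -1e-12:
        for zp in (sf[4], sf[3], sf[2], sf[1], sf[0]):
            if zp < z - 1e-12:
                t = (zp - z) / dz
                if t < t_min:
                    t_min = t
                break
        # note 0.0 plane handled in loop order below water is not needed:
        if z > 0.0 > z + dz * t_min:
            t = (0.0 - z) / dz
            if t < t_min:
                t_min = t
    # aperture side walls inside the collimator z-span
    if coll_present == 1 and sf[3] <= z < sf[4]:
        if dx > 1e-12:
            for xp in (-sf[6], sf[6]):
                if xp > x + 1e-12:
                    t = (xp - x) / dx
                    if t < t_min:
                        t_min = t
                    break
        elif dx < -1e-12:
            for xp in (sf[6], -sf[6]):
                if xp < x - 1e-12:
                    t = (xp - x) / dx
                    if t < t_min:
                        t_min = t
                    break
        if dy > 1e-12:
            for yp in (-sf[7], sf[7]):
                if yp > y + 1e-12:
                    t = (yp - y) / dy
                    if t < t_min:
                        t_min = t
                    break
        elif dy < -1e-12:
            for yp in (sf[7], -sf[7]):
                if yp < y - 1e-12:
                    t = (yp - y) / dy
                    if t < t_min:
                        t_min = t
                    break
    return t_min


@njit(cache=True, fastmath=True)
def _score_segment(
    x0, y0, z0, x1, y1, z1, eps, letd, ch, batch,
    gx0, gy0, dvox, nx, ny, nz,
    eps_t, epsL_t,
    rec_vox, rec_val, rec_L, rec_ch, rec_n, record,
):
    """Split one in-phantom segment across voxels by exact path fraction.

    Returns (updated record count, clipped flag)."""
    sx = x1 - x0
    sy = y1 - y0
    sz = z1 - z0
    seg_len = np.sqrt(sx * sx + sy * sy + sz * sz)
    clipped = 0
    if seg_len < 1e-12:
        # point deposit
        ix = int(np.floor((x0 - gx0) / dvox))
        iy = int(np.floor((y0 - gy0) / dvox))
        iz = int(np.floor(z0 / dvox))
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            vox = (ix * ny + iy) * nz + iz
            eps_t[batch, ch, vox] += eps
            epsL_t[batch, ch, vox] += eps * letd
            if record == 1 and rec_n < rec_vox.shape[0]:
                rec_vox[rec_n] = vox
                rec_val[rec_n] = eps
                rec_L[rec_n] = letd
                rec_ch[rec_n] = ch
                rec_n += 1
        else:
            clipped = 1
        return rec_n, clipped
    # clip the segment to the grid box (z in [0, nz*dvox), lateral box)
    t0 = 0.0
    t1 = 1.0
    for axis in range(3):
        if axis == 0:
            p, d, lo, hi = x0, sx, gx0, gx0 + nx * dvox
        elif axis == 1:
            p, d, lo, hi = y0, sy, gy0, gy0 + ny * dvox
        else:
            p, d, lo, hi = z0, sz, 0.0, nz * dvox
        if abs(d) < 1e-14:
            if p < lo or p >= hi:
                return rec_n, 1
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 >= t1:
        return rec_n, 1
    if t0 > 0.0 or t1 < 1.0:
        clipped = 1
    inside_frac = t1 - t0
    # walk voxels from t0 to t1 (Amanatides-Woo)
    eps_per_t = eps  # deposit proportional to parameter length
    px = x0 + sx * t0
    py = y0 + sy * t0
    pz = z0 + sz * t0
    ix = int(np.floor((px - gx0) / dvox))
    iy = int(np.floor((py - gy0) / dvox))
    iz = int(np.floor(pz / dvox))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1
    t = t0
    while t < t1 - 1e-14:
        # parameter value at the next voxel face along each axis
        tx = 1e30
        ty = 1e30
        tz = 1e30
        if sx > 1e-14:
            tx = ((gx0 + (ix + 1) * dvox) - x0) / sx
        elif sx < -1e-14:
            tx = ((gx0 + ix * dvox) - x0) / sx
        if sy > 1e-14:
            ty = ((gy0 + (iy + 1) * dvox) - y0) / sy
        elif sy < -1e-14:
            ty = ((gy0 + iy * dvox) - y0) / sy
        if sz > 1e-14:
            tz = (((iz + 1) * dvox) - z0) / sz
        elif sz < -1e-14:
            tz = ((iz * dvox) - z0) / sz
        t_next = tx
        if ty < t_next:
            t_next = ty
        if tz < t_next:
            t_next = tz
        if t_next > t1:
            t_next = t1
        share = eps_per_t * (t_next - t)
        if share > 0.0 and 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            vox = (ix * ny + iy) * nz + iz
            eps_t[batch, ch, vox] += share
            epsL_t[batch, ch, vox] += share * letd
            if record == 1 and rec_n < rec_vox.shape[0]:
                rec_vox[rec_n] = vox
                rec_val[rec_n] = share
                rec_L[rec_n] = letd
                rec_ch[rec_n] = ch
                rec_n += 1
        if t_next >= t1:
            break
        if tx <= ty and tx <= tz:
            ix += 1 if sx > 0 else -1
        elif ty <= tz:
            iy += 1 if sy > 0 else -1
        else:
            iz += 1 if sz > 0 else -1
        t = t_next
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            clipped = 1
            break
    # energy share that fell outside the box
    _ = inside_frac
    return rec_n, clipped


@njit(cache=True, fastmath=True)
def transport_one(
    x, y, z, dx, dy, dz, energy, weight,
    sf, coll_present, phantom_is_water,
    e0, inv_de, s_tab, r_tab,
    max_step, hcoef, bohr, inv_lambda,
    scatter_on, straggle_on, air_loss_on,
    gx0, gy0, dvox, nx, ny, nz,
    eps_t, epsL_t, batch,
    rng_state,
    rec_step, rec_vox, rec_val, rec_L, rec_ch, record,
):
    """Transport a single primary to completion.

    Returns (deposited, removed, escaped_energy, e_enter_phantom,
    dep_phantom, scattered, n_steps, n_vox_records, n_step_records,
    clipped, rng_state).  Energies are statistical-weight weighted MeV.
    """
    deposited = 0.0
    removed = 0.0
    escaped = 0.0
    e_enter_phantom = 0.0
    dep_phantom = 0.0
    scattered = 0
    entered_phantom = 0
    nvox = 0
    nstep = 0
    steps = 0
    alive = 1
    while alive == 1 and steps < MAX_STEPS:
        steps += 1
        mat = _material_at(x, y, z, sf, coll_present, phantom_is_water)
        if mat < 0:
            escaped += weight * energy
            break
        if mat == M_WATER and entered_phantom == 0:
            entered_phantom = 1
            e_enter_phantom = weight * energy
        if energy < E_CUTOFF:
            deposited += weight * energy
            if mat == M_WATER:
                dep_phantom += weight * energy
                letd = _lookup(e0, inv_de, s_tab[M_WATER], energy) * 0.1
                nvox, _ = _score_segment(
                    x, y, z, x, y, z, weight * energy, letd,
                    scattered, batch, gx0, gy0, dvox, nx, ny, nz,
                    eps_t, epsL_t, rec_vox, rec_val, rec_L, rec_ch, nvox, record,
                )
            energy = 0.0
            break
        # step length
        rres = _lookup(e0, inv_de, r_tab[mat], energy)
        step = max_step[mat]
        cap = 0.05 * rres
        if cap < 0.05:
            cap = 0.05
        if cap < step:
            step = cap
        t_bound = _boundary_distance(x, y, z, dx, dy, dz, sf, coll_present)
        crossed = 0
        if t_bound < step:
            step = t_bound
            crossed = 1
        if step < 0.0:
            step = 0.0
        # energy loss at mid-step energy + straggling
        s1 = _lookup(e0, inv_de, s_tab[mat], energy)
        if mat == M_AIR and air_loss_on == 0:
            s1 = 0.0
        e_mid = energy - 0.5 * s1 * step
        if e_mid < e0:
            e_mid = e0
        s2 = _lookup(e0, inv_de, s_tab[mat], e_mid)
        if mat == M_AIR and air_loss_on == 0:
            s2 = 0.0
        de = s2 * step
        if straggle_on == 1 and bohr[mat] > 0.0 and step > 0.0:
            n, rng_state = _normal(rng_state)
            de += np.sqrt(bohr[mat] * step) * n
        if de < 0.0:
            de = 0.0
        if de > energy:
            de = energy
        e_new = energy - de
        dies = 0
        if e_new < E_CUTOFF:
            de = energy
            e_new = 0.0
            dies = 1
        # advance along the pre-deflection direction
        x1 = x + dx * step
        y1 = y + dy * step
        z1 = z + dz * step
        # tag and score
        if mat == M_BRASS:
            scattered = 1
        dep = weight * de
        deposited += dep
        if mat == M_WATER and dep > 0.0:
            dep_phantom += dep
            letd = _lookup(e0, inv_de, s_tab[M_WATER], e_mid) * 0.1  # keV/um
            nvox, _ = _score_segment(
                x, y, z, x1, y1, z1, dep, letd, scattered, batch,
                gx0, gy0, dvox, nx, ny, nz,
                eps_t, epsL_t, rec_vox, rec_val, rec_L, rec_ch, nvox, record,
            )
        if record == 1 and nstep < rec_step.shape[0]:
            rec_step[nstep, 0] = x
            rec_step[nstep, 1] = y
            rec_step[nstep, 2] = z
            rec_step[nstep, 3] = x1
            rec_step[nstep, 4] = y1
            rec_step[nstep, 5] = z1
            rec_step[nstep, 6] = energy
            rec_step[nstep, 7] = e_new
            rec_step[nstep, 8] = weight * de
            rec_step[nstep, 9] = mat
            rec_step[nstep, 10] = scattered
            rec_step[nstep, 11] = weight
            nstep += 1
        x = x1
        y = y1
        z = z1
        # nuclear weight removal at the post-step energy
        if inv_lambda[mat] > 0.0 and step > 0.0 and dies == 0:
            xl = step * inv_lambda[mat]
            f = 1.0 - xl + 0.5 * xl * xl  # exp(-x) to O(x^3); x << 1 always
            removed += weight * (1.0 - f) * e_new
            weight = weight * f
        energy = e_new
        if dies == 1:
            break
        # Highland deflection (post-advance)
        if scatter_on == 1 and step > 0.0 and hcoef[mat] > 0.0:
            theta0 = hcoef[mat] / _pv(e_mid) * np.sqrt(step)
            n1, n2, rng_state = _normal2(rng_state)
            tx = theta0 * n1
            ty = theta0 * n2
            # orthonormal frame around the direction
            if abs(dz) < 0.999999:
                inv = 1.0 / np.sqrt(dx * dx + dy * dy)
                e1x = dy * inv
                e1y = -dx * inv
                e1z = 0.0
            else:
                e1x = 1.0
                e1y = 0.0
                e1z = 0.0
            e2x = dy * e1z - dz * e1y
            e2y = dz * e1x - dx * e1z
            e2z = dx * e1y - dy * e1x
            dx = dx + tx * e1x + ty * e2x
            dy = dy + tx * e1y + ty * e2y
            dz = dz + tx * e1z + ty * e2z
            inv = 1.0 / np.sqrt(dx * dx + dy * dy + dz * dz)
            dx *= inv
            dy *= inv
            dz *= inv
        if crossed == 1:
            x += dx * BOUNDARY_NUDGE
            y += dy * BOUNDARY_NUDGE
            z += dz * BOUNDARY_NUDGE
    return (
        deposited, removed, escaped, e_enter_phantom, dep_phantom,
        scattered, steps, nvox, nstep, 0, rng_state,
    )


@njit(cache=True, fastmath=True)
def run_primaries(
    n_primaries, seed, n_batches,
    spot_x, spot_y, spot_e, spot_sig_pos, spot_sig_ang, spot_cumw,
    z_iso, sad_x, sad_y, energy_dispersion,
    sf, coll_present, phantom_is_water,
    e0, inv_de, s_tab, r_tab,
    max_step, hcoef, bohr, inv_lambda,
    scatter_on, straggle_on, air_loss_on,
    gx0, gy0, dvox, nx, ny, nz,
    eps_t, epsL_t,
):
    """Transport `n_primaries` histories, sampled over the spot list
    proportionally to spot weight (stratified), into the batched tallies.

    Returns the energy ledger
    (initial, deposited, removed, escaped, entered_phantom, dep_phantom).
    """
    z_src = sf[0]
    total_w = spot_cumw[-1]
    empty_step = np.zeros((0, 12))
    empty_i = np.zeros(0, dtype=np.int64)
    empty_f = np.zeros(0)
    empty_b = np.zeros(0, dtype=np.int8)
    e_init = 0.0
    e_dep = 0.0
    e_rem = 0.0
    e_esc = 0.0
    e_phan = 0.0
    e_dep_phan = 0.0
    for p in range(n_primaries):
        rng = primary_stream(seed, p)
        # stratified spot selection
        u = (p + 0.5) / n_primaries * total_w
        s = np.searchsorted(spot_cumw, u)
        if s >= spot_x.shape[0]:
            s = spot_x.shape[0] - 1
        # phase-space sampling at the source plane
        fx = (z_src - (z_iso - sad_x)) / sad_x  # (z_src - z_mag)/(z_iso - z_mag)
        fy = (z_src - (z_iso - sad_y)) / sad_y
        n1, rng = _normal(rng)
        n2, rng = _normal(rng)
        n3, rng = _normal(rng)
        n4, rng = _normal(rng)
        n5, rng = _normal(rng)
        x = spot_x[s] * fx + spot_sig_pos[s] * n1
        y = spot_y[s] * fy + spot_sig_pos[s] * n2
        tx = spot_x[s] / sad_x + spot_sig_ang[s] * n3
        ty = spot_y[s] / sad_y + spot_sig_ang[s] * n4
        energy = spot_e[s] * (1.0 + energy_dispersion * n5)
        inv = 1.0 / np.sqrt(tx * tx + ty * ty + 1.0)
        batch = p % n_batches
        out = transport_one(
            x, y, z_src + 1e-9, tx * inv, ty * inv, inv, energy, 1.0,
            sf, coll_present, phantom_is_water,
            e0, inv_de, s_tab, r_tab,
            max_step, hcoef, bohr, inv_lambda,
            scatter_on, straggle_on, air_loss_on,
            gx0, gy0, dvox, nx, ny, nz,
            eps_t, epsL_t, batch, rng,
            empty_step, empty_i, empty_f, empty_f, empty_b, 0,
        )
        e_init += energy
        e_dep += out[0]
        e_rem += out[1]
        e_esc += out[2]
        e_phan += out[3]
        e_dep_phan += out[4]
    return e_init, e_dep, e_rem, e_esc, e_phan, e_dep_phan


@njit(cache=True, fastmath=True)
def pencil_depth_dose(
    n, seed, energy0, energy_dispersion,
    sf, e0, inv_de, s_tab, r_tab,
    max_step, hcoef, bohr, inv_lambda,
    scatter_on, straggle_on, air_loss_on,
    dz_bin, dose_z,
):
    """Laterally integrated depth-dose of an on-axis pencil beam through the
    collimator-free scene, in MeV per z-bin summed over `n` primaries.

    Used by the SOBP weight fit: for a broad uniform field of fluence
    `phi` protons/cm^2, dose(z) = phi * dose_z(z) / (n * dz_bin) MeV cm^2/g.
    """
    nbin = dose_z.shape[0]
    for p in range(n):
        rng = primary_stream(seed, p)
        nr, rng = _normal(rng)
        energy = energy0 * (1.0 + energy_dispersion * nr)
        x = 0.0
        y = 0.0
        z = sf[0] + 1e-9
        dx = 0.0
        dy = 0.0
        dz = 1.0
        weight = 1.0
        steps = 0
        while steps < MAX_STEPS:
            steps += 1
            mat = _material_at(x, y, z, sf, 0, 1)
            if mat < 0:
                break
            if energy < E_CUTOFF:
                if mat == M_WATER:
                    ib = int(z / dz_bin)
                    if 0 <= ib < nbin:
                        dose_z[ib] += weight * energy
                break
            rres = _lookup(e0, inv_de, r_tab[mat], energy)
            step = max_step[mat]
            cap = 0.05 * rres
            if cap < 0.05:
                cap = 0.05
            if cap < step:
                step = cap
            t_bound = _boundary_distance(x, y, z, dx, dy, dz, sf, 0)
            crossed = 0
            if t_bound < step:
                step = t_bound
                crossed = 1
            s1 = _lookup(e0, inv_de, s_tab[mat], energy)
            if mat == M_AIR and air_loss_on == 0:
                s1 = 0.0
            e_mid = energy - 0.5 * s1 * step
            if e_mid < e0:
                e_mid = e0
            s2 = _lookup(e0, inv_de, s_tab[mat], e_mid)
            if mat == M_AIR and air_loss_on == 0:
                s2 = 0.0
            de = s2 * step
            if straggle_on == 1 and bohr[mat] > 0.0 and step > 0.0:
                nr, rng = _normal(rng)
                de += np.sqrt(bohr[mat] * step) * nr
            if de < 0.0:
                de = 0.0
            if de > energy:
                de = energy
            e_new = energy - de
            dies = 0
            if e_new < E_CUTOFF:
                de = energy
                e_new = 0.0
                dies = 1
            x1 = x + dx * step
            y1 = y + dy * step
            z1 = z + dz * step
            if mat == M_WATER and de > 0.0:
                # split the deposit across z-bins by path fraction
                za = z
                zb = z1
                if zb < za:
                    za, zb = zb, za
                ia = int(za / dz_bin)
                ib = int(zb / dz_bin)
                if ia == ib:
                    if 0 <= ia < nbin:
                        dose_z[ia] += weight * de
                else:
                    span = zb - za
                    for ibin in range(max(ia, 0), min(ib, nbin - 1) + 1):
                        lo = max(za, ibin * dz_bin)
                        hi = min(zb, (ibin + 1) * dz_bin)
                        if hi > lo:
                            dose_z[ibin] += weight * de * (hi - lo) / span
            x = x1
            y = y1
            z = z1
            if inv_lambda[mat] > 0.0 and step > 0.0 and dies == 0:
                xl = step * inv_lambda[mat]
                weight = weight * (1.0 - xl + 0.5 * xl * xl)
            energy = e_new
            if dies == 1:
                break
            if scatter_on == 1 and step > 0.0 and hcoef[mat] > 0.0:
                theta0 = hcoef[mat] / _pv(e_mid) * np.sqrt(step)
                n1, n2, rng = _normal2(rng)
                txx = theta0 * n1
                tyy = theta0 * n2
                if abs(dz) < 0.999999:
                    invn = 1.0 / np.sqrt(dx * dx + dy * dy)
                    e1x = dy * invn
                    e1y = -dx * invn
                    e1z = 0.0
                else:
                    e1x = 1.0
                    e1y = 0.0
                    e1z = 0.0
                e2x = dy * e1z - dz * e1y
                e2y = dz * e1x - dx * e1z
                e2z = dx * e1y - dy * e1x
                dx = dx + txx * e1x + tyy * e2x
                dy = dy + txx * e1y + tyy * e2y
                dz = dz + txx * e1z + tyy * e2z
                invn = 1.0 / np.sqrt(dx * dx + dy * dy + dz * dz)
                dx *= invn
                dy *= invn
                dz *= invn
            if crossed == 1:
                x += dx * BOUNDARY_NUDGE
                y += dy * BOUNDARY_NUDGE
                z += dz * BOUNDARY_NUDGE
    return 0


@njit(cache=True, fastmath=True)
def trace_to_plane(
    n, seed, x_iso, y_iso, energy0, sig_pos, sig_ang,
    z_iso, sad_x, sad_y, energy_dispersion, z_plane,
    sf, coll_present,
    e0, inv_de, s_tab, r_tab,
    max_step, hcoef, bohr, inv_lambda,
    scatter_on, straggle_on, air_loss_on,
    out_xy,
):
    """Collimator-free in-air verification: transport one spot and record
    (x, y) at the crossing of ``z_plane``.  Returns the number recorded."""
    z_src = sf[0]
    fx = (z_src - (z_iso - sad_x)) / sad_x
    fy = (z_src - (z_iso - sad_y)) / sad_y
    count = 0
    for p in range(n):
        rng = primary_stream(seed, p)
        n1, rng = _normal(rng)
        n2, rng = _normal(rng)
        n3, rng = _normal(rng)
        n4, rng = _normal(rng)
        n5, rng = _normal(rng)
        x = x_iso * fx + sig_pos * n1
        y = y_iso * fy + sig_pos * n2
        tx = x_iso / sad_x + sig_ang * n3
        ty = y_iso / sad_y + sig_ang * n4
        energy = energy0 * (1.0 + energy_dispersion * n5)
        inv = 1.0 / np.sqrt(tx * tx + ty * ty + 1.0)
        dx = tx * inv
        dy = ty * inv
        dz = inv
        z = z_src + 1e-9
        alive = 1
        steps = 0
        while alive == 1 and steps < MAX_STEPS:
            steps += 1
            if z >= z_plane:
                # back up to the exact plane crossing
                back = (z - z_plane) / dz
                out_xy[count, 0] = x - dx * back
                out_xy[count, 1] = y - dy * back
                count += 1
                break
            mat = _material_at(x, y, z, sf, coll_present, 0)
            if mat < 0 or energy < E_CUTOFF:
                break
            rres = _lookup(e0, inv_de, r_tab[mat], energy)
            step = max_step[mat]
            cap = 0.05 * rres
            if cap < 0.05:
                cap = 0.05
            if cap < step:
                step = cap
            t_bound = _boundary_distance(x, y, z, dx, dy, dz, sf, coll_present)
            crossed = 0
            if t_bound < step:
                step = t_bound
                crossed = 1
            # stop the step at the recording plane
            if dz > 0 and z + dz * step > z_plane:
                step = (z_plane - z) / dz + 1e-9
                crossed = 0
            s1 = _lookup(e0, inv_de, s_tab[mat], energy)
            if mat == M_AIR and air_loss_on == 0:
                s1 = 0.0
            e_mid = energy - 0.5 * s1 * step
            if e_mid < e0:
                e_mid = e0
            s2 = _lookup(e0, inv_de, s_tab[mat], e_mid)
            if mat == M_AIR and air_loss_on == 0:
                s2 = 0.0
            de = s2 * step
            if straggle_on == 1 and bohr[mat] > 0.0 and step > 0.0:
                nr, rng = _normal(rng)
                de += np.sqrt(bohr[mat] * step) * nr
            if de < 0.0:
                de = 0.0
            if de > energy:
                de = energy
            energy = energy - de
            x += dx * step
            y += dy * step
            z += dz * step
            if energy < E_CUTOFF:
                break
            if scatter_on == 1 and step > 0.0 and hcoef[mat] > 0.0:
                theta0 = hcoef[mat] / _pv(e_mid) * np.sqrt(step)
                na, nb, rng = _normal2(rng)
                txx = theta0 * na
                tyy = theta0 * nb
                if abs(dz) < 0.999999:
                    invn = 1.0 / np.sqrt(dx * dx + dy * dy)
                    e1x = dy * invn
                    e1y = -dx * invn
                    e1z = 0.0
                else:
                    e1x = 1.0
                    e1y = 0.0
                    e1z = 0.0
                e2x = dy * e1z - dz * e1y
                e2y = dz * e1x - dx * e1z
                e2z = dx * e1y - dy * e1x
                dx = dx + txx * e1x + tyy * e2x
                dy = dy + txx * e1y + tyy * e2y
                dz = dz + txx * e1z + tyy * e2z
                invn = 1.0 / np.sqrt(dx * dx + dy * dy + dz * dz)
                dx *= invn
                dy *= invn
                dz *= invn
            if crossed == 1:
                x += dx * BOUNDARY_NUDGE
                y += dy * BOUNDARY_NUDGE
                z += dz * BOUNDARY_NUDGE
    return count
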