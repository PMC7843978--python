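"""Numba-compiled weighted-photon voxel Monte Carlo kernel.

mcxyz-lineage transport: exponential scattering free paths, continuous
Beer-Lambert absorption weighting along every traversed voxel segment,
Henyey-Greenstein deflection sampling, unpolarized Fresnel reflection /
Snell refraction at the surface and (optionally) at internal index
mismatches, Russian roulette termination, and NA-limited square-aperture
detection on the top surface.

Detection supports two estimators: analog (tally photons physically exiting
through the aperture inside the acceptance cone) and shadow-ray next-event
estimation (score the expected uncollided escape into the detector at every
scattering event).  Both are unbiased; the shadow-ray form has far lower
variance for this small, distant aperture.

Optional variance reduction: importance-based weight windows.  A coarse
importance map (collision density of an adjoint-style run launched from the
detector) defines a position-dependent target weight; photons above the
window split, photons below it play Russian roulette.  Unbiased by
construction, it concentrates the photon population along the paths that can
reach the detector.

Randomness is counter-based: every photon owns a splitmix64 substream seeded
from (base seed, global photon index), so partitioned runs merge exactly and
the same photon index retraces the same path in any geometry until the
geometries diverge along it (common random numbers across pulse positions
and scenarios).  Split photons spawn child substreams from the parent state.

Tally layout (weights, normalized by the caller):
  0 specular, 1 diffuse reflectance (top exits), 2 detected, 3 absorbed,
  4 transmitted (bottom), 5 side escape, 6 roulette loss, 7 roulette gain,
  8 scattering events (diagnostic count).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "transport_kernel",
    "TALLY_SPECULAR",
    "TALLY_DIFFUSE",
    "TALLY_DETECTED",
    "TALLY_ABSORBED",
    "TALLY_TRANSMITTED",
    "TALLY_SIDE",
    "TALLY_ROULETTE_LOSS",
    "TALLY_ROULETTE_GAIN",
    "TALLY_EVENTS",
]

TALLY_SPECULAR = 0
TALLY_DIFFUSE = 1
TALLY_DETECTED = 2
TALLY_ABSORBED = 3
TALLY_TRANSMITTED = 4
TALLY_SIDE = 5
TALLY_ROULETTE_LOSS = 6
TALLY_ROULETTE_GAIN = 7
TALLY_EVENTS = 8
N_TALLIES = 9

_U64 = np.uint64
_GAMMA = _U64(0x9E3779B97F4A7C15)
_STACK_CAP = 4096


@njit(cache=True, fastmath=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, fastmath=True, inline="always")
def _photon_stream(seed, index):
    # Distinct well-separated splitmix64 starting state per photon.
    return _mix64(seed ^ (_U64(index) * _U64(0xD1342543DE82EF95)))


@njit(cache=True, fastmath=True, inline="always")
def _u01(state):
    """Advance the splitmix64 state; return uniform double in (0, 1]."""
    state = state + _GAMMA
    x = _mix64(state)
    return state, ((x >> _U64(11)) + _U64(1)) * 1.1102230246251565e-16


@njit(cache=True, fastmath=True, inline="always")
def _hg_cos(g, u):
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - f * f) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, fastmath=True, inline="always")
def _hg_phase(g, c):
    """Henyey-Greenstein phase function value (per steradian)."""
    denom = 1.0 + g * g - 2.0 * g * c
    return (1.0 - g * g) / (4.0 * np.pi * denom * np.sqrt(denom))


@njit(cache=True, fastmath=True, inline="always")
def _fresnel_unpolarized(n1, n2, cosi):
    """Unpolarized reflectance and transmitted cosine for |cos incidence|."""
    sini2 = 1.0 - cosi * cosi
    sint2 = (n1 / n2) * (n1 / n2) * sini2
    if sint2 >= 1.0:
        return 1.0, 0.0  # total internal reflection
    cost = np.sqrt(1.0 - sint2)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp), cost


@njit(cache=True, fastmath=True, inline="always")
def _spin(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nux = sint * cosp
        nuy = sint * sinp
        nuz = cost * (1.0 if uz >= 0.0 else -1.0)
    else:
        temp = np.sqrt(1.0 - uz * uz)
        nux = sint * (ux * uz * cosp - uy * sinp) / temp + ux * cost
        nuy = sint * (uy * uz * cosp + ux * sinp) / temp + uy * cost
        nuz = -sint * cosp * temp + uz * cost
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True, fastmath=True)
def _nee_contribution(
    state, w, x, y, z, ix, iy, iz, ux, uy, uz,
    media, mua, mus, gg, nn,
    dx, dy, dz, x0, y0,
    n_ambient, det_x, det_y, det_half,
    cos_int_min, internal_fresnel,
):
    """Shadow-ray estimate of the detector signal from one scattering event.

    Samples one upward direction uniformly over the internal acceptance cone
    (the internal solid angle that refracts into the detector's NA), follows
    the straight uncollided flight to the surface accumulating exp(-mu_t l)
    per voxel, applies Fresnel transmission at the exit, and scores

        w * P_HG(u . omega) * Omega_cone * T * (1 - R)

    if the exit point falls inside the aperture.  Internal index-mismatch
    faces along the ray reduce it by their (1 - R); their refractive bending
    is neglected (such rays are attenuated to nothing in practice).
    """
    state, u1 = _u01(state)
    state, u2 = _u01(state)
    cost = cos_int_min + (1.0 - cos_int_min) * u1
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * np.pi * u2
    ox = sint * np.cos(phi)
    oy = sint * np.sin(phi)
    oz = -cost  # upward

    t_total = z / cost
    ex = x + ox * t_total
    ey = y + oy * t_total
    if abs(ex - det_x) > det_half or abs(ey - det_y) > det_half:
        return state, 0.0

    # march the straight segment through the voxel grid
    jx, jy, jz = ix, iy, iz
    px, py, pz = x, y, z
    tau = 0.0
    trans_fresnel = 1.0
    m_prev = media[jx, jy, jz]
    while jz >= 0:
        m = media[jx, jy, jz]
        if internal_fresnel and nn[m] != nn[m_prev]:
            r_f, _ = _fresnel_unpolarized(nn[m_prev], nn[m], cost)
            trans_fresnel *= 1.0 - r_f
            if trans_fresnel <= 0.0:
                return state, 0.0
        m_prev = m
        if ox > 0.0:
            d_x = ((jx + 1) * dx + x0 - px) / ox
        elif ox < 0.0:
            d_x = (jx * dx + x0 - px) / ox
        else:
            d_x = 1e30
        if oy > 0.0:
            d_y = ((jy + 1) * dy + y0 - py) / oy
        elif oy < 0.0:
            d_y = (jy * dy + y0 - py) / oy
        else:
            d_y = 1e30
        d_z = (jz * dz - pz) / oz  # oz < 0
        axis = 0
        d_b = d_x
        if d_y < d_b:
            d_b = d_y
            axis = 1
        if d_z < d_b:
            d_b = d_z
            axis = 2
        if d_b < 0.0:
            d_b = 0.0
        tau += (mua[m] + mus[m]) * d_b
        if tau > 40.0:
            return state, 0.0
        px += ox * d_b
        py += oy * d_b
        pz += oz * d_b
        if axis == 0:
            jx += 1 if ox > 0.0 else -1
            if jx < 0 or jx >= media.shape[0]:
                return state, 0.0
        elif axis == 1:
            jy += 1 if oy > 0.0 else -1
            if jy < 0 or jy >= media.shape[1]:
                return state, 0.0
        else:
            jz -= 1
            if jz < 0:
                break
    # exit through the top face of the surface voxel
    r_exit, _ = _fresnel_unpolarized(nn[m_prev], n_ambient, cost)
    c = ux * ox + uy * oy + uz * oz
    g_m = gg[media[ix, iy, iz]]
    omega_cone = 2.0 * np.pi * (1.0 - cos_int_min)
    contrib = (
        w * _hg_phase(g_m, c) * omega_cone * np.exp(-tau)
        * trans_fresnel * (1.0 - r_exit)
    )
    return state, contrib


@njit(cache=True, fastmath=True)
def transport_kernel(
    media,            # uint8 (nx, ny, nz)
    mua, mus, gg, nn,  # float64 per-label property arrays
    dx, dy, dz,
    x0, y0,           # coordinates of the low-x / low-y grid corner (z0 = 0)
    src_x, src_y, src_radius, src_gaussian,
    n_ambient,
    det_x, det_y, det_half, det_cos_min, det_na,
    n_photons, photon_offset, seed,
    roulette_threshold, roulette_multiplier,
    internal_fresnel, use_nee,
    abs_map, accumulate_map,
    imp_map, accumulate_importance,  # coarse (cx, cy, cz) collision tally
    ww_target, use_ww,               # coarse per-supervoxel target weight
):
    nx, ny, nz = media.shape
    lx = nx * dx
    ly = ny * dy
    tallies = np.zeros(N_TALLIES)
    inv_mult = 1.0 / roulette_multiplier

    # supervoxel decimation factors for the coarse importance/window maps
    if accumulate_importance:
        fx = (nx + imp_map.shape[0] - 1) // imp_map.shape[0]
        fy = (ny + imp_map.shape[1] - 1) // imp_map.shape[1]
        fz = (nz + imp_map.shape[2] - 1) // imp_map.shape[2]
    elif use_ww:
        fx = (nx + ww_target.shape[0] - 1) // ww_target.shape[0]
        fy = (ny + ww_target.shape[1] - 1) // ww_target.shape[1]
        fz = (nz + ww_target.shape[2] - 1) // ww_target.shape[2]
    else:
        fx = fy = fz = 1

    # internal acceptance cone for the shadow-ray (next-event) estimator:
    # directions that refract at the surface into the detector's NA
    n_surface = nn[media[0, 0, 0]]
    sin_int_max = min(1.0, det_na * n_ambient / n_surface)
    cos_int_min = np.sqrt(1.0 - sin_int_max * sin_int_max)
    tan_int_max = sin_int_max / cos_int_min
    mu_t_min = 1e30
    for lbl in range(mua.shape[0]):
        if mua[lbl] + mus[lbl] < mu_t_min:
            mu_t_min = mua[lbl] + mus[lbl]
    z_cut = 40.0 / mu_t_min if mu_t_min > 0 else 1e30

    # secondary-particle stack for weight-window splitting
    stack = np.empty((_STACK_CAP, 7))
    stack_state = np.empty(_STACK_CAP, dtype=np.uint64)

    for ip in range(n_photons):
        state = _photon_stream(_U64(seed), _U64(photon_offset + ip))
        n_spawned = 0
        sp = 0

        # --- launch: sample the beam profile on the surface ---
        x = src_x
        y = src_y
        for _ in range(1000):
            state, u1 = _u01(state)
            state, u2 = _u01(state)
            if src_gaussian:
                r = src_radius * np.sqrt(-np.log(u1) / 2.0)
            else:
                r = src_radius * np.sqrt(u1)
            phi = 2.0 * np.pi * u2
            x = src_x + r * np.cos(phi)
            y = src_y + r * np.sin(phi)
            if x0 < x < x0 + lx and y0 < y < y0 + ly:
                break
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        ix = int((x - x0) / dx)
        iy = int((y - y0) / dy)
        iz = 0
        if ix >= nx:
            ix = nx - 1
        if iy >= ny:
            iy = ny - 1

        m = media[ix, iy, iz]
        r_spec, _ = _fresnel_unpolarized(n_ambient, nn[m], 1.0)
        tallies[TALLY_SPECULAR] += r_spec
        w = 1.0 - r_spec

        working = True
        while working:
            alive = True
            events = 0
            while alive:
                state, u = _u01(state)
                s = -np.log(u)  # dimensionless scattering depth
                while s > 0.0 and alive:
                    events += 1
                    if events > 10_000_000:
                        tallies[TALLY_ROULETTE_LOSS] += w
                        alive = False
                        break
                    m = media[ix, iy, iz]
                    mus_m = mus[m]
                    mua_m = mua[m]
                    d_scat = s / mus_m if mus_m > 0.0 else 1e30

                    # distance to the nearest voxel face along the direction
                    if ux > 0.0:
                        d_x = ((ix + 1) * dx + x0 - x) / ux
                    elif ux < 0.0:
                        d_x = (ix * dx + x0 - x) / ux
                    else:
                        d_x = 1e30
                    if uy > 0.0:
                        d_y = ((iy + 1) * dy + y0 - y) / uy
                    elif uy < 0.0:
                        d_y = (iy * dy + y0 - y) / uy
                    else:
                        d_y = 1e30
                    if uz > 0.0:
                        d_z = ((iz + 1) * dz - z) / uz
                    elif uz < 0.0:
                        d_z = (iz * dz - z) / uz
                    else:
                        d_z = 1e30

                    axis = 0
                    d_b = d_x
                    if d_y < d_b:
                        d_b = d_y
                        axis = 1
                    if d_z < d_b:
                        d_b = d_z
                        axis = 2
                    if d_b < 0.0:
                        d_b = 0.0

                    scatter_here = d_scat <= d_b
                    step = d_scat if scatter_here else d_b

                    if mua_m > 0.0 and step > 0.0:
                        att = np.exp(-mua_m * step)
                        dep = w * (1.0 - att)
                        tallies[TALLY_ABSORBED] += dep
                        if accumulate_map:
                            abs_map[ix, iy, iz] += dep
                        w *= att
                    x += ux * step
                    y += uy * step
                    z += uz * step

                    if scatter_here:
                        s = 0.0
                        tallies[TALLY_EVENTS] += 1.0
                        if accumulate_importance:
                            imp_map[ix // fx, iy // fy, iz // fz] += w
                        g_m = gg[m]
                        if (
                            use_nee
                            and z <= z_cut
                            and abs(x - det_x) <= det_half + z * tan_int_max
                            and abs(y - det_y) <= det_half + z * tan_int_max
                        ):
                            state, contrib = _nee_contribution(
                                state, w, x, y, z, ix, iy, iz, ux, uy, uz,
                                media, mua, mus, gg, nn,
                                dx, dy, dz, x0, y0,
                                n_ambient, det_x, det_y, det_half,
                                cos_int_min, internal_fresnel,
                            )
                            tallies[TALLY_DETECTED] += contrib
                        state, u1 = _u01(state)
                        state, u2 = _u01(state)
                        cost = _hg_cos(g_m, u1)
                        ux, uy, uz = _spin(ux, uy, uz, cost, 2.0 * np.pi * u2)

                        if use_ww:
                            wt = ww_target[ix // fx, iy // fy, iz // fz]
                            if w > 2.0 * wt:
                                n_copies = int(w / wt)
                                if n_copies > 8:
                                    n_copies = 8
                                share = w / n_copies
                                for _c in range(n_copies - 1):
                                    if sp < _STACK_CAP:
                                        stack[sp, 0] = x
                                        stack[sp, 1] = y
                                        stack[sp, 2] = z
                                        stack[sp, 3] = ux
                                        stack[sp, 4] = uy
                                        stack[sp, 5] = uz
                                        stack[sp, 6] = share
                                        n_spawned += 1
                                        stack_state[sp] = _photon_stream(
                                            state, _U64(n_spawned)
                                        )
                                        sp += 1
                                    else:
                                        # stack full: keep the weight on the
                                        # current photon (still unbiased)
                                        share += w / n_copies
                                w = share
                            elif w < 0.5 * wt:
                                state, u3 = _u01(state)
                                if u3 <= w / wt:
                                    tallies[TALLY_ROULETTE_GAIN] += wt - w
                                    w = wt
                                else:
                                    tallies[TALLY_ROULETTE_LOSS] += w
                                    alive = False
                        elif w < roulette_threshold:
                            state, u3 = _u01(state)
                            if u3 <= inv_mult:
                                tallies[TALLY_ROULETTE_GAIN] += w * (
                                    roulette_multiplier - 1.0
                                )
                                w *= roulette_multiplier
                            else:
                                tallies[TALLY_ROULETTE_LOSS] += w
                                alive = False
                    else:
                        s -= d_b * mus_m
                        if s < 0.0:
                            s = 0.0
                        # cross the face
                        if axis == 0:
                            jx = ix + (1 if ux > 0.0 else -1)
                            jy = iy
                            jz = iz
                        elif axis == 1:
                            jx = ix
                            jy = iy + (1 if uy > 0.0 else -1)
                            jz = iz
                        else:
                            jx = ix
                            jy = iy
                            jz = iz + (1 if uz > 0.0 else -1)

                        if jz < 0:
                            # top surface: refract into ambient or reflect back
                            cosi = -uz
                            r_f, cost = _fresnel_unpolarized(nn[m], n_ambient, cosi)
                            state, u4 = _u01(state)
                            if u4 < r_f:
                                uz = -uz
                            else:
                                tallies[TALLY_DIFFUSE] += w
                                if (
                                    not use_nee
                                    and cost >= det_cos_min
                                    and abs(x - det_x) <= det_half
                                    and abs(y - det_y) <= det_half
                                ):
                                    tallies[TALLY_DETECTED] += w
                                alive = False
                        elif jz >= nz:
                            tallies[TALLY_TRANSMITTED] += w
                            alive = False
                        elif jx < 0 or jx >= nx or jy < 0 or jy >= ny:
                            tallies[TALLY_SIDE] += w
                            alive = False
                        else:
                            m2 = media[jx, jy, jz]
                            if internal_fresnel and nn[m2] != nn[m]:
                                if axis == 0:
                                    cosi = abs(ux)
                                elif axis == 1:
                                    cosi = abs(uy)
                                else:
                                    cosi = abs(uz)
                                r_f, cost = _fresnel_unpolarized(nn[m], nn[m2], cosi)
                                state, u5 = _u01(state)
                                if u5 < r_f:
                                    if axis == 0:
                                        ux = -ux
                                    elif axis == 1:
                                        uy = -uy
                                    else:
                                        uz = -uz
                                else:
                                    ratio = nn[m] / nn[m2]
                                    if axis == 0:
                                        sign = 1.0 if ux > 0.0 else -1.0
                                        ux2 = sign * cost
                                        uy2 = uy * ratio
                                        uz2 = uz * ratio
                                    elif axis == 1:
                                        sign = 1.0 if uy > 0.0 else -1.0
                                        ux2 = ux * ratio
                                        uy2 = sign * cost
                                        uz2 = uz * ratio
                                    else:
                                        sign = 1.0 if uz > 0.0 else -1.0
                                        ux2 = ux * ratio
                                        uy2 = uy * ratio
                                        uz2 = sign * cost
                                    norm = np.sqrt(
                                        ux2 * ux2 + uy2 * uy2 + uz2 * uz2
                                    )
                                    ux = ux2 / norm
                                    uy = uy2 / norm
                                    uz = uz2 / norm
                                    ix = jx
                                    iy = jy
                                    iz = jz
                            else:
                                ix = jx
                                iy = jy
                                iz = jz

            # continue with a stacked split photon, if any
            if sp > 0:
                sp -= 1
                x = stack[sp, 0]
                y = stack[sp, 1]
                z = stack[sp, 2]
                ux = stack[sp, 3]
                uy = stack[sp, 4]
                uz = stack[sp, 5]
                w = stack[sp, 6]
                state = stack_state[sp]
                ix = int((x - x0) / dx)
                iy = int((y - y0) / dy)
                iz = int(z / dz)
                if ix < 0:
                    ix = 0
                elif ix >= nx:
                    ix = nx - 1
                if iy < 0:
                    iy = 0
                elif iy >= ny:
                    iy = ny - 1
                if iz < 0:
                    iz = 0
                elif iz >= nz:
                    iz = nz - 1
            else:
                working = False
    return tallies
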