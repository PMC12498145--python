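"""Numba photon-transport kernel.

Voxelized heterogeneous media, MCML-style survival weighting (deposit
``w * mu_a / mu_t`` at each interaction), Henyey-Greenstein scattering,
Fresnel reflection at the top surface, absorbing side/bottom boundaries,
Russian roulette below a weight threshold. The same kernel serves
excitation (collimated launches, optional fluorescence-event recording)
and emission (isotropic launches from an event table with exponential
lifetime delays).

Geometry: z is depth, z = 0 is the top surface, the medium occupies
z in [0, nz * h]. Positions in mm, time in ps.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: Vacuum speed of light, mm/ps.
C_MM_PER_PS = 0.299792

# launch modes
LAUNCH_PLANAR = 0    # collimated downward, x ~ U[x0,x1], y ~ U[y0,y1]
LAUNCH_PENCIL = 1    # collimated downward at (x0, y0)
LAUNCH_TABLE_ISO = 2   # isotropic from source table (emission)
LAUNCH_TABLE_COLL = 3  # collimated downward from source table x/y (pattern-sampled)

# exit faces
FACE_TOP = 0
FACE_BOTTOM = 1
FACE_SIDE = 2

_EPS = 1e-7  # boundary push, mm


@njit(cache=True, inline="always")
def _fresnel_r(n1, n2, ci):
    """Unpolarized Fresnel reflectance for incidence cosine ``ci``."""
    if n1 == n2:
        return 0.0
    sin2t = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if sin2t >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - sin2t)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _hg_cosine(g):
    u = np.random.random()
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) > 0.99999:
        nux = sint * cosp
        nuy = sint * sinp
        nuz = cost if uz > 0.0 else -cost
    else:
        den = math.sqrt(1.0 - uz * uz)
        nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nuz = -sint * cosp * den + uz * cost
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def run_transport(
    seed,
    label,            # (nx, ny, nz) uint8 tissue labels
    h,                # voxel size, mm
    mua_tab,          # per-label mu_a (1/mm)
    mus_tab,          # per-label mu_s (1/mm)
    g_tab,            # per-label anisotropy
    n_medium,         # refractive index inside
    n_outside,        # refractive index above the top surface
    launch_mode,
    n_photons,        # used by modes 0/1
    x0, x1, y0, y1,   # launch field (modes 0/1)
    src_x, src_y, src_z, src_t, src_w, src_tag, src_tau_ps,  # table modes
    t_max_ps,
    absorbed,         # (nx, ny, nz) float64, time-integrated deposit
    record_tr,        # bool: fill tr_field
    tr_field,         # (nx, ny, nz, nt) float32 or dummy (1,1,1,1)
    tr_bin_ps,
    fluor_yield,      # (nx, ny, nz) float32
    record_events,    # bool
    ev_ref_w,         # thinning reference weight (0 -> store raw)
    ev_buf,           # (cap, 6) float32: ix, iy, iz, t, w, tag
    record_exits,     # bool
    out_buf,          # (cap, 6) float32: x, y, t, w, tag, face
    roulette_thresh,
    roulette_p,
    mirror_sides=False,  # reflecting x/y boundaries (laterally infinite medium)
):
    np.random.seed(seed)
    nx, ny, nz = label.shape
    lx = nx * h
    ly = ny * h
    lz = nz * h
    nt = tr_field.shape[3]

    launched_w = 0.0
    absorbed_w = 0.0
    escaped_top_w = 0.0
    escaped_other_w = 0.0
    time_killed_w = 0.0
    roulette_killed_w = 0.0
    roulette_gain_w = 0.0

    n_ev = 0
    n_out = 0
    ev_cap = ev_buf.shape[0]
    out_cap = out_buf.shape[0]
    ev_overflow = 0
    out_overflow = 0

    if launch_mode == LAUNCH_TABLE_ISO or launch_mode == LAUNCH_TABLE_COLL:
        n_launch = src_x.shape[0]
    else:
        n_launch = n_photons

    inv_c = 1.0 / C_MM_PER_PS

    for ip in range(n_launch):
        # --- launch ---
        if launch_mode == LAUNCH_PLANAR:
            px = x0 + (x1 - x0) * np.random.random()
            py = y0 + (y1 - y0) * np.random.random()
            pz = _EPS
            ux = 0.0
            uy = 0.0
            uz = 1.0
            t = 0.0
            w = 1.0
            tag = px
        elif launch_mode == LAUNCH_PENCIL:
            px = x0
            py = y0
            pz = _EPS
            ux = 0.0
            uy = 0.0
            uz = 1.0
            t = 0.0
            w = 1.0
            tag = px
        else:
            px = src_x[ip]
            py = src_y[ip]
            pz = src_z[ip]
            t = src_t[ip]
            w = src_w[ip]
            tag = src_tag[ip]
            if src_tau_ps[ip] > 0.0:
                t += -math.log(np.random.random()) * src_tau_ps[ip]
            if launch_mode == LAUNCH_TABLE_ISO:
                uz = 2.0 * np.random.random() - 1.0
                phi = 2.0 * math.pi * np.random.random()
                sro = math.sqrt(max(0.0, 1.0 - uz * uz))
                ux = sro * math.cos(phi)
                uy = sro * math.sin(phi)
            else:
                ux = 0.0
                uy = 0.0
                uz = 1.0
                pz = _EPS

        launched_w += w
        # roulette threshold is relative to the launch weight so that
        # low-weight emission launches are not immediately rouletted
        w_floor = roulette_thresh * w
        s = -math.log(np.random.random())  # dimensionless optical path

        while True:
            ix = int(px / h)
            iy = int(py / h)
            iz = int(pz / h)
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                # numerical straggler: treat as side loss
                escaped_other_w += w
                break
            lab = label[ix, iy, iz]
            mua = mua_tab[lab]
            mus = mus_tab[lab]
            mut = mua + mus

            # distance to nearest voxel boundary along the direction
            db = 1e30
            if ux > 0.0:
                d = ((ix + 1) * h - px) / ux
                if d < db:
                    db = d
            elif ux < 0.0:
                d = (ix * h - px) / ux
                if d < db:
                    db = d
            if uy > 0.0:
                d = ((iy + 1) * h - py) / uy
                if d < db:
                    db = d
            elif uy < 0.0:
                d = (iy * h - py) / uy
                if d < db:
                    db = d
            if uz > 0.0:
                d = ((iz + 1) * h - pz) / uz
                if d < db:
                    db = d
            elif uz < 0.0:
                d = (iz * h - pz) / uz
                if d < db:
                    db = d
            if db < 0.0:
                db = 0.0

            if mut > 0.0 and s / mut <= db:
                # interaction inside this voxel
                step = s / mut
                px += ux * step
                py += uy * step
                pz += uz * step
                t += step * n_medium * inv_c
                if t > t_max_ps:
                    time_killed_w += w
                    break
                dep = w * mua / mut
                absorbed[ix, iy, iz] += dep
                absorbed_w += dep
                if record_tr:
                    ib = int(t / tr_bin_ps)
                    if ib < nt:
                        tr_field[ix, iy, iz, ib] += dep
                if record_events and dep > 0.0:
                    fy = fluor_yield[ix, iy, iz]
                    if fy > 0.0:
                        ew = dep * fy
                        keep = True
                        if ev_ref_w > 0.0 and ew < ev_ref_w:
                            if np.random.random() < ew / ev_ref_w:
                                ew = ev_ref_w
                            else:
                                keep = False
                        if keep:
                            if n_ev < ev_cap:
                                ev_buf[n_ev, 0] = ix
                                ev_buf[n_ev, 1] = iy
                                ev_buf[n_ev, 2] = iz
                                ev_buf[n_ev, 3] = t
                                ev_buf[n_ev, 4] = ew
                                ev_buf[n_ev, 5] = tag
                                n_ev += 1
                            else:
                                ev_overflow += 1
                w *= 1.0 - mua / mut
                if w <= 0.0:
                    break  # fully deposited (pure absorber)
                cost = _hg_cosine(g_tab[lab])
                phi = 2.0 * math.pi * np.random.random()
                ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
                s = -math.log(np.random.random())
                if w < w_floor:
                    if np.random.random() < roulette_p:
                        roulette_gain_w += w * (1.0 / roulette_p - 1.0)
                        w /= roulette_p
                    else:
                        roulette_killed_w += w
                        break
            else:
                # march to the voxel boundary
                step = db + _EPS
                px += ux * step
                py += uy * step
                pz += uz * step
                t += step * n_medium * inv_c
                if mut > 0.0:
                    s -= db * mut
                    if s < 0.0:
                        s = 0.0
                if t > t_max_ps:
                    time_killed_w += w
                    break
                if pz < 0.0:
                    # top surface: Fresnel
                    ci = abs(uz)
                    r = _fresnel_r(n_medium, n_outside, ci)
                    if np.random.random() < r:
                        pz = -pz
                        if pz <= 0.0:
                            pz = _EPS
                        uz = -uz
                    else:
                        # project the exit point back onto z = 0
                        f = pz / uz  # uz < 0, pz < 0 -> f > 0
                        ex = px - ux * f
                        ey = py - uy * f
                        escaped_top_w += w
                        if record_exits:
                            if n_out < out_cap:
                                out_buf[n_out, 0] = ex
                                out_buf[n_out, 1] = ey
                                out_buf[n_out, 2] = t
                                out_buf[n_out, 3] = w
                                out_buf[n_out, 4] = tag
                                out_buf[n_out, 5] = FACE_TOP
                                n_out += 1
                            else:
                                out_overflow += 1
                        break
                elif pz >= lz:
                    escaped_other_w += w
                    if record_exits:
                        if n_out < out_cap:
                            out_buf[n_out, 0] = px
                            out_buf[n_out, 1] = py
                            out_buf[n_out, 2] = t
                            out_buf[n_out, 3] = w
                            out_buf[n_out, 4] = tag
                            out_buf[n_out, 5] = FACE_BOTTOM
                            n_out += 1
                        else:
                            out_overflow += 1
                    break
                elif mirror_sides and (px < 0.0 or px >= lx or py < 0.0 or py >= ly):
                    if px < 0.0:
                        px = -px + _EPS
                        ux = -ux
                    elif px >= lx:
                        px = 2.0 * lx - px - _EPS
                        ux = -ux
                    if py < 0.0:
                        py = -py + _EPS
                        uy = -uy
                    elif py >= ly:
                        py = 2.0 * ly - py - _EPS
                        uy = -uy
                elif px < 0.0 or px >= lx or py < 0.0 or py >= ly:
                    escaped_other_w += w
                    if record_exits:
                        if n_out < out_cap:
                            out_buf[n_out, 0] = px
                            out_buf[n_out, 1] = py
                            out_buf[n_out, 2] = t
                            out_buf[n_out, 3] = w
                            out_buf[n_out, 4] = tag
                            out_buf[n_out, 5] = FACE_SIDE
                            n_out += 1
                        else:
                            out_overflow += 1
                    break

    return (
        launched_w,
        absorbed_w,
        escaped_top_w,
        escaped_other_w,
        time_killed_w,
        roulette_killed_w,
        roulette_gain_w,
        n_ev,
        n_out,
        ev_overflow,
        out_overflow,
    )
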