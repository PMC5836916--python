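"""Numba-compiled hot loop of the random walk.

Coordinates are kept unwrapped (they feed the center-of-mass accumulators);
compartment membership is evaluated on coordinates wrapped into the primary
cell, which implements the periodic lattice of RBC images.  The per-step cost
must stay minimal, so the kernel uses an inlined xoshiro256++ generator
(seeded via splitmix64) and Marsaglia's polar method for directions instead
of library RNG calls.

Membrane transmission uses P = 2·d_s·κ_i/D_i evaluated at a crossing attempt
with d_s the perpendicular distance from the pre-step position to the
membrane.  For isotropic fixed-length steps of length ds and dt = ds²/(6D)
this scheme transmits an exact flux κ·c across a plane boundary:
∫₀^ds (1 − x/ds)/2 · (2xκ/D) dx / dt = κ, so the intracellular pre-exchange
lifetime equals (V/S)/κ_e = τ_e with no step-size-dependent correction.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np

__all__ = ["walk_kernel"]

_U64 = np.uint64
_MASK = _U64(0xFFFFFFFFFFFFFFFF)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@nb.njit(inline="always")
def _splitmix64(z):
    z = (z + _U64(0x9E3779B97F4A7C15)) & _MASK
    x = z
    x = ((x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _MASK
    x = ((x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)) & _MASK
    return x ^ (x >> _U64(31)), z


@nb.njit(inline="always")
def _rotl(x, k):
    return ((x << _U64(k)) | (x >> _U64(64 - k))) & _MASK


@nb.njit(inline="always")
def _next(s0, s1, s2, s3):
    """xoshiro256++: one uniform double in [0, 1) plus advanced state."""
    result = (_rotl((s0 + s3) & _MASK, 23) + s0) & _MASK
    t = (s1 << _U64(17)) & _MASK
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = _rotl(s3, 45)
    return (result >> _U64(11)) * _INV53, s0, s1, s2, s3


@nb.njit(inline="always")
def _inside(x, y, z, Lxy, Lz, r2, half_h):
    # wrap into [-L/2, L/2) then test the centered cylinder
    xw = x - Lxy * math.floor(x / Lxy + 0.5)
    yw = y - Lxy * math.floor(y / Lxy + 0.5)
    zw = z - Lz * math.floor(z / Lz + 0.5)
    return (xw * xw + yw * yw < r2) and (abs(zw) < half_h)


@nb.njit(inline="always")
def _membrane_distance(x, y, z, Lxy, Lz, radius, half_h):
    """Distance to the nearest RBC membrane over the 27 adjacent images."""
    xw = x - Lxy * math.floor(x / Lxy + 0.5)
    yw = y - Lxy * math.floor(y / Lxy + 0.5)
    zw = z - Lz * math.floor(z / Lz + 0.5)
    best = 1e300
    for ix in range(-1, 2):
        for iy in range(-1, 2):
            for iz in range(-1, 2):
                qx = xw - ix * Lxy
                qy = yw - iy * Lxy
                qz = zw - iz * Lz
                rho = math.sqrt(qx * qx + qy * qy)
                dr = rho - radius
                dz = abs(qz) - half_h
                if dr > 0.0 or dz > 0.0:
                    a = dr if dr > 0.0 else 0.0
                    b = dz if dz > 0.0 else 0.0
                    d = math.sqrt(a * a + b * b)
                else:
                    d = -dr if -dr < -dz else -dz
                if d < best:
                    best = d
    return best


@nb.njit(cache=True)
def walk_kernel(
    seed,
    n_particles,
    n_steps,
    bidx,
    radius,
    half_h,
    Lxy,
    Lz,
    ds_p,
    ds_e,
    kfac_e,
    kfac_p,
    f_init,
):
    """Simulate ``n_particles`` fixed-step random walks of ``n_steps`` steps.

    ``kfac_i`` = 2·κ_i/D_i (µm⁻¹), multiplied by the pre-step membrane
    distance at each crossing attempt to form the transmission probability.
    Returns per-particle cumulative position sums sampled at the step indices
    ``bidx`` (sorted, strictly positive), start/end compartment flags
    (1 = erythrocyte), start/end unwrapped positions, the first-exit step of
    particles started intracellularly (-1 if none) and the number of steps
    spent intracellularly.
    """
    # seed four non-zero state words via splitmix64
    z = _U64(seed) & _MASK
    s0, z = _splitmix64(z)
    s1, z = _splitmix64(z)
    s2, z = _splitmix64(z)
    s3, z = _splitmix64(z)

    n_bounds = bidx.shape[0]
    cum = np.zeros((n_particles, n_bounds, 3))
    start_comp = np.zeros(n_particles, np.int8)
    end_comp = np.zeros(n_particles, np.int8)
    start_pos = np.zeros((n_particles, 3))
    end_pos = np.zeros((n_particles, 3))
    first_exit = np.full(n_particles, -1, np.int64)
    inside_steps = np.zeros(n_particles, np.int64)
    r2 = radius * radius

    for i in range(n_particles):
        # water-concentration-weighted initialization: intracellular with
        # probability f, uniform within the chosen compartment
        u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
        if u < f_init:
            u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
            rho = radius * math.sqrt(u)
            u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
            th = 2.0 * math.pi * u
            x = rho * math.cos(th)
            y = rho * math.sin(th)
            u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
            z_ = (u - 0.5) * 2.0 * half_h
            comp = 1
        else:
            x = y = z_ = 0.0
            comp = 0
            while True:
                u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
                x = (u - 0.5) * Lxy
                u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
                y = (u - 0.5) * Lxy
                u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
                z_ = (u - 0.5) * Lz
                if not _inside(x, y, z_, Lxy, Lz, r2, half_h):
                    break
        start_comp[i] = comp
        start_pos[i, 0] = x
        start_pos[i, 1] = y
        start_pos[i, 2] = z_

        sx = 0.0
        sy = 0.0
        sz = 0.0
        j = 0
        for s in range(1, n_steps + 1):
            # uniform direction on the sphere (Marsaglia polar method)
            aa = 0.0
            bb = 0.0
            ss = 2.0
            while ss >= 1.0 or ss < 1e-14:
                u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
                aa = 2.0 * u - 1.0
                u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
                bb = 2.0 * u - 1.0
                ss = aa * aa + bb * bb
            root = 2.0 * math.sqrt(1.0 - ss)
            ux = aa * root
            uy = bb * root
            uz = 1.0 - 2.0 * ss

            L = ds_e if comp == 1 else ds_p
            nx = x + L * ux
            ny = y + L * uy
            nz = z_ + L * uz
            nc = 1 if _inside(nx, ny, nz, Lxy, Lz, r2, half_h) else 0
            if nc == comp:
                x = nx
                y = ny
                z_ = nz
            else:
                # crossing attempt: transmission uses the pre-step distance
                d_s = _membrane_distance(x, y, z_, Lxy, Lz, radius, half_h)
                kfac = kfac_e if comp == 1 else kfac_p
                P = d_s * kfac
                u, s0, s1, s2, s3 = _next(s0, s1, s2, s3)
                # locate the crossing point on the step segment by bisection
                a = 0.0
                b = 1.0
                for _ in range(30):
                    m = 0.5 * (a + b)
                    mc = (
                        1
                        if _inside(
                            x + m * L * ux, y + m * L * uy, z_ + m * L * uz,
                            Lxy, Lz, r2, half_h,
                        )
                        else 0
                    )
                    if mc == comp:
                        a = m
                    else:
                        b = m
                tc = 0.5 * (a + b)
                cx = x + tc * L * ux
                cy = y + tc * L * uy
                cz = z_ + tc * L * uz
                if u < P:
                    # transmit: continue into the other compartment with the
                    # residual path rescaled to the destination step length
                    Ld = ds_p if comp == 1 else ds_e
                    rem = (1.0 - tc) * Ld
                    x = cx + rem * ux
                    y = cy + rem * uy
                    z_ = cz + rem * uz
                    comp = 1 if _inside(x, y, z_, Lxy, Lz, r2, half_h) else 0
                else:
                    # elastic (specular) reflection at the crossing point
                    xw = cx - Lxy * math.floor(cx / Lxy + 0.5)
                    yw = cy - Lxy * math.floor(cy / Lxy + 0.5)
                    zw = cz - Lz * math.floor(cz / Lz + 0.5)
                    rho = math.sqrt(xw * xw + yw * yw)
                    dr = abs(rho - radius)
                    dz = abs(abs(zw) - half_h)
                    if dr < dz and rho > 1e-12:
                        nxv = xw / rho
                        nyv = yw / rho
                        nzv = 0.0
                    else:
                        nxv = 0.0
                        nyv = 0.0
                        nzv = 1.0 if zw > 0.0 else -1.0
                    dot = ux * nxv + uy * nyv + uz * nzv
                    rux = ux - 2.0 * dot * nxv
                    ruy = uy - 2.0 * dot * nyv
                    ruz = uz - 2.0 * dot * nzv
                    rem = (1.0 - tc) * L
                    fx = cx + rem * rux
                    fy = cy + rem * ruy
                    fz = cz + rem * ruz
                    fc = 1 if _inside(fx, fy, fz, Lxy, Lz, r2, half_h) else 0
                    if fc == comp:
                        x = fx
                        y = fy
                        z_ = fz
                    # else: reflected path slipped through a rim corner —
                    # reject the step (particle stays put, compartment kept)

            if comp == 1:
                inside_steps[i] += 1
            elif first_exit[i] < 0 and start_comp[i] == 1:
                first_exit[i] = s

            sx += x
            sy += y
            sz += z_
            if j < n_bounds and s == bidx[j]:
                cum[i, j, 0] = sx
                cum[i, j, 1] = sy
                cum[i, j, 2] = sz
                j += 1

        end_comp[i] = comp
        end_pos[i, 0] = x
        end_pos[i, 1] = y
        end_pos[i, 2] = z_

    return cum, start_comp, end_comp, start_pos, end_pos, first_exit, inside_steps
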