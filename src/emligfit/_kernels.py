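"""Numba-accelerated inner loops for density stamping and CC gradients.

The numpy implementations in :mod:`densmap` are the reference; these
kernels compute the same quantities atom-by-atom and are used when numba
is importable.  Both paths evaluate the Gaussian separably per axis and
truncate on the sphere ``r <= R``, so results agree to float64 rounding.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(func):
            return func
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def density_and_mask(coords, amps, origin, voxel, dims, sigma, R):
    """Sum of truncated atomic Gaussians plus the support mask."""
    d0, d1, d2 = dims[0], dims[1], dims[2]
    values = np.zeros((d0, d1, d2))
    mask = np.zeros((d0, d1, d2), dtype=np.bool_)
    norm = 1.0 / ((2.0 * math.pi) ** 1.5 * sigma ** 3)
    inv2s2 = 0.5 / (sigma * sigma)
    R2 = R * R
    hw0 = int(math.ceil(R / voxel[0] + 0.5))
    hw1 = int(math.ceil(R / voxel[1] + 0.5))
    hw2 = int(math.ceil(R / voxel[2] + 0.5))
    m = 2 * max(hw0, max(hw1, hw2)) + 1
    gx = np.empty(m)
    gy = np.empty(m)
    gz = np.empty(m)
    dx2 = np.empty(m)
    dy2 = np.empty(m)
    dz2 = np.empty(m)
    for a in range(coords.shape[0]):
        x, y, z = coords[a, 0], coords[a, 1], coords[a, 2]
        b0 = int(math.floor((x - origin[0]) / voxel[0] + 0.5))
        b1 = int(math.floor((y - origin[1]) / voxel[1] + 0.5))
        b2 = int(math.floor((z - origin[2]) / voxel[2] + 0.5))
        i_lo, i_hi = max(b0 - hw0, 0), min(b0 + hw0, d0 - 1)
        j_lo, j_hi = max(b1 - hw1, 0), min(b1 + hw1, d1 - 1)
        k_lo, k_hi = max(b2 - hw2, 0), min(b2 + hw2, d2 - 1)
        if i_lo > i_hi or j_lo > j_hi or k_lo > k_hi:
            continue
        amp = amps[a] * norm
        for i in range(i_lo, i_hi + 1):
            d = origin[0] + i * voxel[0] - x
            dx2[i - i_lo] = d * d
            gx[i - i_lo] = math.exp(-d * d * inv2s2)
        for j in range(j_lo, j_hi + 1):
            d = origin[1] + j * voxel[1] - y
            dy2[j - j_lo] = d * d
            gy[j - j_lo] = math.exp(-d * d * inv2s2)
        for k in range(k_lo, k_hi + 1):
            d = origin[2] + k * voxel[2] - z
            dz2[k - k_lo] = d * d
            gz[k - k_lo] = math.exp(-d * d * inv2s2)
        for i in range(i_lo, i_hi + 1):
            ri = dx2[i - i_lo]
            wi = amp * gx[i - i_lo]
            for j in range(j_lo, j_hi + 1):
                rij = ri + dy2[j - j_lo]
                if rij > R2:
                    continue
                wij = wi * gy[j - j_lo]
                for k in range(k_lo, k_hi + 1):
                    if rij + dz2[k - k_lo] <= R2:
                        values[i, j, k] += wij * gz[k - k_lo]
                        mask[i, j, k] = True
    return values, mask


@njit(cache=True)
def cc_grad_atoms(coords, amps, origin, voxel, sigma, R, dccdf):
    """Per-atom gradient contributions given d(cc)/d(voxel value).

    ``dccdf`` is a full grid of derivatives (zero outside the mask); the
    returned array is d(cc)/d(position) per atom.
    """
    d0, d1, d2 = dccdf.shape
    n = coords.shape[0]
    grad = np.zeros((n, 3))
    norm = 1.0 / ((2.0 * math.pi) ** 1.5 * sigma ** 3)
    inv2s2 = 0.5 / (sigma * sigma)
    inv_s2 = 1.0 / (sigma * sigma)
    R2 = R * R
    hw0 = int(math.ceil(R / voxel[0] + 0.5))
    hw1 = int(math.ceil(R / voxel[1] + 0.5))
    hw2 = int(math.ceil(R / voxel[2] + 0.5))
    m = 2 * max(hw0, max(hw1, hw2)) + 1
    gx = np.empty(m)
    gy = np.empty(m)
    gz = np.empty(m)
    dxv = np.empty(m)
    dyv = np.empty(m)
    dzv = np.empty(m)
    for a in range(n):
        x, y, z = coords[a, 0], coords[a, 1], coords[a, 2]
        b0 = int(math.floor((x - origin[0]) / voxel[0] + 0.5))
        b1 = int(math.floor((y - origin[1]) / voxel[1] + 0.5))
        b2 = int(math.floor((z - origin[2]) / voxel[2] + 0.5))
        i_lo, i_hi = max(b0 - hw0, 0), min(b0 + hw0, d0 - 1)
        j_lo, j_hi = max(b1 - hw1, 0), min(b1 + hw1, d1 - 1)
        k_lo, k_hi = max(b2 - hw2, 0), min(b2 + hw2, d2 - 1)
        if i_lo > i_hi or j_lo > j_hi or k_lo > k_hi:
            continue
        amp = amps[a] * norm
        for i in range(i_lo, i_hi + 1):
            d = origin[0] + i * voxel[0] - x
            dxv[i - i_lo] = d
            gx[i - i_lo] = math.exp(-d * d * inv2s2)
        for j in range(j_lo, j_hi + 1):
            d = origin[1] + j * voxel[1] - y
            dyv[j - j_lo] = d
            gy[j - j_lo] = math.exp(-d * d * inv2s2)
        for k in range(k_lo, k_hi + 1):
            d = origin[2] + k * voxel[2] - z
            dzv[k - k_lo] = d
            gz[k - k_lo] = math.exp(-d * d * inv2s2)
        acc0 = 0.0
        acc1 = 0.0
        acc2 = 0.0
        for i in range(i_lo, i_hi + 1):
            dx = dxv[i - i_lo]
            ri = dx * dx
            wi = amp * gx[i - i_lo]
            for j in range(j_lo, j_hi + 1):
                dy = dyv[j - j_lo]
                rij = ri + dy * dy
                if rij > R2:
                    continue
                wij = wi * gy[j - j_lo]
                for k in range(k_lo, k_hi + 1):
                    dz = dzv[k - k_lo]
                    if rij + dz * dz <= R2:
                        c = dccdf[i, j, k]
                        if c != 0.0:
                            w = wij * gz[k - k_lo] * c
                            acc0 += w * dx
                            acc1 += w * dy
                            acc2 += w * dz
        grad[a, 0] = acc0 * inv_s2
        grad[a, 1] = acc1 * inv_s2
        grad[a, 2] = acc2 * inv_s2
    return grad


@njit(cache=True)
def nonbonded_energy_forces(coords, lj_sigma, lj_eps, charges, pair_code,
                            r_on, r_off, coulomb_k):
    """LJ + Coulomb with a CHARMM-style potential switch between r_on/r_off.

    ``pair_code[i, j]``: 0 = full interaction, 1 = excluded (1-2/1-3),
    2 = scaled 1-4 (factor 0.5).  Returns (energy, forces, min_distance).
    """
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    min_d = 1.0e30
    ron2 = r_on * r_on
    roff2 = r_off * r_off
    denom = (roff2 - ron2) ** 3
    for i in range(n):
        for j in range(i + 1, n):
            code = pair_code[i, j]
            if code == 1:
                continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= roff2:
                continue
            r = math.sqrt(r2)
            if r < min_d:
                min_d = r
            sig = 0.5 * (lj_sigma[i] + lj_sigma[j])
            eps = math.sqrt(lj_eps[i] * lj_eps[j])
            sr6 = (sig * sig / r2) ** 3
            v = 4.0 * eps * (sr6 * sr6 - sr6)
            dv = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r  # dV/dr
            qq = coulomb_k * charges[i] * charges[j]
            if qq != 0.0:
                v += qq / r
                dv += -qq / r2
            if code == 2:
                v *= 0.5
                dv *= 0.5
            if r2 > ron2:
                s = (roff2 - r2) ** 2 * (roff2 + 2.0 * r2 - 3.0 * ron2) / denom
                ds = (12.0 * r * (roff2 - r2) * (ron2 - r2)) / denom  # dS/dr
                dv = dv * s + v * ds
                v = v * s
            energy += v
            f = -dv / r
            fx, fy, fz = f * dx, f * dy, f * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return energy, forces, min_d


@njit(cache=True)
def bonded_energy_forces(coords, bond_idx, bond_r0, bond_k,
                         angle_idx, angle_t0, angle_k):
    """Harmonic bond + angle energy and forces."""
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    for b in range(bond_idx.shape[0]):
        i, j = bond_idx[b, 0], bond_idx[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        energy += bond_k[b] * dr * dr
        if r > 1e-12:
            f = -2.0 * bond_k[b] * dr / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
    for t in range(angle_idx.shape[0]):
        i, j, k = angle_idx[t, 0], angle_idx[t, 1], angle_idx[t, 2]
        ax = coords[i, 0] - coords[j, 0]
        ay = coords[i, 1] - coords[j, 1]
        az = coords[i, 2] - coords[j, 2]
        bx = coords[k, 0] - coords[j, 0]
        by = coords[k, 1] - coords[j, 1]
        bz = coords[k, 2] - coords[j, 2]
        ra = math.sqrt(ax * ax + ay * ay + az * az)
        rb = math.sqrt(bx * bx + by * by + bz * bz)
        if ra < 1e-12 or rb < 1e-12:
            continue
        cosv = (ax * bx + ay * by + az * bz) / (ra * rb)
        if cosv > 1.0:
            cosv = 1.0
        elif cosv < -1.0:
            cosv = -1.0
        theta = math.acos(cosv)
        dt = theta - angle_t0[t]
        energy += angle_k[t] * dt * dt
        sinv = math.sqrt(1.0 - cosv * cosv)
        if sinv < 1e-8:
            continue
        coef = 2.0 * angle_k[t] * dt / sinv
        # d(theta)/d(r_i) etc. via standard angle force expressions
        fia = coef * (cosv * ax / ra - bx / rb) / ra
        fib = coef * (cosv * ay / ra - by / rb) / ra
        fic = coef * (cosv * az / ra - bz / rb) / ra
        fka = coef * (cosv * bx / rb - ax / ra) / rb
        fkb = coef * (cosv * by / rb - ay / ra) / rb
        fkc = coef * (cosv * bz / rb - az / ra) / rb
        forces[i, 0] -= fia
        forces[i, 1] -= fib
        forces[i, 2] -= fic
        forces[k, 0] -= fka
        forces[k, 1] -= fkb
        forces[k, 2] -= fkc
        forces[j, 0] += fia + fka
        forces[j, 1] += fib + fkb
        forces[j, 2] += fic + fkc
    return energy, forces
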