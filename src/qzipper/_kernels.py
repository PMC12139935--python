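"""Numba force kernels for the coarse-grained engine.

Units: nm, kJ/mol, ps, amu.  Periodicity is per-axis (minimum image on
axes flagged periodic).  All kernels accumulate forces in place and
return the energy of their term.
"""
from __future__ import annotations

import numba
import numpy as np

NB = numba.njit(cache=True, fastmath=False)


@NB
def _min_image(d, box, periodic):
    for k in range(3):
        if periodic[k]:
            d[k] -= box[k] * np.rint(d[k] / box[k])
    return d


@NB
def bond_energy_forces(pos, bonds, r0, kb, box, periodic, forces):
    e = 0.0
    d = np.empty(3)
    for n in range(bonds.shape[0]):
        i, j = bonds[n, 0], bonds[n, 1]
        for k in range(3):
            d[k] = pos[j, k] - pos[i, k]
        _min_image(d, box, periodic)
        r = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        dr = r - r0[n]
        e += 0.5 * kb[n] * dr * dr
        fmag = -kb[n] * dr / r
        for k in range(3):
            forces[j, k] += fmag * d[k]
            forces[i, k] -= fmag * d[k]
    return e


@NB
def angle_energy_forces(pos, angles, theta0, ka, box, periodic, forces):
    e = 0.0
    rij = np.empty(3)
    rkj = np.empty(3)
    for n in range(angles.shape[0]):
        i, j, k = angles[n, 0], angles[n, 1], angles[n, 2]
        for m in range(3):
            rij[m] = pos[i, m] - pos[j, m]
            rkj[m] = pos[k, m] - pos[j, m]
        _min_image(rij, box, periodic)
        _min_image(rkj, box, periodic)
        lij = np.sqrt(rij[0] ** 2 + rij[1] ** 2 + rij[2] ** 2)
        lkj = np.sqrt(rkj[0] ** 2 + rkj[1] ** 2 + rkj[2] ** 2)
        cosv = (rij[0] * rkj[0] + rij[1] * rkj[1] + rij[2] * rkj[2]) / (lij * lkj)
        if cosv > 1.0:
            cosv = 1.0
        elif cosv < -1.0:
            cosv = -1.0
        th = np.arccos(cosv)
        dth = th - theta0[n]
        e += 0.5 * ka[n] * dth * dth
        sinv = np.sqrt(1.0 - cosv * cosv)
        if sinv < 1e-8:
            sinv = 1e-8
        coef = ka[n] * dth / sinv
        for m in range(3):
            fi = coef * (rkj[m] / (lij * lkj) - cosv * rij[m] / (lij * lij))
            fk = coef * (rij[m] / (lij * lkj) - cosv * rkj[m] / (lkj * lkj))
            forces[i, m] += fi
            forces[k, m] += fk
            forces[j, m] -= fi + fk
    return e


@NB
def dihedral_energy_forces(pos, dihedrals, phi0, kd, box, periodic, forces):
    """U = kd * (1 - cos(phi - phi0)) per quadruple."""
    e = 0.0
    b1 = np.empty(3)
    b2 = np.empty(3)
    b3 = np.empty(3)
    for n in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[n, 0], dihedrals[n, 1], dihedrals[n, 2], dihedrals[n, 3]
        for m in range(3):
            b1[m] = pos[j, m] - pos[i, m]
            b2[m] = pos[k, m] - pos[j, m]
            b3[m] = pos[l, m] - pos[k, m]
        _min_image(b1, box, periodic)
        _min_image(b2, box, periodic)
        _min_image(b3, box, periodic)
        # n1 = b1 x b2 ; n2 = b2 x b3
        n1x = b1[1] * b2[2] - b1[2] * b2[1]
        n1y = b1[2] * b2[0] - b1[0] * b2[2]
        n1z = b1[0] * b2[1] - b1[1] * b2[0]
        n2x = b2[1] * b3[2] - b2[2] * b3[1]
        n2y = b2[2] * b3[0] - b2[0] * b3[2]
        n2z = b2[0] * b3[1] - b2[1] * b3[0]
        lb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        x = n1x * n2x + n1y * n2y + n1z * n2z
        # m1 = n1 x b2hat ; phi = atan2(m1.n2, n1.n2) (IUPAC convention)
        m1x = (n1y * b2[2] - n1z * b2[1]) / lb2
        m1y = (n1z * b2[0] - n1x * b2[2]) / lb2
        m1z = (n1x * b2[1] - n1y * b2[0]) / lb2
        phi = np.arctan2(m1x * n2x + m1y * n2y + m1z * n2z, x)
        dphi = phi - phi0[n]
        e += kd[n] * (1.0 - np.cos(dphi))
        dV = kd[n] * np.sin(dphi)  # dU/dphi
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        # analytic gradient of phi (Blondel-Karplus form):
        #   dphi/dri = -(|b2|/|n1|^2) n1 ; dphi/drl = (|b2|/|n2|^2) n2
        gi_x = lb2 / n1sq * n1x
        gi_y = lb2 / n1sq * n1y
        gi_z = lb2 / n1sq * n1z
        gl_x = -lb2 / n2sq * n2x
        gl_y = -lb2 / n2sq * n2y
        gl_z = -lb2 / n2sq * n2z
        s1 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (lb2 * lb2)
        s3 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (lb2 * lb2)
        gj_x = -(1.0 + s1) * gi_x + s3 * gl_x
        gj_y = -(1.0 + s1) * gi_y + s3 * gl_y
        gj_z = -(1.0 + s1) * gi_z + s3 * gl_z
        gk_x = s1 * gi_x - (1.0 + s3) * gl_x
        gk_y = s1 * gi_y - (1.0 + s3) * gl_y
        gk_z = s1 * gi_z - (1.0 + s3) * gl_z
        forces[i, 0] -= dV * gi_x
        forces[i, 1] -= dV * gi_y
        forces[i, 2] -= dV * gi_z
        forces[j, 0] -= dV * gj_x
        forces[j, 1] -= dV * gj_y
        forces[j, 2] -= dV * gj_z
        forces[k, 0] -= dV * gk_x
        forces[k, 1] -= dV * gk_y
        forces[k, 2] -= dV * gk_z
        forces[l, 0] -= dV * gl_x
        forces[l, 1] -= dV * gl_y
        forces[l, 2] -= dV * gl_z
    return e


@NB
def native_energy_forces(pos, pairs, eps, sigma, cutoff, box, periodic, forces):
    """Truncated-and-shifted 12-6 Lennard-Jones on explicit native pairs."""
    e = 0.0
    d = np.empty(3)
    rc2 = cutoff * cutoff
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        for k in range(3):
            d[k] = pos[j, k] - pos[i, k]
        _min_image(d, box, periodic)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        if r2 >= rc2:
            continue
        s2 = sigma[n] * sigma[n] / r2
        s6 = s2 * s2 * s2
        sc6 = (sigma[n] * sigma[n] / rc2) ** 3
        e += 4.0 * eps[n] * (s6 * s6 - s6) - 4.0 * eps[n] * (sc6 * sc6 - sc6)
        fr = 24.0 * eps[n] * (2.0 * s6 * s6 - s6) / r2  # (1/r dU/dr) * -1
        for k in range(3):
            forces[j, k] += fr * d[k]
            forces[i, k] -= fr * d[k]
    return e


@NB
def repulsive_energy_forces(pos, pairs, sigma, eps, box, periodic, forces):
    """Excluded volume: U = eps*((sigma/r)^12 - 1) for r < sigma, else 0."""
    e = 0.0
    d = np.empty(3)
    s2cut = sigma * sigma
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        for k in range(3):
            d[k] = pos[j, k] - pos[i, k]
        _min_image(d, box, periodic)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        if r2 >= s2cut:
            continue
        if r2 < 1e-12:
            r2 = 1e-12
        s2 = sigma * sigma / r2
        s6 = s2 * s2 * s2
        e += eps * (s6 * s6 - 1.0)
        fr = 12.0 * eps * s6 * s6 / r2
        for k in range(3):
            forces[j, k] += fr * d[k]
            forces[i, k] -= fr * d[k]
    return e


@NB
def filter_active_pairs(pos, pairs, box, periodic, rlist):
    """Indices of explicit pairs currently within ``rlist`` (nm)."""
    n = pairs.shape[0]
    out = np.empty(n, dtype=np.int64)
    cnt = 0
    d = np.empty(3)
    r2max = rlist * rlist
    for k in range(n):
        i, j = pairs[k, 0], pairs[k, 1]
        for m in range(3):
            d[m] = pos[j, m] - pos[i, m]
        _min_image(d, box, periodic)
        if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] < r2max:
            out[cnt] = k
            cnt += 1
    return out[:cnt].copy()


@NB
def build_pair_list(pos, box, periodic, rlist, excl_keys, n_beads):
    """All-pairs Verlet list (brute-force scan), skipping excluded pairs.

    ``excl_keys`` is a sorted array of i*n_beads+j keys (i<j).
    """
    n = pos.shape[0]
    cap = 64 * n
    out = np.empty((cap, 2), dtype=np.int64)
    cnt = 0
    d = np.empty(3)
    r2max = rlist * rlist
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(3):
                d[k] = pos[j, k] - pos[i, k]
            _min_image(d, box, periodic)
            r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
            if r2 >= r2max:
                continue
            key = i * n_beads + j
            lo = np.searchsorted(excl_keys, key)
            if lo < excl_keys.shape[0] and excl_keys[lo] == key:
                continue
            if cnt >= cap:
                # grow
                newcap = cap * 2
                tmp = np.empty((newcap, 2), dtype=np.int64)
                tmp[:cnt] = out[:cnt]
                out = tmp
                cap = newcap
            out[cnt, 0] = i
            out[cnt, 1] = j
            cnt += 1
    return out[:cnt].copy()
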