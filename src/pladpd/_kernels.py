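"""Numba kernels: cell-list pair forces, bond forces, integrator updates.

All kernels operate on reduced units with the single cutoff r_c = 1. The
random thermostat force uses a counter-based hash RNG keyed on
(seed, step, i, j) with i < j so both members of a pair see the same draw:
random forces are exactly pairwise antisymmetric, momentum is conserved to
summation accuracy, and trajectories are bit-reproducible regardless of
pair iteration order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)
_C4 = np.uint64(0xD6E8FEB86659FD93)
_SQRT3 = 1.7320508075688772
_TWO64 = 18446744073709551616.0


@njit(cache=True, inline="always")
def _pair_noise(seed, step, i, j):
    """Unit-variance symmetric draw for pair (i, j) at a given step.

    splitmix64-style finalizer over a linear combination of the counters;
    returns a uniform variate on [-sqrt(3), sqrt(3)).
    """
    z = (
        np.uint64(seed) * _C1
        + np.uint64(step) * _C2
        + np.uint64(i) * _C3
        + np.uint64(j) * _C4
    )
    z = (z ^ (z >> np.uint64(30))) * _C2
    z = (z ^ (z >> np.uint64(27))) * _C3
    z = z ^ (z >> np.uint64(31))
    u = np.float64(z) / _TWO64
    return (2.0 * u - 1.0) * _SQRT3


@njit(cache=True)
def _cell_index(pos, box, ncell):
    n = pos.shape[0]
    cells = np.empty(n, np.int64)
    for k in range(n):
        cx = np.int64(pos[k, 0] / box[0] * ncell[0])
        cy = np.int64(pos[k, 1] / box[1] * ncell[1])
        cz = np.int64(pos[k, 2] / box[2] * ncell[2])
        if cx >= ncell[0]:
            cx = ncell[0] - 1
        if cy >= ncell[1]:
            cy = ncell[1] - 1
        if cz >= ncell[2]:
            cz = ncell[2] - 1
        cells[k] = (cx * ncell[1] + cy) * ncell[2] + cz
    return cells


@njit(cache=True)
def _counting_sort(cells, ntot):
    n = cells.shape[0]
    count = np.zeros(ntot + 1, np.int64)
    for k in range(n):
        count[cells[k] + 1] += 1
    for c in range(ntot):
        count[c + 1] += count[c]
    order = np.empty(n, np.int64)
    fill = count[:ntot].copy()
    for k in range(n):
        c = cells[k]
        order[fill[c]] = k
        fill[c] += 1
    return count, order


@njit(cache=True)
def _pair_force_terms(a, r, gamma, sigma, ev, inv_sqrt_dt, theta):
    """Scalar force along the unit separation vector for one pair.

    Conservative a(1-r), dissipative -gamma (1-r)^2 (e.v), random
    sigma (1-r) theta / sqrt(dt); all zero at or beyond the cutoff.
    """
    w = 1.0 - r
    return a * w - gamma * w * w * ev + sigma * w * theta * inv_sqrt_dt


@njit(cache=True)
def compute_nonbonded_forces(
    pos, vel, types, amat, box, gamma, sigma, inv_sqrt_dt, seed, step, forces
):
    """Accumulate conservative + dissipative + random pair forces (cell list)."""
    n = pos.shape[0]
    ncell = np.empty(3, np.int64)
    for d in range(3):
        nc = np.int64(box[d])  # cell edge >= 1 = r_c
        ncell[d] = nc if nc >= 3 else 1
    use_cells = ncell[0] >= 3 and ncell[1] >= 3 and ncell[2] >= 3
    if not use_cells:
        for i in range(n):
            for j in range(i + 1, n):
                _accumulate_pair(
                    pos, vel, types, amat, box, gamma, sigma,
                    inv_sqrt_dt, seed, step, i, j, forces,
                )
        return

    ntot = ncell[0] * ncell[1] * ncell[2]
    cells = _cell_index(pos, box, ncell)
    start, order = _counting_sort(cells, ntot)
    for ci in range(ncell[0]):
        for cj in range(ncell[1]):
            for ck in range(ncell[2]):
                c = (ci * ncell[1] + cj) * ncell[2] + ck
                for dx in range(-1, 2):
                    for dy in range(-1, 2):
                        for dz in range(-1, 2):
                            ni = (ci + dx) % ncell[0]
                            nj = (cj + dy) % ncell[1]
                            nk = (ck + dz) % ncell[2]
                            c2 = (ni * ncell[1] + nj) * ncell[2] + nk
                            for p in range(start[c], start[c + 1]):
                                i = order[p]
                                for q in range(start[c2], start[c2 + 1]):
                                    j = order[q]
                                    if j > i:
                                        _accumulate_pair(
                                            pos, vel, types, amat, box,
                                            gamma, sigma, inv_sqrt_dt,
                                            seed, step, i, j, forces,
                                        )


@njit(cache=True, inline="always")
def _accumulate_pair(
    pos, vel, types, amat, box, gamma, sigma, inv_sqrt_dt, seed, step, i, j, forces
):
    rx = pos[i, 0] - pos[j, 0]
    ry = pos[i, 1] - pos[j, 1]
    rz = pos[i, 2] - pos[j, 2]
    rx -= box[0] * np.round(rx / box[0])
    ry -= box[1] * np.round(ry / box[1])
    rz -= box[2] * np.round(rz / box[2])
    r2 = rx * rx + ry * ry + rz * rz
    if r2 >= 1.0 or r2 == 0.0:
        return
    r = np.sqrt(r2)
    ex = rx / r
    ey = ry / r
    ez = rz / r
    ev = (
        ex * (vel[i, 0] - vel[j, 0])
        + ey * (vel[i, 1] - vel[j, 1])
        + ez * (vel[i, 2] - vel[j, 2])
    )
    theta = _pair_noise(seed, step, i, j)
    f = _pair_force_terms(
        amat[types[i], types[j]], r, gamma, sigma, ev, inv_sqrt_dt, theta
    )
    forces[i, 0] += f * ex
    forces[i, 1] += f * ey
    forces[i, 2] += f * ez
    forces[j, 0] -= f * ex
    forces[j, 1] -= f * ey
    forces[j, 2] -= f * ez


@njit(cache=True)
def compute_bond_forces(pos, bonds, k_bond, r0, box, forces):
    """Harmonic springs between bonded beads (minimum image)."""
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        rx -= box[0] * np.round(rx / box[0])
        ry -= box[1] * np.round(ry / box[1])
        rz -= box[2] * np.round(rz / box[2])
        r = np.sqrt(rx * rx + ry * ry + rz * rz)
        if r == 0.0:
            continue
        f = -k_bond * (r - r0) / r
        forces[i, 0] += f * rx
        forces[i, 1] += f * ry
        forces[i, 2] += f * rz
        forces[j, 0] -= f * rx
        forces[j, 1] -= f * ry
        forces[j, 2] -= f * rz


@njit(cache=True)
def integrate_step(
    pos, vel, masses, types, amat, bonds, k_bond, r0, box,
    dt, lam, gamma, sigma, seed, step, forces,
):
    """One modified velocity-Verlet step, in place. Returns new forces."""
    n = pos.shape[0]
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    vpred = np.empty((n, 3))
    for k in range(n):
        inv_m = 1.0 / masses[k]
        for d in range(3):
            v_half = vel[k, d] + 0.5 * dt * forces[k, d] * inv_m
            vpred[k, d] = vel[k, d] + lam * dt * forces[k, d] * inv_m
            pos[k, d] += dt * v_half
            pos[k, d] -= box[d] * np.floor(pos[k, d] / box[d])
            vel[k, d] = v_half
    new_forces = np.zeros((n, 3))
    compute_nonbonded_forces(
        pos, vpred, types, amat, box, gamma, sigma, inv_sqrt_dt,
        seed, step, new_forces,
    )
    compute_bond_forces(pos, bonds, k_bond, r0, box, new_forces)
    for k in range(n):
        inv_m = 1.0 / masses[k]
        for d in range(3):
            vel[k, d] += 0.5 * dt * new_forces[k, d] * inv_m
    return new_forces


@njit(cache=True)
def conservative_energy(pos, types, amat, bonds, k_bond, r0, box):
    """Soft-repulsion + bond potential energy (all pairs; small systems)."""
    n = pos.shape[0]
    u = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            rx -= box[0] * np.round(rx / box[0])
            ry -= box[1] * np.round(ry / box[1])
            rz -= box[2] * np.round(rz / box[2])
            r2 = rx * rx + ry * ry + rz * rz
            if r2 < 1.0:
                w = 1.0 - np.sqrt(r2)
                u += 0.5 * amat[types[i], types[j]] * w * w
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        rx -= box[0] * np.round(rx / box[0])
        ry -= box[1] * np.round(ry / box[1])
        rz -= box[2] * np.round(rz / box[2])
        r = np.sqrt(rx * rx + ry * ry + rz * rz)
        u += 0.5 * k_bond * (r - r0) ** 2
    return u
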