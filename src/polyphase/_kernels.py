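"""Numba-compiled force, neighbor-list and integrator kernels.

Everything here works on bare arrays in the package's internal units
(Å, fs, kcal/mol, Da). The Python-facing wrappers live in ``engine``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: (Å/fs²) per (kcal/mol/Å / Da) — force→acceleration conversion.
FCONV = 4.184e-4


@njit(cache=True, inline="always", error_model="numpy")
def _mi(d: float, box: float) -> float:
    return d - box * np.floor(d / box + 0.5)


@njit(cache=True, inline="always", error_model="numpy")
def _mib(d: float, box: float, ib: float) -> float:
    return d - box * np.floor(d * ib + 0.5)


@njit(cache=True, error_model="numpy")
def bond_energy_forces(pos, box, bonds, ks, r0, f):
    """Harmonic bonds E = k_s (|r| − r0)² (no 1/2 prefactor). Adds to f."""
    e = 0.0
    for n in range(bonds.shape[0]):
        i = bonds[n, 0]
        j = bonds[n, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        e += ks * dr * dr
        if r > 0.0:
            fac = -2.0 * ks * dr / r
            f[i, 0] += fac * dx
            f[i, 1] += fac * dy
            f[i, 2] += fac * dz
            f[j, 0] -= fac * dx
            f[j, 1] -= fac * dy
            f[j, 2] -= fac * dz
    return e


@njit(cache=True, error_model="numpy")
def angle_energy_forces(pos, box, angles, kappa, f):
    """Bending E = κ (1 − cos θ) per consecutive bond pair. Adds to f."""
    e = 0.0
    for n in range(angles.shape[0]):
        i = angles[n, 0]
        j = angles[n, 1]
        k = angles[n, 2]
        b1x = _mi(pos[j, 0] - pos[i, 0], box)
        b1y = _mi(pos[j, 1] - pos[i, 1], box)
        b1z = _mi(pos[j, 2] - pos[i, 2], box)
        b2x = _mi(pos[k, 0] - pos[j, 0], box)
        b2y = _mi(pos[k, 1] - pos[j, 1], box)
        b2z = _mi(pos[k, 2] - pos[j, 2], box)
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        inv12 = 1.0 / (n1 * n2)
        c = (b1x * b2x + b1y * b2y + b1z * b2z) * inv12
        e += kappa * (1.0 - c)
        # dc/db1 = (v − c u)/n1, dc/db2 = (u − c v)/n2 with unit bonds u, v
        ux = b1x / n1
        uy = b1y / n1
        uz = b1z / n1
        vx = b2x / n2
        vy = b2y / n2
        vz = b2z / n2
        g1x = (vx - c * ux) / n1
        g1y = (vy - c * uy) / n1
        g1z = (vz - c * uz) / n1
        g2x = (ux - c * vx) / n2
        g2y = (uy - c * vy) / n2
        g2z = (uz - c * vz) / n2
        # F_i = −κ dc/db1, F_k = +κ dc/db2, F_j balances
        fix = -kappa * g1x
        fiy = -kappa * g1y
        fiz = -kappa * g1z
        fkx = kappa * g2x
        fky = kappa * g2y
        fkz = kappa * g2z
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz
    return e


@njit(cache=True, inline="always", error_model="numpy")
def _lj_accumulate(pos, box, roles, i, j, eps44, rc2_44, sigma2, f):
    """Add LJ energy/force for one pair; returns (energy, overlapped)."""
    dx = _mi(pos[i, 0] - pos[j, 0], box)
    dy = _mi(pos[i, 1] - pos[j, 1], box)
    dz = _mi(pos[i, 2] - pos[j, 2], box)
    r2 = dx * dx + dy * dy + dz * dz
    rc2 = rc2_44[roles[i], roles[j]]
    if r2 >= rc2:
        return 0.0, 0
    eps = eps44[roles[i], roles[j]]
    sr2 = sigma2 / r2
    sr6 = sr2 * sr2 * sr2
    sr12 = sr6 * sr6
    e = 4.0 * eps * (sr12 - sr6)
    fac = 24.0 * eps * (2.0 * sr12 - sr6) / r2
    f[i, 0] += fac * dx
    f[i, 1] += fac * dy
    f[i, 2] += fac * dz
    f[j, 0] -= fac * dx
    f[j, 1] -= fac * dy
    f[j, 2] -= fac * dz
    overlapped = 1 if r2 < 0.09 * sigma2 else 0
    return e, overlapped


@njit(cache=True, error_model="numpy")
def pair_energy_forces_brute(pos, box, roles, chain_id, eps44, rc2_44, sigma2, f):
    """All non-excluded pairs, O(N²). Returns (energy, overlap count)."""
    n = pos.shape[0]
    e = 0.0
    overlaps = 0
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j == i + 1:
                continue  # 1–2 exclusion
            de, ov = _lj_accumulate(pos, box, roles, i, j, eps44, rc2_44, sigma2, f)
            e += de
            overlaps += ov
    return e, overlaps


@njit(cache=True, error_model="numpy")
def build_pairs(pos, box, chain_id, rlist2, pairs):
    """Verlet list: all non-excluded pairs within sqrt(rlist2).

    Fills ``pairs`` (capacity, 2) and returns the number of pairs found
    (which may exceed the capacity — the caller must then grow and retry).
    """
    n = pos.shape[0]
    cap = pairs.shape[0]
    ib = 1.0 / box
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j == i + 1:
                continue
            dx = _mib(pos[i, 0] - pos[j, 0], box, ib)
            dy = _mib(pos[i, 1] - pos[j, 1], box, ib)
            dz = _mib(pos[i, 2] - pos[j, 2], box, ib)
            if dx * dx + dy * dy + dz * dz < rlist2:
                if count < cap:
                    pairs[count, 0] = i
                    pairs[count, 1] = j
                count += 1
    return count


@njit(cache=True, error_model="numpy")
def pair_tables(pairs, n_pairs, roles, eps44, rc2_44, pair_eps, pair_rc2):
    """Cache per-pair LJ depth and squared cutoff for a fresh pair list."""
    for n in range(n_pairs):
        a = roles[pairs[n, 0]]
        b = roles[pairs[n, 1]]
        pair_eps[n] = eps44[a, b]
        pair_rc2[n] = rc2_44[a, b]


@njit(cache=True, error_model="numpy")
def pair_energy_forces_list(pos, box, roles, pairs, n_pairs, eps44, rc2_44, sigma2, f):
    """LJ over a prebuilt pair list. Returns (energy, overlap count)."""
    e = 0.0
    overlaps = 0
    for n in range(n_pairs):
        de, ov = _lj_accumulate(
            pos, box, roles, pairs[n, 0], pairs[n, 1], eps44, rc2_44, sigma2, f
        )
        e += de
        overlaps += ov
    return e, overlaps


@njit(cache=True, fastmath=True, error_model="numpy")
def pair_forces_cached(pos, box, pairs, n_pairs, pair_eps, pair_rc2, sigma2, f):
    """LJ over a pair list with cached per-pair parameters (hot path)."""
    e = 0.0
    ib = 1.0 / box
    for n in range(n_pairs):
        i = pairs[n, 0]
        j = pairs[n, 1]
        dx = _mib(pos[i, 0] - pos[j, 0], box, ib)
        dy = _mib(pos[i, 1] - pos[j, 1], box, ib)
        dz = _mib(pos[i, 2] - pos[j, 2], box, ib)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= pair_rc2[n]:
            continue
        eps = pair_eps[n]
        sr2 = sigma2 / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        e += 4.0 * eps * (sr12 - sr6)
        fac = 24.0 * eps * (2.0 * sr12 - sr6) / r2
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz
    return e


@njit(cache=True, error_model="numpy")
def _max_disp2(pos, ref, box):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = _mi(pos[i, 0] - ref[i, 0], box)
        dy = _mi(pos[i, 1] - ref[i, 1], box)
        dz = _mi(pos[i, 2] - ref[i, 2], box)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m:
            m = d2
    return m


@njit(cache=True, error_model="numpy")
def compute_forces(
    pos, box, roles, chain_id, bonds, angles, ks, r0, kappa,
    eps44, rc2_44, sigma2, use_nlist, pairs, n_pairs, f,
):
    """Total force into f (zeroed here); returns (potential, overlaps)."""
    f[:] = 0.0
    e = bond_energy_forces(pos, box, bonds, ks, r0, f)
    e += angle_energy_forces(pos, box, angles, kappa, f)
    if use_nlist:
        ep, ov = pair_energy_forces_list(
            pos, box, roles, pairs, n_pairs, eps44, rc2_44, sigma2, f
        )
    else:
        ep, ov = pair_energy_forces_brute(
            pos, box, roles, chain_id, eps44, rc2_44, sigma2, f
        )
    return e + ep, ov


@njit(cache=True, error_model="numpy")
def _step_forces(
    pos, box, roles, chain_id, bonds, angles, ks, r0, kappa,
    eps44, rc2_44, sigma2, use_nlist, pairs, n_pairs, pair_eps, pair_rc2, f,
):
    """Force evaluation inside the integrator (cached pair parameters)."""
    f[:] = 0.0
    e = bond_energy_forces(pos, box, bonds, ks, r0, f)
    e += angle_energy_forces(pos, box, angles, kappa, f)
    if use_nlist:
        e += pair_forces_cached(pos, box, pairs, n_pairs, pair_eps, pair_rc2, sigma2, f)
    else:
        ep, _ = pair_energy_forces_brute(
            pos, box, roles, chain_id, eps44, rc2_44, sigma2, f
        )
        e += ep
    return e


@njit(cache=True, error_model="numpy")
def baoab_chunk(
    pos, vel, forces, box, roles, chain_id, bonds, angles,
    ks, r0, kappa, mass, dt, c1, c2, noise,
    eps44, rc2_44, sigma2,
    use_nlist, rlist2, rebuild_disp2, pairs, pair_eps, pair_rc2, ref_pos, nlist_state,
):
    """Advance ``noise.shape[0]`` BAOAB steps in place.

    ``forces`` must hold the forces for the entering positions. ``c1`` is
    exp(−γ dt), ``c2`` = sqrt(kT/m (1 − c1²)) in Å/fs. ``nlist_state[0]``
    carries the current pair count across chunks. The neighbor list is
    checked/rebuilt at step starts, where the state is consistent.

    Returns ``(status, steps_done)`` with status 0 = success, 1 = blow-up
    (non-finite coordinate after ``steps_done`` completed steps), 2 =
    neighbor-list overflow (grow ``pairs`` to ``nlist_state[0]`` and call
    again with the remaining noise rows).
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    half_dt = 0.5 * dt
    bf = half_dt * FCONV / mass  # B-step multiplier
    for s in range(n_steps):
        if use_nlist and _max_disp2(pos, ref_pos, box) > rebuild_disp2:
            cnt = build_pairs(pos, box, chain_id, rlist2, pairs)
            nlist_state[0] = cnt
            if cnt > pairs.shape[0]:
                return 2, s
            pair_tables(pairs, cnt, roles, eps44, rc2_44, pair_eps, pair_rc2)
            ref_pos[:] = pos
        for i in range(n):
            vel[i, 0] += bf * forces[i, 0]
            vel[i, 1] += bf * forces[i, 1]
            vel[i, 2] += bf * forces[i, 2]
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        for i in range(n):
            vel[i, 0] = c1 * vel[i, 0] + c2 * noise[s, i, 0]
            vel[i, 1] = c1 * vel[i, 1] + c2 * noise[s, i, 1]
            vel[i, 2] = c1 * vel[i, 2] + c2 * noise[s, i, 2]
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        _step_forces(
            pos, box, roles, chain_id, bonds, angles, ks, r0, kappa,
            eps44, rc2_44, sigma2, use_nlist, pairs, nlist_state[0],
            pair_eps, pair_rc2, forces,
        )
        for i in range(n):
            vel[i, 0] += bf * forces[i, 0]
            vel[i, 1] += bf * forces[i, 1]
            vel[i, 2] += bf * forces[i, 2]
            if not (
                np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1]) and np.isfinite(pos[i, 2])
            ):
                return 1, s
    return 0, n_steps


@njit(cache=True, error_model="numpy")
def first_bad_bead(pos):
    for i in range(pos.shape[0]):
        if not (
            np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1]) and np.isfinite(pos[i, 2])
        ):
            return i
    return -1
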