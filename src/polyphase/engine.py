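"""Energy terms, forces, and the Langevin (BAOAB) integrator.

The potential has three parts: harmonic stretching ``k_s (r − r0)²``
(literal form, no 1/2 — the effective stiffness is 2 k_s), bending
``κ (1 − cos θ)`` over consecutive bond pairs, and truncated (unshifted)
Lennard-Jones between all non-bonded pairs under cubic periodic
boundaries. Attractive pairs are cut at 2.5 σ, repulsive-only pairs at
2^(1/6) σ. Only directly bonded (1–2) pairs are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Any

import numpy as np

from . import _kernels
from ._kernels import FCONV
from .model import EngineParams, InteractionTable, K_B_KCAL, KCAL_MOL_TO_DA_A2_FS2
from .state import Frame, SystemState, Trajectory

__all__ = [
    "ForceField",
    "build_forcefield",
    "stretch_energy",
    "bend_energy",
    "pair_energy",
    "forces",
    "potential_energy",
    "kinetic_energy",
    "kinetic_temperature",
    "langevin_step",
    "run",
    "BlowUpError",
]

logger = logging.getLogger(__name__)


class BlowUpError(RuntimeError):
    """Raised when the integrator produces a non-finite coordinate."""


@dataclass
class ForceField:
    """Resolved per-system force-field tables (internal kcal/mol units)."""

    bonds: np.ndarray  # (n_bonds, 2) int
    angles: np.ndarray  # (n_angles, 3) int
    eps_kcal: np.ndarray  # (4, 4) pair depths, kcal/mol
    rcut2: np.ndarray  # (4, 4) squared pair cutoffs, Å²
    params: EngineParams
    table: InteractionTable

    @property
    def max_cutoff(self) -> float:
        return float(np.sqrt(self.rcut2.max()))


def build_forcefield(
    roles: np.ndarray, chain_id: np.ndarray, table: InteractionTable, params: EngineParams
) -> ForceField:
    """Resolve bonds, angles and pair tables for a fixed topology."""
    chain_id = np.asarray(chain_id)
    n = chain_id.shape[0]
    bonds = [
        (i, i + 1) for i in range(n - 1) if chain_id[i] == chain_id[i + 1]
    ]
    angles = [
        (i, i + 1, i + 2)
        for i in range(n - 2)
        if chain_id[i] == chain_id[i + 1] == chain_id[i + 2]
    ]
    rcut2 = np.where(
        table.attractive, params.r_cut_attr**2, params.r_cut_rep**2
    ).astype(np.float64)
    return ForceField(
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.array(angles, dtype=np.int64).reshape(-1, 3),
        eps_kcal=np.ascontiguousarray(table.eps_kcal(), dtype=np.float64),
        rcut2=np.ascontiguousarray(rcut2),
        params=params,
        table=table,
    )


def stretch_energy(state: SystemState, ff: ForceField) -> float:
    """Total harmonic bond energy, kcal/mol."""
    f = np.zeros_like(state.positions)
    return float(
        _kernels.bond_energy_forces(
            state.positions, state.box_edge, ff.bonds, ff.params.k_s, ff.params.r0, f
        )
    )


def bend_energy(state: SystemState, ff: ForceField) -> float:
    """Total bending energy, kcal/mol."""
    if len(ff.angles):
        i, j, k = ff.angles[:, 0], ff.angles[:, 1], ff.angles[:, 2]
        box = state.box_edge
        b1 = state.positions[j] - state.positions[i]
        b2 = state.positions[k] - state.positions[j]
        b1 -= box * np.round(b1 / box)
        b2 -= box * np.round(b2 / box)
        if np.any(np.linalg.norm(b1, axis=1) == 0) or np.any(
            np.linalg.norm(b2, axis=1) == 0
        ):
            raise ValueError("zero-length bond: bending angle undefined")
    f = np.zeros_like(state.positions)
    return float(
        _kernels.angle_energy_forces(
            state.positions, state.box_edge, ff.angles, ff.params.kappa, f
        )
    )


def pair_energy(state: SystemState, ff: ForceField) -> float:
    """Total truncated LJ energy over non-excluded pairs, kcal/mol."""
    f = np.zeros_like(state.positions)
    e, overlaps = _kernels.pair_energy_forces_brute(
        state.positions,
        state.box_edge,
        state.roles,
        state.chain_id,
        ff.eps_kcal,
        ff.rcut2,
        ff.params.sigma**2,
        f,
    )
    if overlaps:
        logger.warning("pair_energy: %d bead pairs overlap closer than 0.3 sigma", overlaps)
    return float(e)


def stretch_forces(state: SystemState, ff: ForceField) -> tuple[np.ndarray, float]:
    """Bond-term force and energy only."""
    f = np.zeros_like(state.positions)
    e = _kernels.bond_energy_forces(
        state.positions, state.box_edge, ff.bonds, ff.params.k_s, ff.params.r0, f
    )
    return f, float(e)


def bend_forces(state: SystemState, ff: ForceField) -> tuple[np.ndarray, float]:
    """Bending-term force and energy only."""
    f = np.zeros_like(state.positions)
    e = _kernels.angle_energy_forces(
        state.positions, state.box_edge, ff.angles, ff.params.kappa, f
    )
    return f, float(e)


def pair_forces(state: SystemState, ff: ForceField) -> tuple[np.ndarray, float]:
    """Non-bonded LJ force and energy only."""
    f = np.zeros_like(state.positions)
    e, _ = _kernels.pair_energy_forces_brute(
        state.positions, state.box_edge, state.roles, state.chain_id,
        ff.eps_kcal, ff.rcut2, ff.params.sigma**2, f,
    )
    return f, float(e)


def forces(state: SystemState, ff: ForceField) -> tuple[np.ndarray, float]:
    """Total force (kcal/mol/Å per bead) and potential energy (kcal/mol)."""
    f = np.zeros_like(state.positions)
    e, _ = _kernels.compute_forces(
        state.positions,
        state.box_edge,
        state.roles,
        state.chain_id,
        ff.bonds,
        ff.angles,
        ff.params.k_s,
        ff.params.r0,
        ff.params.kappa,
        ff.eps_kcal,
        ff.rcut2,
        ff.params.sigma**2,
        False,
        np.empty((0, 2), dtype=np.int64),
        0,
        f,
    )
    return f, float(e)


def potential_energy(state: SystemState, ff: ForceField) -> float:
    return forces(state, ff)[1]


def kinetic_energy(state: SystemState, params: EngineParams) -> float:
    """Kinetic energy, kcal/mol."""
    ke_da = 0.5 * params.bead_mass * float(np.sum(state.velocities**2))
    return ke_da / KCAL_MOL_TO_DA_A2_FS2


def kinetic_temperature(state: SystemState, params: EngineParams) -> float:
    """Instantaneous kinetic temperature, K (3N degrees of freedom)."""
    ke = kinetic_energy(state, params)
    return 2.0 * ke / (3.0 * state.n_beads * K_B_KCAL)


def _ou_coefficients(params: EngineParams, temperature: float | None = None) -> tuple[float, float]:
    T = params.T if temperature is None else temperature
    c1 = math.exp(-params.dt / params.damping_time)
    kT_da = K_B_KCAL * T * KCAL_MOL_TO_DA_A2_FS2
    c2 = math.sqrt(kT_da / params.bead_mass * (1.0 - c1 * c1))
    return c1, c2


@dataclass
class _NeighborList:
    pairs: np.ndarray
    pair_eps: np.ndarray
    pair_rc2: np.ndarray
    ref_pos: np.ndarray
    count: np.ndarray  # shape (1,), carried into the kernel
    rlist2: float
    rebuild_disp2: float


def _make_nlist(state: SystemState, ff: ForceField, skin: float) -> _NeighborList:
    rlist = ff.max_cutoff + skin
    cap = max(4096, state.n_beads * 64)
    pairs = np.empty((cap, 2), dtype=np.int64)
    while True:
        cnt = _kernels.build_pairs(
            state.positions, state.box_edge, state.chain_id, rlist**2, pairs
        )
        if cnt <= pairs.shape[0]:
            break
        pairs = np.empty((2 * cnt, 2), dtype=np.int64)
    pair_eps = np.empty(pairs.shape[0])
    pair_rc2 = np.empty(pairs.shape[0])
    _kernels.pair_tables(pairs, cnt, state.roles, ff.eps_kcal, ff.rcut2, pair_eps, pair_rc2)
    # staleness check runs at step starts, so leave slack for one step's move
    trigger = max(0.3 * skin, 0.5 * skin - 0.15)
    return _NeighborList(
        pairs=pairs,
        pair_eps=pair_eps,
        pair_rc2=pair_rc2,
        ref_pos=state.positions.copy(),
        count=np.array([cnt], dtype=np.int64),
        rlist2=rlist**2,
        rebuild_disp2=trigger**2,
    )


def langevin_step(
    state: SystemState,
    ff: ForceField,
    params: EngineParams,
    rng: np.random.Generator,
    temperature: float | None = None,
) -> SystemState:
    """One BAOAB Langevin step; returns a new state (input untouched)."""
    new = state.copy()
    _advance(new, ff, params, rng, n_steps=1, use_nlist=False, nlist=None,
             temperature=temperature)
    return new


def _advance(
    state: SystemState,
    ff: ForceField,
    params: EngineParams,
    rng: np.random.Generator,
    n_steps: int,
    use_nlist: bool,
    nlist: _NeighborList | None,
    temperature: float | None = None,
    chunk: int = 2000,
) -> None:
    """Advance ``state`` in place by ``n_steps`` BAOAB steps."""
    c1, c2 = _ou_coefficients(params, temperature)
    f, _ = forces(state, ff)
    if use_nlist and nlist is None:
        nlist = _make_nlist(state, ff, skin=0.5 * params.sigma)
    dummy_pairs = np.empty((0, 2), dtype=np.int64)
    done = 0
    while done < n_steps:
        take = min(chunk, n_steps - done)
        noise = rng.standard_normal((take, state.n_beads, 3))
        offset = 0
        while offset < take:
            status, steps_done = _kernels.baoab_chunk(
                state.positions,
                state.velocities,
                f,
                state.box_edge,
                state.roles,
                state.chain_id,
                ff.bonds,
                ff.angles,
                ff.params.k_s,
                ff.params.r0,
                ff.params.kappa,
                params.bead_mass,
                params.dt,
                c1,
                c2,
                noise[offset:],
                ff.eps_kcal,
                ff.rcut2,
                ff.params.sigma**2,
                use_nlist,
                nlist.rlist2 if nlist else 0.0,
                nlist.rebuild_disp2 if nlist else 0.0,
                nlist.pairs if nlist else dummy_pairs,
                nlist.pair_eps if nlist else np.empty(0),
                nlist.pair_rc2 if nlist else np.empty(0),
                nlist.ref_pos if nlist else state.positions,
                nlist.count if nlist else np.zeros(1, dtype=np.int64),
            )
            offset += steps_done
            state.time += steps_done * params.dt
            if status == 1:
                idx = _kernels.first_bad_bead(state.positions)
                raise BlowUpError(
                    f"non-finite coordinate on bead {idx} after step "
                    f"{done + offset} (dt too large or overlapping start?)"
                )
            if status == 2:  # grow the pair list and continue where we left off
                needed = int(nlist.count[0])
                nlist.pairs = np.empty((2 * needed, 2), dtype=np.int64)
                nlist.pair_eps = np.empty(2 * needed)
                nlist.pair_rc2 = np.empty(2 * needed)
                cnt = _kernels.build_pairs(
                    state.positions, state.box_edge, state.chain_id,
                    nlist.rlist2, nlist.pairs,
                )
                nlist.count[0] = cnt
                _kernels.pair_tables(
                    nlist.pairs, cnt, state.roles, ff.eps_kcal, ff.rcut2,
                    nlist.pair_eps, nlist.pair_rc2,
                )
                nlist.ref_pos[:] = state.positions
        done += take


def run(
    state: SystemState,
    ff: ForceField,
    params: EngineParams,
    n_steps: int,
    report_every: int,
    rng: np.random.Generator,
    use_neighbor_list: bool = True,
    temperature: float | None = None,
    store_velocities: bool = False,
    metadata: dict[str, Any] | None = None,
) -> tuple[Trajectory, SystemState]:
    """Integrate ``n_steps`` steps, reporting every ``report_every`` steps.

    Returns the trajectory (frames at steps 0, report_every, 2·report_every,
    … — ``floor(n_steps / report_every) + 1`` frames when ``report_every``
    divides ``n_steps``) and the final state. Frame coordinates are wrapped
    into the box.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if report_every < 1:
        raise ValueError("report_every must be >= 1")

    work = state.copy()
    nlist = _make_nlist(work, ff, skin=0.5 * params.sigma) if use_neighbor_list else None

    meta = {
        "engine_params": vars(params).copy(),
        "eps_sp": ff.table.eps_sp,
        "eps_ns": ff.table.eps_ns,
        "T_ref": ff.table.T_ref,
        "n_steps": n_steps,
        "report_every": report_every,
    }
    if metadata:
        meta.update(metadata)

    traj = Trajectory(
        roles=work.roles.copy(),
        chain_id=work.chain_id.copy(),
        box_edge=work.box_edge,
        metadata=meta,
    )
    wrapped = work.wrapped()
    traj.append(
        Frame(
            time=work.time,
            positions=wrapped.positions,
            velocities=work.velocities.copy() if store_velocities else None,
        )
    )

    done = 0
    while done < n_steps:
        take = min(report_every, n_steps - done)
        _advance(
            work, ff, params, rng, n_steps=take,
            use_nlist=use_neighbor_list, nlist=nlist, temperature=temperature,
        )
        done += take
        if done % report_every == 0 or done == n_steps:
            wrapped_pos = np.mod(work.positions, work.box_edge)
            traj.append(
                Frame(
                    time=work.time,
                    positions=wrapped_pos,
                    velocities=work.velocities.copy() if store_velocities else None,
                )
            )
    return traj, work
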