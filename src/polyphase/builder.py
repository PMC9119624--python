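"""Synthetic-data stage: role sequences, boxes, initial configurations and
deterministic fixture trajectories with known contact histories.

All randomness flows through :class:`numpy.random.Generator` instances
seeded from the spec, so identical seeds give bitwise-identical builds.
"""

from __future__ import annotations

import math

import numpy as np

from .model import (
    KCAL_MOL_TO_DA_A2_FS2,
    N_AVOGADRO,
    BeadRole,
    ChainSpec,
    EngineParams,
    SystemSpec,
)
from .state import Frame, SystemState, Trajectory

__all__ = [
    "default_chain_roles",
    "three_bead_roles",
    "box_from_concentration",
    "concentration_from_box",
    "default_system_spec",
    "build_system",
    "build_contact_dimer",
    "make_fixture_trajectory",
]


def default_chain_roles(M: int = 80, patch_len: int = 7) -> tuple[BeadRole, ...]:
    """Two-bead chain layout: a contiguous central specific patch.

    The patch starts at ``floor((M - patch_len) / 2)``; with M=80 and a
    7-bead patch the non-core beads split 36 before / 37 after.
    """
    if patch_len > M:
        raise ValueError(f"patch_len ({patch_len}) cannot exceed chain length ({M})")
    if patch_len < 0 or M < 1:
        raise ValueError("M must be >= 1 and patch_len >= 0")
    start = (M - patch_len) // 2
    roles = [BeadRole.NONSPECIFIC] * M
    for i in range(start, start + patch_len):
        roles[i] = BeadRole.SPECIFIC
    return tuple(roles)


def _round_half_away(x: float) -> int:
    """Round half away from zero (x >= 0 here)."""
    return int(math.floor(x + 0.5))


def three_bead_roles(
    M: int, patch_len: int, n_frac: float, seed: int
) -> tuple[BeadRole, ...]:
    """Three-bead chain layout with a tunable attractive non-core fraction.

    ``n_frac`` is the percentage of the M − patch_len non-core beads that
    are attractive (nonspecific); the rest are inert. The attractive
    positions are chosen uniformly at random with ``seed``.
    """
    if not (0.0 <= n_frac <= 100.0):
        raise ValueError(f"n_frac must lie in [0, 100], got {n_frac}")
    base = list(default_chain_roles(M, patch_len))
    non_core = [i for i, r in enumerate(base) if r != BeadRole.SPECIFIC]
    n_attract = _round_half_away(n_frac / 100.0 * len(non_core))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(non_core), size=n_attract, replace=False).tolist())
    for k, i in enumerate(non_core):
        base[i] = BeadRole.NONSPECIFIC if k in chosen else BeadRole.INERT
    return tuple(base)


def box_from_concentration(n_chains: int, conc: float) -> float:
    """Cubic box edge (Å) realizing ``conc`` mol/L for ``n_chains`` chains.

    1 L = 1e27 Å³, so edge³ = n / (N_A · conc · 1e−27 Å⁻³).
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if conc <= 0:
        raise ValueError(f"concentration must be positive, got {conc}")
    return (n_chains / (N_AVOGADRO * conc * 1e-27)) ** (1.0 / 3.0)


def concentration_from_box(n_chains: int, box_edge: float) -> float:
    """Inverse of :func:`box_from_concentration` (mol/L)."""
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    return n_chains / (N_AVOGADRO * box_edge**3 * 1e-27)


def default_system_spec(
    n_chains: int = 30,
    seed: int = 0,
    concentration: float = 200e-6,
    box_edge: float | None = None,
    M: int = 80,
    patch_len: int = 7,
) -> SystemSpec:
    """Homogeneous two-bead system spec (dimer for n_chains=2, etc.)."""
    chain = ChainSpec(roles=default_chain_roles(M, patch_len))
    kwargs = (
        {"box_edge": box_edge}
        if box_edge is not None
        else {"concentration": concentration}
    )
    return SystemSpec(chains=((chain, n_chains),), seed=seed, **kwargs)


def _maxwell_velocities(
    rng: np.random.Generator, n: int, T: float, mass: float
) -> np.ndarray:
    from .model import K_B_KCAL

    kT = K_B_KCAL * T * KCAL_MOL_TO_DA_A2_FS2  # Da Å²/fs²
    return rng.standard_normal((n, 3)) * math.sqrt(kT / mass)


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def build_system(
    spec: SystemSpec,
    params: EngineParams,
    max_chain_retries: int = 200,
    max_step_retries: int = 60,
) -> SystemState:
    """Place chains as self-avoiding random walks and draw thermal velocities.

    Bond lengths are exactly ``r0``; no non-bonded pair starts closer than
    σ (overlap-free start keeps the big timestep stable). Identical specs
    and seeds give bitwise-identical states.
    """
    box = spec.resolve_box_edge()
    if box <= 2.0 * params.r_cut_attr:
        raise ValueError(
            f"box edge {box:.1f} Å must exceed twice the attractive cutoff "
            f"({2 * params.r_cut_attr:.1f} Å)"
        )
    rng = np.random.default_rng(spec.seed)

    chain_lengths: list[int] = []
    roles: list[BeadRole] = []
    for chain_spec, count in spec.chains:
        for _ in range(count):
            chain_lengths.append(chain_spec.length)
            roles.extend(chain_spec.roles)

    n_total = sum(chain_lengths)
    positions = np.empty((n_total, 3))
    placed = 0  # beads committed so far
    sigma2 = params.sigma**2

    for chain_idx, M in enumerate(chain_lengths):
        for attempt in range(max_chain_retries):
            chain_pos = np.empty((M, 3))
            chain_pos[0] = rng.uniform(0.0, box, size=3)
            ok = True
            if placed and _too_close(chain_pos[0], positions[:placed], box, sigma2):
                continue
            for i in range(1, M):
                for _ in range(max_step_retries):
                    step = rng.standard_normal(3)
                    step *= params.r0 / np.linalg.norm(step)
                    cand = chain_pos[i - 1] + step
                    # check against committed beads and this chain so far
                    # (bonded predecessor exempt from the σ criterion)
                    if placed and _too_close(cand, positions[:placed], box, sigma2):
                        continue
                    if i >= 2 and _too_close(cand, chain_pos[: i - 1], box, sigma2):
                        continue
                    chain_pos[i] = cand
                    break
                else:
                    ok = False
                    break
            if ok:
                positions[placed : placed + M] = chain_pos
                placed += M
                break
        else:
            raise RuntimeError(
                f"failed to place chain {chain_idx} after {max_chain_retries} "
                "retries; try a larger box or lower concentration"
            )

    positions = np.mod(positions, box)
    velocities = _maxwell_velocities(rng, n_total, params.T, params.bead_mass)
    chain_id = np.repeat(np.arange(len(chain_lengths)), chain_lengths)
    return SystemState(
        positions=positions,
        velocities=velocities,
        roles=np.array([int(r) for r in roles]),
        chain_id=chain_id,
        box_edge=box,
        time=0.0,
    )


def _too_close(point: np.ndarray, others: np.ndarray, box: float, sigma2: float) -> bool:
    d = _min_image(others - point, box)
    return bool(np.any(np.einsum("ij,ij->i", d, d) < sigma2))


def _straight_chain(M: int, r0: float, origin: np.ndarray) -> np.ndarray:
    pos = np.zeros((M, 3))
    pos[:, 0] = np.arange(M) * r0
    return pos + origin


def build_contact_dimer(
    chain_spec: ChainSpec,
    params: EngineParams,
    box_edge: float,
    seed: int,
    target_gap: float | None = None,
    arrangement: str = "coils",
    rod_offset_beads: int = 10,
) -> SystemState:
    """Two chains already in non-specific contact.

    ``arrangement="coils"`` builds two self-avoiding coils and rigidly
    translates the second chain along the closest-pair line until the
    minimum inter-chain bead distance sits at ``target_gap`` (default
    2^(1/6) σ, the pair minimum). ``arrangement="rods"`` places two
    straight parallel rods ``target_gap`` apart, the second shifted
    ``rod_offset_beads`` bonds along the axis so the specific patches
    start separated — a reproducible "non-specifically zipped dimer"
    start. Desk-scale kinetics runs use these states so
    dissociation/maturation can be observed without waiting for a
    diffusive encounter.
    """
    if target_gap is None:
        target_gap = 2.0 ** (1.0 / 6.0) * params.sigma
    if not params.sigma <= target_gap < params.r_cut_attr:
        raise ValueError("target_gap must lie in [sigma, attractive cutoff)")
    M = chain_spec.length

    if arrangement == "rods":
        extent = (M - 1 + rod_offset_beads) * params.r0
        if box_edge <= 2.0 * extent:
            raise ValueError(
                "rod arrangement needs box_edge > twice the rod span "
                f"({2 * extent:.0f} Å) to avoid periodic self-images"
            )
        rng = np.random.default_rng(seed)
        center = np.full(3, box_edge / 2.0)
        origin = center - np.array([(M - 1) * params.r0 / 2.0, 0.0, 0.0])
        pos1 = _straight_chain(M, params.r0, origin)
        pos2 = _straight_chain(
            M, params.r0, origin + np.array([rod_offset_beads * params.r0, target_gap, 0.0])
        )
        return SystemState(
            positions=np.mod(np.vstack([pos1, pos2]), box_edge),
            velocities=_maxwell_velocities(rng, 2 * M, params.T, params.bead_mass),
            roles=np.array([int(r) for r in chain_spec.roles] * 2),
            chain_id=np.repeat([0, 1], M),
            box_edge=box_edge,
            time=0.0,
        )
    if arrangement == "blob":
        # a compact, pre-formed non-specific dimer: zip two rods, then
        # briefly equilibrate at strong non-specific attraction so the
        # pair collapses into a bound blob with the patches still apart —
        # the "non-specific dimer" state kinetics measurements start from
        from .engine import build_forcefield, run as engine_run
        from .model import BeadRole as _BR, build_interaction_table

        big_box = 4.0 * (M + rod_offset_beads) * params.r0
        state = build_contact_dimer(
            chain_spec, params, big_box, seed, target_gap, "rods", rod_offset_beads
        )
        table = build_interaction_table(1.2, 1.0, T_ref=params.T)
        # patch-patch repulsive during preparation so the blob forms with
        # the specific patches still apart (no pre-formed specific contacts)
        table.attractive[_BR.SPECIFIC, _BR.SPECIFIC] = False
        ff = build_forcefield(state.roles, state.chain_id, table, params)
        rng = np.random.default_rng(seed + 7_777)
        pos = None
        for _ in range(12):  # equilibrate in blocks until the pair is compact
            _, state = engine_run(state, ff, params, 60_000, 60_000, rng)
            pos = state.positions.copy()
            pos = pos[0] + _min_image(pos - pos[0], big_box)
            pos += box_edge / 2.0 - pos.mean(axis=0)
            span = pos.max(axis=0) - pos.min(axis=0)
            if np.all(span < 0.9 * box_edge):
                break
        else:
            raise ValueError(
                f"equilibrated dimer spans {span.max():.0f} Å and does not fit "
                f"the requested box ({box_edge:.0f} Å)"
            )
        return SystemState(
            positions=np.mod(pos, box_edge),
            velocities=state.velocities.copy(),
            roles=state.roles.copy(),
            chain_id=state.chain_id.copy(),
            box_edge=box_edge,
            time=0.0,
        )
    if arrangement != "coils":
        raise ValueError(f"unknown arrangement: {arrangement!r}")

    spec = SystemSpec(chains=((chain_spec, 2),), seed=seed, box_edge=box_edge)
    state = build_system(spec, params)
    c2 = slice(M, 2 * M)

    for _ in range(200):
        d = _min_image(state.positions[c2, None, :] - state.positions[None, :M, :], box_edge)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        jmin, imin = np.unravel_index(np.argmin(dist), dist.shape)
        d_min = dist[jmin, imin]
        if abs(d_min - target_gap) < 0.05 * params.sigma:
            break
        # move chain 2 along the closest-pair line, capped per iteration
        direction = d[jmin, imin] / d_min
        step = np.clip(d_min - target_gap, -0.5 * params.sigma, 2.0 * params.sigma)
        state.positions[c2] -= step * direction
    else:
        raise RuntimeError("could not bring chains into contact without overlap")
    state.positions = np.mod(state.positions, box_edge)
    return state


def _specific_contact_count(
    xs1: np.ndarray, xs2: np.ndarray, dy: float, cutoff: float
) -> int:
    """Inter-chain specific pairs for straight chains offset by dy laterally."""
    dx = xs1[:, None] - xs2[None, :]
    return int(np.count_nonzero(dx * dx + dy * dy < cutoff * cutoff))


def make_fixture_trajectory(
    script: list[tuple[int, str, int]],
    chain_spec: ChainSpec | None = None,
    params: EngineParams | None = None,
    frame_dt: float = 30.0,
) -> Trajectory:
    """Deterministic two-chain trajectory realizing a scripted contact history.

    Each script entry is ``(n_frames, mode, n_specific_contacts)`` with mode
    ``"apart"`` (no inter-chain contacts at all) or ``"contact"`` (chains
    within the 2.5 σ cutoff with exactly the requested number of
    specific–specific inter-chain pairs). Chains are rigid straight rods
    translated whole; a segment whose contact count cannot be realized by
    any whole-bead shift raises ``ValueError``.
    """
    if params is None:
        params = EngineParams()
    if chain_spec is None:
        chain_spec = ChainSpec(roles=default_chain_roles())
    M = chain_spec.length
    cutoff = params.r_cut_attr
    r0 = params.r0
    extent = (M - 1) * r0
    # big enough that no scripted placement ever folds through the boundary
    box = 4.0 * extent + 8.0 * cutoff

    roles_one = np.array([int(r) for r in chain_spec.roles])
    spec_x = np.flatnonzero(roles_one == int(BeadRole.SPECIFIC)) * r0

    base = np.full(3, 2.0 * cutoff)
    pos1 = _straight_chain(M, r0, base)

    # candidate lateral separations inside the cutoff; shift is in whole bonds
    dy_candidates = [0.96 * cutoff, 0.8 * cutoff, 0.5 * cutoff, 0.25 * cutoff]

    def placement_for(mode: str, n_sp: int) -> np.ndarray:
        if mode == "apart":
            return base + np.array([0.0, extent + 3.0 * cutoff, 0.0])
        if mode != "contact":
            raise ValueError(f"unknown fixture mode: {mode!r}")
        for dy in dy_candidates:
            for shift in range(0, M):
                if _specific_contact_count(spec_x, spec_x + shift * r0, dy, cutoff) == n_sp:
                    return base + np.array([shift * r0, dy, 0.0])
        raise ValueError(
            f"cannot realize {n_sp} specific contacts with rigid straight "
            "chains for this chain layout"
        )

    frames: list[Frame] = []
    t = 0.0
    for n_frames, mode, n_sp in script:
        if n_frames < 1:
            raise ValueError("script durations must be positive frame counts")
        origin2 = placement_for(mode, int(n_sp))
        pos2 = _straight_chain(M, r0, origin2)
        stacked = np.vstack([pos1, pos2])
        for _ in range(n_frames):
            frames.append(Frame(time=t, positions=stacked.copy()))
            t += frame_dt
    return Trajectory(
        roles=np.concatenate([roles_one, roles_one]),
        chain_id=np.repeat([0, 1], M),
        box_edge=box,
        frames=frames,
        metadata={"fixture_script": [list(s) for s in script], "frame_dt": frame_dt},
    )
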