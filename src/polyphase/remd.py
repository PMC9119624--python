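"""Parallel tempering over the Langevin engine.

Replicas hold fixed temperatures; neighbor-pair configuration swaps are
attempted at a fixed interval with Metropolis/Boltzmann acceptance,
alternating even/odd pairs. Velocities are rescaled by sqrt(T_new/T_old)
when a swap is accepted. The potential is temperature-independent — only
the thermostat temperature varies across the ladder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import ForceField, _advance, _make_nlist, potential_energy
from .model import EngineParams, K_B_KCAL
from .state import Frame, SystemState, Trajectory

__all__ = [
    "ReplicaLadder",
    "SwapAttempt",
    "FreeEnergyProfile",
    "temperature_ladder",
    "swap_probability",
    "run_remd",
    "free_energy_profile",
]


@dataclass(frozen=True)
class ReplicaLadder:
    """Strictly increasing temperature ladder with per-replica seeds."""

    temperatures: tuple[float, ...]
    swap_interval: float  # fs
    seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(t2 <= t1 for t1, t2 in zip(self.temperatures, self.temperatures[1:])):
            raise ValueError("ladder temperatures must be strictly increasing")
        if len(self.seeds) != len(self.temperatures):
            raise ValueError("one seed per replica required")
        if self.swap_interval <= 0:
            raise ValueError("swap_interval must be positive")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)


def temperature_ladder(
    T_min: float,
    dT: float,
    T_max: float,
    swap_interval: float = 0.5e6,  # fs (0.5 ns)
    seed: int = 0,
) -> ReplicaLadder:
    """Uniform ladder T_min, T_min+dT, …, T_max.

    The range must be an integer multiple of the spacing (to 1e-9).
    """
    if T_max < T_min:
        raise ValueError("T_max must be >= T_min")
    if dT <= 0:
        raise ValueError("dT must be positive")
    span = T_max - T_min
    n_int = round(span / dT)
    if abs(span - n_int * dT) > 1e-9:
        raise ValueError(
            f"(T_max - T_min) = {span} is not an integer multiple of dT = {dT}"
        )
    temps = tuple(T_min + k * dT for k in range(n_int + 1))
    rng = np.random.default_rng(seed)
    seeds = tuple(int(s) for s in rng.integers(0, 2**63 - 1, size=len(temps)))
    return ReplicaLadder(temperatures=temps, swap_interval=swap_interval, seeds=seeds)


def swap_probability(E_i: float, E_j: float, T_i: float, T_j: float) -> float:
    """Metropolis acceptance min(1, exp[(β_i − β_j)(E_i − E_j)])."""
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    beta_i = 1.0 / (K_B_KCAL * T_i)
    beta_j = 1.0 / (K_B_KCAL * T_j)
    arg = (beta_i - beta_j) * (E_i - E_j)
    if arg >= 0:
        return 1.0
    return math.exp(arg)


@dataclass(frozen=True)
class SwapAttempt:
    """One logged swap attempt between ladder slots ``i`` and ``i+1``."""

    time: float  # fs
    pair: tuple[int, int]
    E_i: float  # kcal/mol
    E_j: float
    probability: float
    accepted: bool


def run_remd(
    initial_states: list[SystemState],
    ff: ForceField,
    params: EngineParams,
    ladder: ReplicaLadder,
    n_steps: int,
    report_every: int,
    swap_seed: int = 0,
) -> tuple[list[Trajectory], list[SwapAttempt]]:
    """Run replica exchange; returns per-temperature trajectories + swap log.

    ``initial_states`` holds one state per ladder slot (same topology).
    The swap interval must be a multiple of ``report_every × dt``, and
    frames are recorded per temperature slot (configurations flow through
    slots as swaps are accepted).
    """
    n_rep = ladder.n_replicas
    if len(initial_states) != n_rep:
        raise ValueError("need one initial state per replica")
    steps_per_swap = ladder.swap_interval / params.dt
    if abs(steps_per_swap - round(steps_per_swap)) > 1e-9:
        raise ValueError("swap_interval must be a whole number of timesteps")
    steps_per_swap = int(round(steps_per_swap))
    if steps_per_swap % report_every != 0:
        raise ValueError("swap_interval must be a multiple of report_every * dt")

    states = [s.copy() for s in initial_states]
    rngs = [np.random.default_rng(seed) for seed in ladder.seeds]
    swap_rng = np.random.default_rng(swap_seed)
    nlists = [_make_nlist(s, ff, skin=0.5 * params.sigma) for s in states]

    trajs = [
        Trajectory(
            roles=s.roles.copy(),
            chain_id=s.chain_id.copy(),
            box_edge=s.box_edge,
            metadata={
                "temperature": T,
                "replica_seed": seed,
                "swap_interval": ladder.swap_interval,
            },
        )
        for s, T, seed in zip(states, ladder.temperatures, ladder.seeds)
    ]
    for traj, s in zip(trajs, states):
        traj.append(Frame(time=s.time, positions=np.mod(s.positions, s.box_edge)))

    log: list[SwapAttempt] = []
    parity = 0
    done = 0
    while done < n_steps:
        block = min(steps_per_swap, n_steps - done)
        for r in range(n_rep):
            sub_done = 0
            while sub_done < block:
                take = min(report_every, block - sub_done)
                _advance(
                    states[r], ff, params, rngs[r], n_steps=take,
                    use_nlist=True, nlist=nlists[r],
                    temperature=ladder.temperatures[r],
                )
                sub_done += take
                trajs[r].append(
                    Frame(
                        time=states[r].time,
                        positions=np.mod(states[r].positions, states[r].box_edge),
                    )
                )
        done += block
        if done >= n_steps:
            break
        energies = [potential_energy(s, ff) for s in states]
        for i in range(parity, n_rep - 1, 2):
            j = i + 1
            p = swap_probability(
                energies[i], energies[j], ladder.temperatures[i], ladder.temperatures[j]
            )
            accepted = bool(swap_rng.random() < p)
            log.append(
                SwapAttempt(
                    time=states[i].time,
                    pair=(i, j),
                    E_i=energies[i],
                    E_j=energies[j],
                    probability=p,
                    accepted=accepted,
                )
            )
            if accepted:
                _exchange(states, nlists, energies, i, j, ladder.temperatures, ff, params)
        parity = 1 - parity
    return trajs, log


def _exchange(states, nlists, energies, i, j, temperatures, ff, params) -> None:
    """Swap configurations between slots i and j, rescaling velocities."""
    si, sj = states[i], states[j]
    si.positions, sj.positions = sj.positions, si.positions
    scale_i = math.sqrt(temperatures[i] / temperatures[j])
    vi, vj = si.velocities, sj.velocities
    si.velocities = vj * scale_i
    sj.velocities = vi / scale_i
    energies[i], energies[j] = energies[j], energies[i]
    # the slots' neighbor lists describe the old configurations — rebuild
    nlists[i] = _make_nlist(si, ff, skin=0.5 * params.sigma)
    nlists[j] = _make_nlist(sj, ff, skin=0.5 * params.sigma)


def run_remd_from_spec(
    system_spec,
    table,
    params: EngineParams,
    ladder: ReplicaLadder,
    n_steps: int,
    report_every: int,
    swap_seed: int = 0,
) -> tuple[list[Trajectory], list[SwapAttempt]]:
    """Build one configuration from a system spec and replicate it across
    the ladder (all replicas start from the same seeded build)."""
    from .builder import build_system
    from .engine import build_forcefield

    state = build_system(system_spec, params)
    ff = build_forcefield(state.roles, state.chain_id, table, params)
    states = [state.copy() for _ in range(ladder.n_replicas)]
    return run_remd(states, ff, params, ladder, n_steps, report_every, swap_seed)


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Binned F(order parameter) in k_B T at a statistical temperature.

    Bins never visited carry NaN; the profile is shifted so min(F) = 0.
    """

    bin_centers: np.ndarray
    F: np.ndarray  # k_B T
    statistical_temperature: float
    bin_width: float

    def __post_init__(self) -> None:
        finite = self.F[np.isfinite(self.F)]
        if finite.size == 0:
            raise ValueError("free energy profile has no occupied bins")


def free_energy_profile(
    order_values: np.ndarray,
    bin_width: float = 0.1,
    statistical_temperature: float = 309.0,
) -> FreeEnergyProfile:
    """F(b) = −ln P(b) in k_B T over a histogram of order-parameter values."""
    values = np.asarray(order_values, dtype=float)
    if values.size == 0:
        raise ValueError("free_energy_profile needs at least one sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    prob = counts / counts.sum()
    with np.errstate(divide="ignore"):
        F = -np.log(prob)
    F[counts == 0] = np.nan
    F -= np.nanmin(F)
    return FreeEnergyProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        F=F,
        statistical_temperature=statistical_temperature,
        bin_width=bin_width,
    )
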