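"""Order parameters: contacts, clusters, radii of gyration, radial shell
profiles, and dwell/maturation kinetics.

Contacts are inter-chain bead pairs within 2.5 σ (minimum-image
distance). A pair of two specific beads is a specific contact; any other
inter-chain pair within the cutoff that involves at least one
(alt-)nonspecific bead is a non-specific contact. Per-bead values divide
specific pairs by the number of specific beads and non-specific pairs by
the total bead count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import BeadRole
from .state import Trajectory

__all__ = [
    "ContactCounts",
    "ContactSeries",
    "ShellProfile",
    "KineticsResult",
    "contact_pairs",
    "contact_counts",
    "raw_contact_counts",
    "cluster_chains",
    "unwrap_clusters",
    "rg_specific",
    "shell_profile",
    "contact_series",
    "dwell_times",
    "maturation_times",
]

_NS_ROLES = (int(BeadRole.NONSPECIFIC), int(BeadRole.ALT_NONSPECIFIC))


def contact_pairs(
    positions: np.ndarray, chain_id: np.ndarray, box: float, cutoff: float
) -> np.ndarray:
    """Inter-chain bead pairs with minimum-image distance < cutoff.

    Positions must be wrapped into [0, box). Returns an (n_pairs, 2) int
    array (i < j).
    """
    chain_id = np.asarray(chain_id)
    pos = np.mod(np.asarray(positions, dtype=float), box)
    # cKDTree requires points strictly inside the box for boxsize queries
    pos[pos >= box] = 0.0
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    inter = chain_id[pairs[:, 0]] != chain_id[pairs[:, 1]]
    return pairs[inter]


@dataclass(frozen=True)
class ContactCounts:
    """Raw pair counts and their per-bead normalizations for one frame."""

    n_sp_pairs: int
    n_ns_pairs: int
    n_sp_per_bead: float
    n_ns_per_bead: float


def raw_contact_counts(
    positions: np.ndarray,
    roles: np.ndarray,
    chain_id: np.ndarray,
    box: float,
    cutoff: float,
) -> ContactCounts:
    """Classify inter-chain contacts in one frame."""
    pairs = contact_pairs(positions, chain_id, box, cutoff)
    roles = np.asarray(roles)
    if pairs.size:
        ra, rb = roles[pairs[:, 0]], roles[pairs[:, 1]]
        is_sp = (ra == int(BeadRole.SPECIFIC)) & (rb == int(BeadRole.SPECIFIC))
        is_ns = ~is_sp & (np.isin(ra, _NS_ROLES) | np.isin(rb, _NS_ROLES))
        n_sp, n_ns = int(is_sp.sum()), int(is_ns.sum())
    else:
        n_sp = n_ns = 0
    n_specific_beads = int(np.count_nonzero(roles == int(BeadRole.SPECIFIC)))
    n_total = roles.shape[0]
    return ContactCounts(
        n_sp_pairs=n_sp,
        n_ns_pairs=n_ns,
        n_sp_per_bead=n_sp / n_specific_beads if n_specific_beads else 0.0,
        n_ns_per_bead=n_ns / n_total,
    )


def contact_counts(
    positions: np.ndarray,
    roles: np.ndarray,
    chain_id: np.ndarray,
    box: float,
    cutoff: float,
) -> tuple[float, float]:
    """Per-bead (N_ns, N_sp) for one frame."""
    c = raw_contact_counts(positions, roles, chain_id, box, cutoff)
    return c.n_ns_per_bead, c.n_sp_per_bead


def cluster_chains(
    positions: np.ndarray, chain_id: np.ndarray, box: float, cutoff: float
) -> tuple[np.ndarray, int]:
    """Chain cluster labels and the largest cluster size N_lc.

    Two chains are connected iff any inter-chain bead pair is within the
    cutoff; clusters are connected components of that graph.
    """
    chain_id = np.asarray(chain_id)
    n_chains = int(np.max(chain_id)) + 1
    pairs = contact_pairs(positions, chain_id, box, cutoff)
    if pairs.size:
        ca, cb = chain_id[pairs[:, 0]], chain_id[pairs[:, 1]]
        adj = sparse.coo_matrix(
            (np.ones(len(ca)), (ca, cb)), shape=(n_chains, n_chains)
        )
        n_comp, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n_chains)
    counts = np.bincount(labels)
    return labels, int(counts.max())


def unwrap_clusters(
    positions: np.ndarray, chain_id: np.ndarray, box: float, cutoff: float
) -> np.ndarray:
    """Make every cluster spatially coherent across periodic boundaries.

    Each chain is first unwrapped internally by walking its bond path with
    minimum-image steps; chains are then attached to their cluster via the
    minimum-image displacement of a linking contact pair.
    """
    chain_id = np.asarray(chain_id)
    pos = np.mod(np.asarray(positions, dtype=float), box)
    out = np.empty_like(pos)
    n_chains = int(np.max(chain_id)) + 1
    chain_beads = [np.flatnonzero(chain_id == c) for c in range(n_chains)]

    for beads in chain_beads:
        out[beads[0]] = pos[beads[0]]
        steps = pos[beads[1:]] - pos[beads[:-1]]
        steps -= box * np.round(steps / box)
        out[beads[1:]] = out[beads[0]] + np.cumsum(steps, axis=0)

    pairs = contact_pairs(pos, chain_id, box, cutoff)
    links: dict[int, list[tuple[int, int, int]]] = {c: [] for c in range(n_chains)}
    for i, j in pairs:
        ci, cj = int(chain_id[i]), int(chain_id[j])
        links[ci].append((cj, int(i), int(j)))
        links[cj].append((ci, int(j), int(i)))

    placed = np.zeros(n_chains, dtype=bool)
    for seed in range(n_chains):
        if placed[seed]:
            continue
        placed[seed] = True
        queue = [seed]
        while queue:
            a = queue.pop()
            for b, ia, ib in links[a]:
                if placed[b]:
                    continue
                d = pos[ib] - pos[ia]
                d -= box * np.round(d / box)
                shift = (out[ia] + d) - out[ib]
                out[chain_beads[b]] += shift
                placed[b] = True
                queue.append(b)
    return out


def rg_specific(
    positions: np.ndarray,
    roles: np.ndarray,
    chain_id: np.ndarray,
    box: float,
    cutoff: float,
) -> tuple[float, float]:
    """(Rg_red, Rg_norm) for one frame.

    Rg_red is the radius of gyration of all specific beads (computed on
    cluster-unwrapped coordinates); Rg_norm divides it by the frame's N_lc.
    """
    roles = np.asarray(roles)
    spec = roles == int(BeadRole.SPECIFIC)
    if not spec.any():
        raise ValueError("rg_specific needs at least one specific bead")
    unwrapped = unwrap_clusters(positions, chain_id, box, cutoff)
    pts = unwrapped[spec]
    centroid = pts.mean(axis=0)
    rg = math.sqrt(float(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    _, n_lc = cluster_chains(positions, chain_id, box, cutoff)
    return rg, rg / n_lc


@dataclass(frozen=True)
class ShellProfile:
    """Radial shell statistics of specific beads around a center."""

    r_inner: np.ndarray  # Å
    r_outer: np.ndarray  # Å
    fraction: np.ndarray  # specific beads in shell / normalization count
    phi: np.ndarray  # number density of specific beads per Å³
    center: np.ndarray
    normalization: str  # "largest_cluster" or "system"


def shell_profile(
    positions: np.ndarray,
    roles: np.ndarray,
    chain_id: np.ndarray,
    box: float,
    cutoff: float,
    shell_width: float = 3.0,
) -> ShellProfile:
    """Fraction and number density of specific beads in 3 Å radial shells.

    When a multimer exists (N_lc ≥ 2) the center is the largest cluster's
    center of mass and fractions are normalized by the specific beads in
    that cluster; otherwise the box center is used and fractions are
    normalized by all specific beads in the system.
    """
    roles = np.asarray(roles)
    chain_id = np.asarray(chain_id)
    spec = roles == int(BeadRole.SPECIFIC)
    labels, n_lc = cluster_chains(positions, chain_id, box, cutoff)
    if n_lc >= 2:
        largest = int(np.argmax(np.bincount(labels)))
        in_cluster = np.isin(chain_id, np.flatnonzero(labels == largest))
        unwrapped = unwrap_clusters(positions, chain_id, box, cutoff)
        center = unwrapped[in_cluster].mean(axis=0)
        sel = spec & in_cluster
        d = np.linalg.norm(unwrapped[sel] - center, axis=1)
        norm = "largest_cluster"
    else:
        center = np.full(3, box / 2.0)
        sel = spec
        disp = np.mod(np.asarray(positions, dtype=float), box)[sel] - center
        disp -= box * np.round(disp / box)
        d = np.linalg.norm(disp, axis=1)
        norm = "system"
    denom = int(sel.sum())
    if denom == 0:
        raise ValueError("shell_profile needs at least one specific bead")
    n_shells = max(1, int(math.ceil((d.max() + 1e-12) / shell_width)) if d.size else 1)
    edges = np.arange(n_shells + 1) * shell_width
    counts, _ = np.histogram(d, bins=edges)
    volumes = (4.0 / 3.0) * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return ShellProfile(
        r_inner=edges[:-1],
        r_outer=edges[1:],
        fraction=counts / denom,
        phi=counts / volumes,
        center=center,
        normalization=norm,
    )


@dataclass
class ContactSeries:
    """Per-frame order parameters for a trajectory."""

    times: np.ndarray  # fs
    n_ns: np.ndarray  # non-specific contacts per bead
    n_sp: np.ndarray  # specific contacts per bead
    n_sp_pairs: np.ndarray  # raw inter-chain specific pair counts
    n_lc: np.ndarray  # chains in largest cluster
    rg_red: np.ndarray  # Å
    rg_norm: np.ndarray  # Å (rg_red / n_lc)


def contact_series(traj: Trajectory, cutoff: float) -> ContactSeries:
    """Evaluate all per-frame order parameters along a trajectory."""
    n = traj.n_frames
    times = np.empty(n)
    n_ns = np.empty(n)
    n_sp = np.empty(n)
    n_sp_pairs = np.empty(n, dtype=np.int64)
    n_lc = np.empty(n, dtype=np.int64)
    rg_red = np.empty(n)
    rg_norm = np.empty(n)
    for k, fr in enumerate(traj.frames):
        times[k] = fr.time
        c = raw_contact_counts(fr.positions, traj.roles, traj.chain_id, traj.box_edge, cutoff)
        n_ns[k] = c.n_ns_per_bead
        n_sp[k] = c.n_sp_per_bead
        n_sp_pairs[k] = c.n_sp_pairs
        rg, rgn = rg_specific(fr.positions, traj.roles, traj.chain_id, traj.box_edge, cutoff)
        _, lc = cluster_chains(fr.positions, traj.chain_id, traj.box_edge, cutoff)
        n_lc[k] = lc
        rg_red[k] = rg
        rg_norm[k] = rgn
    return ContactSeries(
        times=times, n_ns=n_ns, n_sp=n_sp, n_sp_pairs=n_sp_pairs,
        n_lc=n_lc, rg_red=rg_red, rg_norm=rg_norm,
    )


@dataclass
class KineticsResult:
    """Dwell/maturation intervals in fs with censoring flags."""

    intervals: list[float] = field(default_factory=list)
    censored: list[bool] = field(default_factory=list)

    @property
    def mean(self) -> float:
        """Mean over closed and censored intervals; NaN if empty."""
        if not self.intervals:
            return float("nan")
        return float(np.mean(self.intervals))


def _in_contact_flags(traj: Trajectory, cutoff: float) -> np.ndarray:
    flags = np.empty(traj.n_frames, dtype=bool)
    for k, fr in enumerate(traj.frames):
        pairs = contact_pairs(fr.positions, traj.chain_id, traj.box_edge, cutoff)
        flags[k] = pairs.shape[0] > 0
    return flags


def dwell_times(traj: Trajectory, cutoff: float) -> KineticsResult:
    """Dwell intervals of a two-chain trajectory.

    A frame is "in contact" when any inter-chain bead pair is within the
    cutoff. Each maximal run of consecutive in-contact frames is one
    interval (run length × frame spacing); a run open at the trajectory
    end is flagged censored but still contributes its censored length to
    the mean.
    """
    if traj.n_chains != 2:
        raise ValueError("dwell_times is defined for two-chain trajectories")
    flags = _in_contact_flags(traj, cutoff)
    times = traj.times
    frame_dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    result = KineticsResult()
    run = 0
    for k, flag in enumerate(flags):
        if flag:
            run += 1
        elif run:
            result.intervals.append(run * frame_dt)
            result.censored.append(False)
            run = 0
    if run:
        result.intervals.append(run * frame_dt)
        result.censored.append(True)
    return result


def maturation_times(
    traj: Trajectory,
    cutoff: float,
    n_sp_threshold: int = 10,
    stability_window: float = 20e6,  # fs (20 ns)
) -> KineticsResult:
    """Maturation time of a two-chain trajectory.

    The clock starts at the first in-contact frame with fewer than
    ``n_sp_threshold`` raw inter-chain specific contacts (if the first
    contact already sustains ≥ threshold, maturation time is 0). It stops
    at the first frame whose specific-contact count reaches the threshold
    and stays there for every frame spanning the next ``stability_window``
    fs. Trajectories that never mature report the full trajectory length,
    flagged censored.
    """
    if traj.n_chains != 2:
        raise ValueError("maturation_times is defined for two-chain trajectories")
    flags = _in_contact_flags(traj, cutoff)
    times = traj.times
    n = traj.n_frames
    nsp = np.empty(n, dtype=np.int64)
    for k, fr in enumerate(traj.frames):
        nsp[k] = raw_contact_counts(
            fr.positions, traj.roles, traj.chain_id, traj.box_edge, cutoff
        ).n_sp_pairs

    result = KineticsResult()
    in_contact = np.flatnonzero(flags)
    if in_contact.size == 0:
        result.intervals.append(traj.duration)
        result.censored.append(True)
        return result
    first_contact = int(in_contact[0])
    below = np.flatnonzero(flags & (nsp < n_sp_threshold))
    start = int(below[0]) if below.size else first_contact

    def stable_from(k: int) -> bool:
        horizon = times[k] + stability_window
        for m in range(k, n):
            if times[m] > horizon:
                return True
            if nsp[m] < n_sp_threshold:
                return False
        return True  # stayed mature to the end of the trajectory

    for k in range(first_contact, n):
        if nsp[k] >= n_sp_threshold and stable_from(k):
            result.intervals.append(float(max(0.0, times[k] - times[start])))
            result.censored.append(False)
            return result
    result.intervals.append(traj.duration)
    result.censored.append(True)
    return result
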