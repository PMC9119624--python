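"""Trajectory and table readers/writers.

Three trajectory dialects: XYZ with role-coded element symbols, a
LAMMPS-dump-style text format, and an internal ``.npz`` container. The
text formats are self-describing enough to round-trip topology (roles,
chain ids, box) — XYZ carries chain ids in the comment line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import BeadRole
from .state import Frame, Trajectory

__all__ = [
    "TrajectoryFormatError",
    "write_trajectory",
    "read_trajectory",
    "write_xyz",
    "read_xyz",
    "write_lammps_dump",
    "read_lammps_dump",
    "write_npz",
    "read_npz",
    "write_contact_series",
    "write_swap_log",
    "write_free_energy_profile",
]

#: role <-> element symbol mapping used in XYZ output
_ROLE_SYMBOLS = {
    int(BeadRole.SPECIFIC): "R",
    int(BeadRole.NONSPECIFIC): "B",
    int(BeadRole.INERT): "K",
    int(BeadRole.ALT_NONSPECIFIC): "G",
}
_SYMBOL_ROLES = {v: k for k, v in _ROLE_SYMBOLS.items()}


class TrajectoryFormatError(ValueError):
    """Malformed or truncated trajectory file."""


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "auto") -> None:
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "xyz":
        write_xyz(traj, path)
    elif fmt == "lammps_dump":
        write_lammps_dump(traj, path)
    elif fmt == "internal":
        write_npz(traj, path)
    else:
        raise ValueError(f"unknown trajectory format: {fmt!r}")


def read_trajectory(path: str | Path, format: str = "auto") -> Trajectory:
    """Read a trajectory, validating frame and bead counts against headers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "lammps_dump":
        return read_lammps_dump(path)
    if fmt == "internal":
        return read_npz(path)
    raise ValueError(f"unknown trajectory format: {fmt!r}")


def _resolve_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        return "xyz"
    if suffix in (".dump", ".lammpstrj"):
        return "lammps_dump"
    if suffix == ".npz":
        return "internal"
    raise ValueError(f"cannot infer trajectory format from suffix {suffix!r}")


# ---------------------------------------------------------------- XYZ


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{traj.n_beads}\n")
            chain_str = ",".join(str(c) for c in traj.chain_id)
            fh.write(f"time={fr.time} box={traj.box_edge} chains={chain_str}\n")
            for sym_idx in range(traj.n_beads):
                x, y, z = fr.positions[sym_idx]
                fh.write(
                    f"{_ROLE_SYMBOLS[int(traj.roles[sym_idx])]} "
                    f"{x:.6f} {y:.6f} {z:.6f}\n"
                )


def read_xyz(path: str | Path) -> Trajectory:
    frames: list[Frame] = []
    roles = chain_id = None
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    frame_idx = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"frame {frame_idx}: expected atom count, got {lines[k]!r}"
            ) from None
        if k + 1 + n >= len(lines) + 1 and k + 1 + n > len(lines):
            raise TrajectoryFormatError(f"frame {frame_idx}: truncated ({n} atoms expected)")
        header = dict(
            item.split("=", 1) for item in lines[k + 1].split() if "=" in item
        )
        time = float(header.get("time", frame_idx))
        box = float(header.get("box", box if box is not None else 0.0))
        frame_roles = np.empty(n, dtype=np.int64)
        pos = np.empty((n, 3))
        for a in range(n):
            parts = lines[k + 2 + a].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"frame {frame_idx}: malformed atom line {a}: {lines[k + 2 + a]!r}"
                )
            sym = parts[0]
            if sym not in _SYMBOL_ROLES:
                raise TrajectoryFormatError(
                    f"frame {frame_idx}: unknown role symbol {sym!r}"
                )
            frame_roles[a] = _SYMBOL_ROLES[sym]
            pos[a] = [float(p) for p in parts[1:4]]
        if roles is None:
            roles = frame_roles
            if "chains" in header:
                chain_id = np.array(
                    [int(c) for c in header["chains"].split(",")], dtype=np.int64
                )
            else:
                chain_id = np.zeros(n, dtype=np.int64)
        elif not np.array_equal(roles, frame_roles):
            raise TrajectoryFormatError(f"frame {frame_idx}: topology changed mid-file")
        frames.append(Frame(time=time, positions=pos))
        k += 2 + n
        frame_idx += 1
    if roles is None:
        raise TrajectoryFormatError("empty XYZ file")
    if box is None or box <= 0:
        box = float(np.max([f.positions.max() for f in frames])) + 1.0
    return Trajectory(roles=roles, chain_id=chain_id, box_edge=box, frames=frames)


# ------------------------------------------------------- LAMMPS dump


def write_lammps_dump(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{fr.time:.6f}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{traj.n_beads}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0.0 {traj.box_edge:.6f}\n")
            fh.write("ITEM: ATOMS id type chain x y z\n")
            for i in range(traj.n_beads):
                x, y, z = fr.positions[i]
                fh.write(
                    f"{i + 1} {int(traj.roles[i]) + 1} {int(traj.chain_id[i])} "
                    f"{x:.6f} {y:.6f} {z:.6f}\n"
                )


def read_lammps_dump(path: str | Path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames: list[Frame] = []
    roles = chain_id = None
    box = None
    k = 0
    frame_idx = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        if lines[k].strip() != "ITEM: TIMESTEP":
            raise TrajectoryFormatError(
                f"frame {frame_idx}: expected 'ITEM: TIMESTEP', got {lines[k]!r}"
            )
        time = float(lines[k + 1])
        if lines[k + 2].strip() != "ITEM: NUMBER OF ATOMS":
            raise TrajectoryFormatError(
                f"frame {frame_idx}: missing 'ITEM: NUMBER OF ATOMS' header"
            )
        n = int(lines[k + 3])
        if not lines[k + 4].startswith("ITEM: BOX BOUNDS"):
            raise TrajectoryFormatError(f"frame {frame_idx}: missing box bounds")
        lo, hi = (float(v) for v in lines[k + 5].split()[:2])
        box = hi - lo
        if not lines[k + 8].startswith("ITEM: ATOMS"):
            raise TrajectoryFormatError(f"frame {frame_idx}: missing 'ITEM: ATOMS' header")
        columns = lines[k + 8].split()[2:]
        col = {name: idx for idx, name in enumerate(columns)}
        for req in ("id", "type", "x", "y", "z"):
            if req not in col:
                raise TrajectoryFormatError(
                    f"frame {frame_idx}: dump lacks required column {req!r}"
                )
        if k + 9 + n > len(lines):
            raise TrajectoryFormatError(f"frame {frame_idx}: truncated atom block")
        pos = np.empty((n, 3))
        frame_roles = np.empty(n, dtype=np.int64)
        frame_chain = np.zeros(n, dtype=np.int64)
        for a in range(n):
            parts = lines[k + 9 + a].split()
            idx = int(parts[col["id"]]) - 1
            frame_roles[idx] = int(parts[col["type"]]) - 1
            if "chain" in col:
                frame_chain[idx] = int(parts[col["chain"]])
            pos[idx] = [
                float(parts[col["x"]]),
                float(parts[col["y"]]),
                float(parts[col["z"]]),
            ]
        if roles is None:
            roles, chain_id = frame_roles, frame_chain
        frames.append(Frame(time=time, positions=pos))
        k += 9 + n
        frame_idx += 1
    if roles is None:
        raise TrajectoryFormatError("empty dump file")
    return Trajectory(roles=roles, chain_id=chain_id, box_edge=box, frames=frames)


# ---------------------------------------------------------- internal


def write_npz(traj: Trajectory, path: str | Path) -> None:
    positions = np.stack([f.positions for f in traj.frames])
    times = traj.times
    has_vel = all(f.velocities is not None for f in traj.frames) and traj.frames
    payload = {
        "positions": positions,
        "times": times,
        "roles": traj.roles,
        "chain_id": traj.chain_id,
        "box_edge": np.array(traj.box_edge),
        "metadata": np.array(json.dumps(traj.metadata, default=str)),
    }
    if has_vel:
        payload["velocities"] = np.stack([f.velocities for f in traj.frames])
    np.savez_compressed(path, **payload)


def read_npz(path: str | Path) -> Trajectory:
    with np.load(path, allow_pickle=False) as data:
        times = data["times"]
        positions = data["positions"]
        velocities = data["velocities"] if "velocities" in data else None
        frames = [
            Frame(
                time=float(times[k]),
                positions=positions[k],
                velocities=velocities[k] if velocities is not None else None,
            )
            for k in range(len(times))
        ]
        return Trajectory(
            roles=data["roles"],
            chain_id=data["chain_id"],
            box_edge=float(data["box_edge"]),
            frames=frames,
            metadata=json.loads(str(data["metadata"])),
        )


# -------------------------------------------------- LAMMPS data file


def write_lammps_data(state, path: str | Path) -> None:
    """Initial configuration as a LAMMPS-data-style text file
    (atoms with molecule ids and types, bonds along each chain)."""
    n = state.n_beads
    chain_id = state.chain_id
    bonds = [
        (i, i + 1) for i in range(n - 1) if chain_id[i] == chain_id[i + 1]
    ]
    with open(path, "w") as fh:
        fh.write("# polyphase initial configuration\n\n")
        fh.write(f"{n} atoms\n{len(bonds)} bonds\n\n")
        fh.write("4 atom types\n1 bond types\n\n")
        for axis in ("x", "y", "z"):
            fh.write(f"0.0 {state.box_edge:.6f} {axis}lo {axis}hi\n")
        fh.write("\nAtoms # molecular\n\n")
        for i in range(n):
            x, y, z = state.positions[i]
            fh.write(
                f"{i + 1} {int(chain_id[i]) + 1} {int(state.roles[i]) + 1} "
                f"{x:.6f} {y:.6f} {z:.6f}\n"
            )
        fh.write("\nBonds\n\n")
        for b, (i, j) in enumerate(bonds):
            fh.write(f"{b + 1} 1 {i + 1} {j + 1}\n")
        fh.write("\nVelocities\n\n")
        for i in range(n):
            vx, vy, vz = state.velocities[i]
            fh.write(f"{i + 1} {vx:.8e} {vy:.8e} {vz:.8e}\n")


# ------------------------------------------------------------ tables


def write_contact_series(series, path: str | Path) -> None:
    """Per-frame order parameters as tab-separated text."""
    with open(path, "w") as fh:
        fh.write("# time_fs\tn_ns_per_bead\tn_sp_per_bead\tn_sp_pairs\tn_lc\trg_red_A\trg_norm_A\n")
        for k in range(len(series.times)):
            fh.write(
                f"{series.times[k]:.1f}\t{series.n_ns[k]:.6f}\t{series.n_sp[k]:.6f}\t"
                f"{series.n_sp_pairs[k]}\t{series.n_lc[k]}\t"
                f"{series.rg_red[k]:.4f}\t{series.rg_norm[k]:.4f}\n"
            )


def write_swap_log(log, path: str | Path) -> None:
    """Replica-exchange swap attempts as tab-separated text."""
    with open(path, "w") as fh:
        fh.write("# time_fs\ti\tj\tE_i_kcal\tE_j_kcal\tprobability\taccepted\n")
        for att in log:
            fh.write(
                f"{att.time:.1f}\t{att.pair[0]}\t{att.pair[1]}\t"
                f"{att.E_i:.6f}\t{att.E_j:.6f}\t{att.probability:.6f}\t"
                f"{int(att.accepted)}\n"
            )


def write_free_energy_profile(profile, path: str | Path) -> None:
    """Two-column text: bin center, F in k_B T (nan for unvisited bins)."""
    with open(path, "w") as fh:
        fh.write(
            f"# statistical_temperature_K={profile.statistical_temperature} "
            f"bin_width={profile.bin_width}\n"
        )
        for c, F in zip(profile.bin_centers, profile.F):
            fh.write(f"{c:.6f}\t{F:.6f}\n")
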