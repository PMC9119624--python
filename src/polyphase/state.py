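"""System state and trajectory containers shared by the builder and engine."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .model import BeadRole

__all__ = ["SystemState", "Frame", "Trajectory"]


@dataclass
class SystemState:
    """Instantaneous mechanical state of the polymer system.

    positions/velocities are (N, 3) float arrays in Å and Å/fs; ``roles``
    and ``chain_id`` are length-N integer arrays; ``box_edge`` is the cubic
    periodic box edge in Å; ``time`` is in fs.
    """

    positions: np.ndarray
    velocities: np.ndarray
    roles: np.ndarray
    chain_id: np.ndarray
    box_edge: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.roles = np.ascontiguousarray(self.roles, dtype=np.int64)
        self.chain_id = np.ascontiguousarray(self.chain_id, dtype=np.int64)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must both be (N, 3)")
        if self.roles.shape != (n,) or self.chain_id.shape != (n,):
            raise ValueError("roles and chain_id must be length-N vectors")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1

    def wrapped(self) -> "SystemState":
        """Copy with all coordinates wrapped into [0, box_edge)."""
        pos = np.mod(self.positions, self.box_edge)
        return SystemState(
            positions=pos,
            velocities=self.velocities.copy(),
            roles=self.roles.copy(),
            chain_id=self.chain_id.copy(),
            box_edge=self.box_edge,
            time=self.time,
        )

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            roles=self.roles.copy(),
            chain_id=self.chain_id.copy(),
            box_edge=self.box_edge,
            time=self.time,
        )


@dataclass
class Frame:
    """One trajectory frame; velocities are optional."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray | None = None


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology plus run metadata."""

    roles: np.ndarray
    chain_id: np.ndarray
    box_edge: float
    frames: list[Frame] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.roles = np.ascontiguousarray(self.roles, dtype=np.int64)
        self.chain_id = np.ascontiguousarray(self.chain_id, dtype=np.int64)
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_beads(self) -> int:
        return self.roles.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def duration(self) -> float:
        """Time spanned by the stored frames, fs."""
        if not self.frames:
            return 0.0
        return self.frames[-1].time - self.frames[0].time

    def append(self, frame: Frame) -> None:
        if self.frames and frame.time <= self.frames[-1].time:
            raise ValueError("frame times must be strictly increasing")
        if frame.positions.shape != (self.n_beads, 3):
            raise ValueError("frame has wrong bead count for this topology")
        self.frames.append(frame)

    def state_at(self, index: int) -> SystemState:
        """Materialize a frame as a SystemState (zero velocities if absent)."""
        fr = self.frames[index]
        vel = fr.velocities if fr.velocities is not None else np.zeros_like(fr.positions)
        return SystemState(
            positions=fr.positions.copy(),
            velocities=vel.copy(),
            roles=self.roles.copy(),
            chain_id=self.chain_id.copy(),
            box_edge=self.box_edge,
            time=fr.time,
        )
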