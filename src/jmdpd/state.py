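"""System state container and extended-XYZ trajectory I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topology import BEAD_TYPES, TYPE_INDEX, Topology


@dataclass
class SystemState:
    """Positions, velocities, masses and box of one periodic system.

    The box is orthorhombic and periodic in all directions; coordinates are
    kept wrapped into [0, L) per dimension.
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    topology: Topology
    masses: np.ndarray | None = None
    time: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.masses is None:
            self.masses = np.ones(self.positions.shape[0])
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if np.any(self.masses <= 0):
            raise ValueError("bead masses must be positive")
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities shapes differ")
        if self.positions.shape[0] != self.topology.n_beads:
            raise ValueError("state and topology bead counts differ")
        self.wrap()

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    @property
    def types(self) -> np.ndarray:
        return self.topology.types

    def wrap(self) -> None:
        self.positions -= self.box * np.floor(self.positions / self.box)

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            topology=self.topology,
            masses=self.masses.copy(),
            time=self.time,
            provenance=dict(self.provenance),
        )

    def thermalize(self, T: float, seed: int = 0) -> None:
        """Draw Maxwell-Boltzmann velocities at reduced temperature T."""
        rng = np.random.default_rng(seed)
        v = rng.normal(0.0, 1.0, size=self.velocities.shape)
        v *= np.sqrt(T / self.masses)[:, None]
        v -= np.average(v, axis=0, weights=self.masses)
        self.velocities[:] = v


def write_xyz(path: str | Path, state: SystemState, append: bool = False,
              velocities: bool = True) -> None:
    """Write one extended-XYZ frame (box and fields in the comment line)."""
    labels = state.topology.type_labels()
    lx, ly, lz = state.box
    props = "species:S:1:pos:R:3" + (":vel:R:3" if velocities else "")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{state.n_beads}\n")
        fh.write(
            f'Lattice="{lx:.8f} 0 0 0 {ly:.8f} 0 0 0 {lz:.8f}" '
            f'Properties={props} Time={state.time:.6f}\n')
        for i in range(state.n_beads):
            x, y, z = state.positions[i]
            line = f"{labels[i]} {x:.6f} {y:.6f} {z:.6f}"
            if velocities:
                vx, vy, vz = state.velocities[i]
                line += f" {vx:.6f} {vy:.6f} {vz:.6f}"
            fh.write(line + "\n")


def read_xyz_frames(path: str | Path):
    """Iterate over (labels, positions, velocities|None, box, time) frames."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                return
            n = int(header)
            comment = fh.readline()
            box = _parse_lattice(comment)
            time = 0.0
            for tok in comment.split():
                if tok.startswith("Time="):
                    time = float(tok.split("=")[1])
            labels = []
            pos = np.zeros((n, 3))
            vel = None
            for i in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                pos[i] = [float(v) for v in parts[1:4]]
                if len(parts) >= 7:
                    if vel is None:
                        vel = np.zeros((n, 3))
                    vel[i] = [float(v) for v in parts[4:7]]
            yield labels, pos, vel, box, time


def _parse_lattice(comment: str) -> np.ndarray:
    start = comment.index('Lattice="') + len('Lattice="')
    end = comment.index('"', start)
    vals = [float(v) for v in comment[start:end].split()]
    return np.array([vals[0], vals[4], vals[8]])


def load_state(path: str | Path, topology: Topology) -> SystemState:
    """Load the first frame of an extended-XYZ file against a topology."""
    for labels, pos, vel, box, time in read_xyz_frames(path):
        types = np.array([TYPE_INDEX[l] for l in labels], dtype=np.int64)
        if not np.array_equal(types, topology.types):
            raise ValueError("frame bead types do not match the topology")
        if vel is None:
            vel = np.zeros_like(pos)
        return SystemState(positions=pos, velocities=vel, box=box,
                           topology=topology, time=time)
    raise ValueError(f"no frames in {path}")
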