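"""Bead topology: types, bonds, angles and molecule membership.

The bead alphabet is fixed by the coarse-grained model: water (W), fictitious
gas (B), choline (N), phosphate (P), glycerol (G), alkyl tail (C), and the
nanoparticle hydrophilic (K) and hydrophobic (L) beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BEAD_TYPES = ("W", "B", "N", "P", "G", "C", "K", "L")
TYPE_INDEX = {t: i for i, t in enumerate(BEAD_TYPES)}
N_TYPES = len(BEAD_TYPES)

#: types whose pairwise conservative interaction follows the exponential
#: (gas) law rather than the linear soft repulsion
GAS_TYPES = ("B",)


@dataclass
class Topology:
    """Connectivity and molecule bookkeeping for one system.

    ``bonds`` rows are (i, j); ``angles`` rows are (i, j, k) with the angle
    at the middle bead j.  ``mol_id`` is -1 for solvent/gas beads and a
    non-negative molecule index otherwise; ``lipids`` and ``nps`` list the
    bead indices of each lipid / nanoparticle molecule.
    """

    types: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    charges: np.ndarray | None = None
    mol_id: np.ndarray | None = None
    lipids: list = field(default_factory=list)
    nps: list = field(default_factory=list)
    # per-NP metadata (filled by the builder): dict with keys
    # 'radius', 'phi_L', 'surface_beads', 'cap_axis'
    np_meta: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.types = np.asarray(self.types, dtype=np.int64)
        n = self.types.size
        if self.charges is None:
            self.charges = np.zeros(n)
        if self.mol_id is None:
            self.mol_id = np.full(n, -1, dtype=np.int64)
        self.validate()

    @property
    def n_beads(self) -> int:
        return int(self.types.size)

    def validate(self) -> None:
        n = self.n_beads
        if self.types.size and (self.types.min() < 0 or self.types.max() >= N_TYPES):
            raise ValueError("bead type index outside the bead alphabet")
        for name, arr in (("bond", self.bonds), ("angle", self.angles)):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{name} references a bead that does not exist")
        if len(self.bonds) != len(self.bond_k) or len(self.bonds) != len(self.bond_r0):
            raise ValueError("bond parameter arrays do not match the bond list")
        if len(self.angles) != len(self.angle_k) or len(self.angles) != len(self.angle_theta0):
            raise ValueError("angle parameter arrays do not match the angle list")
        for lip in self.lipids:
            if len(lip) != 14:
                raise ValueError("lipid molecules must have exactly 14 beads")

    def type_labels(self) -> list[str]:
        return [BEAD_TYPES[t] for t in self.types]

    def merge(self, other: "Topology") -> "Topology":
        """Concatenate two topologies; ``other``'s indices are shifted."""
        off = self.n_beads
        nmol = int(self.mol_id.max()) + 1 if (self.mol_id.size and self.mol_id.max() >= 0) else 0
        other_mol = other.mol_id.copy()
        other_mol[other_mol >= 0] += nmol
        return Topology(
            types=np.concatenate([self.types, other.types]),
            bonds=np.vstack([self.bonds, other.bonds + off]).astype(np.int64),
            bond_k=np.concatenate([self.bond_k, other.bond_k]),
            bond_r0=np.concatenate([self.bond_r0, other.bond_r0]),
            angles=np.vstack([self.angles, other.angles + off]).astype(np.int64),
            angle_k=np.concatenate([self.angle_k, other.angle_k]),
            angle_theta0=np.concatenate([self.angle_theta0, other.angle_theta0]),
            charges=np.concatenate([self.charges, other.charges]),
            mol_id=np.concatenate([self.mol_id, other_mol]),
            lipids=self.lipids + [np.asarray(l) + off for l in other.lipids],
            nps=self.nps + [np.asarray(p) + off for p in other.nps],
            np_meta=self.np_meta + [dict(m, surface_beads=np.asarray(m["surface_beads"]) + off)
                                    for m in other.np_meta],
        )


    def to_dict(self) -> dict:
        """JSON-serializable form (sidecar file for trajectories)."""
        return {
            "types": self.types.tolist(),
            "bonds": self.bonds.tolist(),
            "bond_k": self.bond_k.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "angles": self.angles.tolist(),
            "angle_k": self.angle_k.tolist(),
            "angle_theta0": self.angle_theta0.tolist(),
            "charges": self.charges.tolist(),
            "mol_id": self.mol_id.tolist(),
            "lipids": [np.asarray(l).tolist() for l in self.lipids],
            "nps": [np.asarray(p).tolist() for p in self.nps],
            "np_meta": [
                {"radius": float(m["radius"]), "phi_L": float(m["phi_L"]),
                 "surface_beads": np.asarray(m["surface_beads"]).tolist(),
                 "cap_axis": np.asarray(m["cap_axis"]).tolist()}
                for m in self.np_meta],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            types=np.asarray(d["types"], dtype=np.int64),
            bonds=np.asarray(d["bonds"], dtype=np.int64).reshape(-1, 2),
            bond_k=np.asarray(d["bond_k"], dtype=float),
            bond_r0=np.asarray(d["bond_r0"], dtype=float),
            angles=np.asarray(d["angles"], dtype=np.int64).reshape(-1, 3),
            angle_k=np.asarray(d["angle_k"], dtype=float),
            angle_theta0=np.asarray(d["angle_theta0"], dtype=float),
            charges=np.asarray(d["charges"], dtype=float),
            mol_id=np.asarray(d["mol_id"], dtype=np.int64),
            lipids=[np.asarray(l, dtype=np.int64) for l in d["lipids"]],
            nps=[np.asarray(p, dtype=np.int64) for p in d["nps"]],
            np_meta=[
                {"radius": m["radius"], "phi_L": m["phi_L"],
                 "surface_beads": np.asarray(m["surface_beads"], dtype=np.int64),
                 "cap_axis": np.asarray(m["cap_axis"], dtype=float)}
                for m in d["np_meta"]],
        )


def empty_topology() -> Topology:
    return Topology(types=np.zeros(0, dtype=np.int64))
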