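"""Contact-energy surface-energy decomposition of the NP-monolayer system.

The surface energy of the particle-loaded interface is split as
E_S = E_NP + E_m', where E_m' = gamma_m (Lx*Ly - A_I^NP) is the free
energy of the monolayer area not occupied by the particle and E_NP is the
particle's adsorption energy, estimated from bead-bead contact energies:

    E_NP = sum_j (eps_Kj n_Kj + eps_Lj n_Lj)

with n_aj the number of j beads in contact with the particle's surface
beads.  The contact energy of a pair is the RDF-weighted average of the
mismatch potential over the interaction range,

    eps_aj = int_0^R dV_aj(r) g_aj(r) r^2 dr / int_0^R g_aj(r) r^2 dr,
    dV_aj  = V_aj - (V_aa + V_jj)/2,

where V is the conservative pair potential (quadratic for standard DPD
pairs, the integrated exponential for gas pairs).  Negative eps means a
favorable contact.  The g_aj are measured from small bulk simulations of
a few free alpha beads dilute in a bath of j beads.

All energies here are in k_BT (the declared force-field units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .topology import BEAD_TYPES, TYPE_INDEX, Topology


# ---------------------------------------------------------------------------
# pair potentials (k_BT units)


def potential_linear(r, a, R=1.0):
    """Quadratic DPD potential V = a R (1 - r/R)^2 / 2 for r < R."""
    r = np.asarray(r, dtype=float)
    return np.where(r < R, 0.5 * a * R * (1.0 - r / R) ** 2, 0.0)


def potential_exponential(r, a, b, R=1.0):
    """Integrated exponential gas potential; V(R) = 0, -dV/dr = F_exp."""
    if b == 0.0:
        raise ValueError("b=0 is degenerate")
    r = np.asarray(r, dtype=float)
    eb = np.exp(b)
    V = a / (1.0 - eb) * ((r - R) * eb + R / b * (eb - np.exp(b * r / R)))
    return np.where(r < R, V, 0.0)


def pair_potential(r, ff, t1: str, t2: str):
    """Conservative pair potential in k_BT for bead types t1, t2."""
    p = ff.table.pair(t1, t2)
    if p["exponential"]:
        return potential_exponential(r, p["a"], p["b"], p["R"])
    return potential_linear(r, p["a"], p["R"])


def mismatch_potential(r, ff, alpha: str, j: str):
    """dV_aj = V_aj - (V_aa + V_jj)/2 on a grid (k_BT)."""
    return (pair_potential(r, ff, alpha, j)
            - 0.5 * (pair_potential(r, ff, alpha, alpha)
                     + pair_potential(r, ff, j, j)))


# ---------------------------------------------------------------------------
# RDF estimation


@dataclass
class RDF:
    r: np.ndarray
    g: np.ndarray
    pair: tuple
    n_samples: int = 0

    def tail_mean(self, fraction: float = 0.2) -> float:
        k = max(1, int(len(self.r) * fraction))
        return float(self.g[-k:].mean())


def rdf_from_frames(tagged_pos, host_pos, box, r_max: float = 3.0,
                    bin_width: float = 0.02) -> RDF:
    """Radial distribution function of host beads around tagged beads.

    ``tagged_pos``/``host_pos`` are lists of per-frame coordinate arrays.
    Normalized by the host bulk density so g -> 1 at large r.
    """
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_frames = len(tagged_pos)
    if n_frames == 0:
        raise ValueError("no frames given")
    box = np.asarray(box, dtype=float)
    n_tag = tagged_pos[0].shape[0]
    n_host = host_pos[0].shape[0]
    for tp, hp in zip(tagged_pos, host_pos):
        d = tp[:, None, :] - hp[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt((d * d).sum(axis=2)).ravel()
        hist += np.histogram(r, bins=edges)[0]
    vol = float(np.prod(box))
    rho = n_host / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = rho * shell * n_tag * n_frames
    g = hist / ideal
    r_mid = 0.5 * (edges[1:] + edges[:-1])
    return RDF(r=r_mid, g=g, pair=("tag", "host"),
               n_samples=int(n_tag * n_frames))


def estimate_rdf(ff, alpha: str, host: str, seed: int = 0,
                 n_host: int = 500, n_tagged: int = 3,
                 equil_steps: int = 4000, run_steps: int = 20000,
                 sample_every: int = 25, bin_width: float = 0.02,
                 r_max: float = 3.0, dt: float = 0.02) -> RDF:
    """Measure g_aj(r) from a dilute-tagged-bead bulk DPD run."""
    from .engine import DPDEngine, EngineConfig
    from .state import SystemState

    rho = ff.units.rho_W if host != "B" else float(ff.gas.get("rho_B", 1.0))
    L = (n_host / rho) ** (1.0 / 3.0)
    # beyond half the box the minimum-image shell is truncated and g would
    # be biased low; clamp the range
    r_max = min(r_max, 0.45 * L)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, L, size=(n_host + n_tagged, 3))
    types = np.concatenate([
        np.full(n_host, TYPE_INDEX[host], dtype=np.int64),
        np.full(n_tagged, TYPE_INDEX[alpha], dtype=np.int64)])
    st = SystemState(positions=pos, velocities=np.zeros_like(pos),
                     box=np.array([L, L, L]),
                     topology=Topology(types=types))
    st.thermalize(ff.units.T_DPD, seed=seed + 1)
    eng = DPDEngine(st, ff, EngineConfig(dt=dt, seed=seed + 2,
                                         sample_every=0))
    eng.run(equil_steps)
    _, (tp, tb) = eng.run(run_steps, traj_every=sample_every)
    tagged = [f[n_host:] for f in tp]
    hosts = [f[:n_host] for f in tp]
    rdf = rdf_from_frames(tagged, hosts, st.box, r_max=r_max,
                          bin_width=bin_width)
    rdf.pair = (alpha, host)
    if rdf.n_samples < 1000:
        import warnings

        warnings.warn("few RDF samples; the estimate will be noisy")
    return rdf


# ---------------------------------------------------------------------------
# contact energies


def contact_energy(rdf: RDF, dV: np.ndarray, R_cut: float) -> float:
    """eps = int dV g r^2 dr / int g r^2 dr over [0, R_cut] (quadrature)."""
    r = rdf.r
    sel = r <= R_cut
    if not sel.any():
        raise ValueError("empty integration grid")
    r = r[sel]
    g = rdf.g[sel]
    w = g * r * r
    denom = np.trapezoid(w, r)
    if denom <= 0:
        raise ValueError("vanishing RDF weight on the integration range")
    return float(np.trapezoid(dV[sel] * w, r) / denom)


@dataclass
class ContactEnergyTable:
    """eps_aj in k_BT for alpha in {K, L} and j in the environment types."""

    eps: dict = field(default_factory=dict)
    rdfs: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, pair):
        return self.eps[pair]

    def get(self, pair, default=0.0):
        return self.eps.get(pair, default)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"alpha": a, "j": j, "eps_kBT": e}
                for (a, j), e in sorted(self.eps.items())]
        return pd.DataFrame(rows)


def compute_contact_energies(ff, alphas=("K", "L"),
                             environments=("N", "P", "G", "C", "W", "B"),
                             seed: int = 0, **rdf_kwargs) -> ContactEnergyTable:
    """Full eps table from dilute-bead RDF runs (one run per pair)."""
    table = ContactEnergyTable(provenance={"seed": seed, **rdf_kwargs})
    for a in alphas:
        for j in environments:
            rdf = estimate_rdf(ff, a, j, seed=seed + 7919 * (TYPE_INDEX[a] * 8
                                                             + TYPE_INDEX[j]),
                               **rdf_kwargs)
            dV = mismatch_potential(rdf.r, ff, a, j)
            R_cut = ff.table.pair(a, j)["R"]
            table.eps[(a, j)] = contact_energy(rdf, dV, R_cut)
            table.rdfs[(a, j)] = rdf
    return table


# ---------------------------------------------------------------------------
# contact counting and the energy series


def count_contacts(positions: np.ndarray, topology: Topology, box, ff,
                   np_index: int = 0, surface_only: bool = True) -> dict:
    """n_aj: beads of type j in contact with NP (surface) beads.

    Contact means r < R_aj, the conservative cutoff of the pair — the
    upper limit of the contact-energy integral.  Intra-particle contacts
    are excluded.
    """
    box = np.asarray(box, dtype=float)
    npb = np.asarray(topology.nps[np_index])
    if surface_only:
        npb = np.asarray(topology.np_meta[np_index]["surface_beads"])
    others = np.setdiff1d(np.arange(topology.n_beads),
                          np.asarray(topology.nps[np_index]))
    wrapped_np = positions[npb] % box
    wrapped_o = positions[others] % box
    tree = cKDTree(wrapped_o, boxsize=box)
    r_all = float(ff.table.max_cutoff)
    counts: dict = {}
    lists = tree.query_ball_point(wrapped_np, r_all)
    for bead, neigh in zip(npb, lists):
        ta = BEAD_TYPES[topology.types[bead]]
        for o in neigh:
            jb = others[o]
            tj = BEAD_TYPES[topology.types[jb]]
            Rij = ff.table.pair(ta, tj)["R"]
            d = positions[bead] % box - wrapped_o[o]
            d -= box * np.round(d / box)
            if float(d @ d) < Rij * Rij:
                counts[(ta, tj)] = counts.get((ta, tj), 0) + 1
    return counts


@dataclass
class SurfaceEnergyRecord:
    time: float
    contacts: dict
    E_NP_K: float
    E_NP_L: float
    E_NP: float
    E_m: float      # gamma_m (Lx Ly - A_I), k_BT
    E_S: float

    def __post_init__(self):
        assert abs(self.E_S - (self.E_NP + self.E_m)) < 1e-9


def surface_energy_series(traj_pos, traj_box, topology: Topology, ff,
                          eps_table: ContactEnergyTable,
                          gamma_m: np.ndarray, times=None,
                          np_index: int = 0,
                          surface_only: bool = True) -> pd.DataFrame:
    """Per-frame E_NP, E_m', E_S (k_BT) for a trajectory.

    ``gamma_m`` is the per-interface monolayer tension (k_BT/R_c^2) on the
    same frame grid as the trajectory.
    """
    from .observables import np_interfacial_area

    n = len(traj_pos)
    if len(gamma_m) != n:
        raise ValueError("tension series and trajectory frame counts differ")
    rows = []
    for f in range(n):
        pos = traj_pos[f]
        box = traj_box[f]
        counts = count_contacts(pos, topology, box, ff, np_index=np_index,
                                surface_only=surface_only)
        eK = sum(eps_table.get(("K", j), 0.0) * c
                 for (a, j), c in counts.items() if a == "K")
        eL = sum(eps_table.get(("L", j), 0.0) * c
                 for (a, j), c in counts.items() if a == "L")
        A_I = np_interfacial_area(pos, topology, box, np_index=np_index)
        E_m = float(gamma_m[f]) * (float(box[0] * box[1]) - A_I)
        rec = SurfaceEnergyRecord(
            time=times[f] if times is not None else float(f),
            contacts=counts, E_NP_K=eK, E_NP_L=eL, E_NP=eK + eL,
            E_m=E_m, E_S=eK + eL + E_m)
        rows.append({"time": rec.time, "E_NP_K": eK, "E_NP_L": eL,
                     "E_NP": rec.E_NP, "E_m": E_m, "E_S": rec.E_S,
                     "A_I": A_I})
    return pd.DataFrame(rows)
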