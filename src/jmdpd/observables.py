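"""Per-frame monolayer and nanoparticle observables.

Orientation angle of the Janus particle, pressure-tensor surface tension
and surface pressure, lipid tail order and liquid-condensed statistics,
nanoparticle interfacial area, lipid loss, and the effective area per
lipid.  All lengths are reduced (R_c); tensions are reported both in
k_BT/R_c^2 and mN/m through the force field's unit system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .topology import TYPE_INDEX, Topology


# ---------------------------------------------------------------------------
# geometry helpers


def _circular_mean(z: np.ndarray, L: float) -> float:
    ang = z / L * 2 * np.pi
    return float(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi) % 1.0) * L


def _rel_z(z: np.ndarray, z0: float, L: float) -> np.ndarray:
    """Signed z offset from z0 under periodicity, in (-L/2, L/2]."""
    d = (z - z0) % L
    d[d > L / 2] -= L
    return d


def unwrap_group(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap a compact group of beads around its first member."""
    ref = positions[0]
    d = positions - ref
    d -= box * np.round(d / box)
    return ref + d


def water_midplane(positions: np.ndarray, topology: Topology, box) -> float:
    zW = positions[topology.types == TYPE_INDEX["W"], 2]
    return _circular_mean(zW, float(box[2]))


def interface_planes(positions: np.ndarray, topology: Topology, box):
    """Mean phosphate z of each leaflet: (upper plane, lower plane).

    Leaflet membership is assigned per frame by the sign of the phosphate
    offset from the water midplane.
    """
    zc = water_midplane(positions, topology, box)
    L = float(box[2])
    zP = positions[topology.types == TYPE_INDEX["P"], 2]
    rel = _rel_z(zP, zc, L)
    upper = rel[rel >= 0]
    lower = rel[rel < 0]
    z_up = zc + (upper.mean() if upper.size else 0.0)
    z_lo = zc + (lower.mean() if lower.size else 0.0)
    return z_up % L, z_lo % L


# ---------------------------------------------------------------------------
# orientation


@dataclass
class OrientationState:
    director: np.ndarray      # unit vector hydrophobic -> hydrophilic cap
    theta_deg: float          # angle against the leaflet outward normal
    center: np.ndarray
    leaflet: str              # 'upper' or 'lower'


def orientation(positions: np.ndarray, topology: Topology, box,
                np_index: int = 0) -> OrientationState:
    """Janus-particle orientation: u = (R_com^K - R_com^L)/|...|.

    Theta is measured against the outward normal of the leaflet the
    particle is closest to, so a lipophile-adhesion start reads ~0 deg and
    a fully intercalated particle 180 deg.  Undefined for a uniform
    particle (phi_L of 0 or 1).
    """
    beads = np.asarray(topology.nps[np_index])
    types = topology.types[beads]
    box = np.asarray(box, dtype=float)
    pts = unwrap_group(positions[beads], box)
    isK = types == TYPE_INDEX["K"]
    isL = types == TYPE_INDEX["L"]
    if not isK.any() or not isL.any():
        raise ValueError("orientation undefined for a uniform particle "
                         "(phi_L is 0 or 1)")
    u = pts[isK].mean(axis=0) - pts[isL].mean(axis=0)
    u /= np.linalg.norm(u)
    center = pts.mean(axis=0)
    zc = water_midplane(positions, topology, box)
    rel = _rel_z(np.array([center[2]]), zc, float(box[2]))[0]
    leaflet = "upper" if rel >= 0 else "lower"
    normal = np.array([0.0, 0.0, 1.0 if leaflet == "upper" else -1.0])
    theta = np.degrees(np.arccos(np.clip(np.dot(u, normal), -1.0, 1.0)))
    return OrientationState(director=u, theta_deg=float(theta),
                            center=center % box, leaflet=leaflet)


# ---------------------------------------------------------------------------
# tension


@dataclass
class TensionRecord:
    time: float
    P_xx: float
    P_yy: float
    P_zz: float
    gamma_m: float       # per interface, k_BT/R_c^2
    gamma_m_mNm: float
    Pi: float            # surface pressure, k_BT/R_c^2
    Pi_mNm: float


def surface_tension(P_xx, P_yy, P_zz, L_z, units, gamma0=None,
                    time=0.0) -> TensionRecord:
    """Tension of each of the two symmetric interfaces from the pressure
    tensor: gamma_m = L_z/2 (P_zz - (P_xx + P_yy)/2); Pi = gamma0 - gamma_m.

    ``gamma0`` defaults to the in-model bare air-water tension carried by
    the unit system (reduced units); pass ``units.tension_from_mNm(72.8)``
    to use the laboratory value instead.
    """
    gm = 0.5 * L_z * (P_zz - 0.5 * (P_xx + P_yy))
    g0 = units.gamma0_reduced if gamma0 is None else gamma0
    pi = g0 - gm
    return TensionRecord(
        time=time, P_xx=P_xx, P_yy=P_yy, P_zz=P_zz,
        gamma_m=float(gm), gamma_m_mNm=units.tension_to_mNm(float(gm)),
        Pi=float(pi), Pi_mNm=units.tension_to_mNm(float(pi)))


def tension_series(obs: pd.DataFrame, units, gamma0=None) -> pd.DataFrame:
    """Vectorized surface_tension over an engine observable table."""
    gm = 0.5 * obs["Lz"] * (obs["Pzz"] - 0.5 * (obs["Pxx"] + obs["Pyy"]))
    g0 = units.gamma0_reduced if gamma0 is None else gamma0
    out = pd.DataFrame({
        "time": obs["time"], "step": obs["step"],
        "gamma_m": gm, "Pi": g0 - gm})
    out["gamma_m_mNm"] = out["gamma_m"] * units.tension_constant_mNm
    out["Pi_mNm"] = out["Pi"] * units.tension_constant_mNm
    return out


# ---------------------------------------------------------------------------
# tail order / phases


@dataclass
class PhaseStats:
    S: np.ndarray            # per-lipid order parameter (two-tail average)
    lc_mask: np.ndarray      # S > threshold
    n_lc: int
    A_res: float
    f_lc: float
    leaflet_of: np.ndarray   # +1 upper / -1 lower per lipid


def tail_order(positions: np.ndarray, topology: Topology, box,
               tails=((4, 8), (9, 13)), lc_threshold: float = 0.6,
               A_I: float = 0.0, exclude=None) -> PhaseStats:
    """Per-lipid tail order S = (3 cos^2(theta) - 1)/2 against z.

    The tail vector runs from the first to the last bead of each tail;
    S is averaged over the two tails.  f_LC counts lipids above the
    liquid-condensed threshold per residual interfacial area
    A_res = Lx*Ly - A_I (per leaflet, averaged over leaflets).
    ``exclude`` marks lipids (e.g. lost ones) not counted in f_LC.
    """
    box = np.asarray(box, dtype=float)
    lipids = topology.lipids
    n = len(lipids)
    if n == 0:
        raise ValueError("no lipids in topology")
    S = np.zeros(n)
    leaflet = np.zeros(n)
    zc = water_midplane(positions, topology, box)
    for i, beads in enumerate(lipids):
        beads = np.asarray(beads)
        pts = unwrap_group(positions[beads], box)
        acc = 0.0
        for t0, t1 in tails:
            v = pts[t1] - pts[t0]
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                raise ValueError(f"degenerate tail vector in lipid {i}")
            ct = v[2] / norm
            acc += 0.5 * (3.0 * ct * ct - 1.0)
        S[i] = acc / len(tails)
        relz = _rel_z(np.array([pts[1, 2]]), zc, box[2])[0]  # phosphate
        leaflet[i] = 1.0 if relz >= 0 else -1.0
    lc = S > lc_threshold
    counted = lc if exclude is None else (lc & ~exclude)
    A_res = float(box[0] * box[1]) - A_I
    # per-leaflet count, averaged over the two leaflets
    f_lc = 0.5 * counted.sum() / A_res
    return PhaseStats(S=S, lc_mask=lc, n_lc=int(counted.sum()),
                      A_res=A_res, f_lc=float(f_lc), leaflet_of=leaflet)


# ---------------------------------------------------------------------------
# nanoparticle interfacial area


def np_interfacial_area(positions: np.ndarray, topology: Topology, box,
                        np_index: int = 0, method: str = "geometric") -> float:
    """Interfacial area occupied by the nanoparticle (one leaflet).

    'geometric' (default): cross-section pi (R^2 - d^2) of the particle
    sphere at its leaflet's interface plane (mean phosphate z), zero when
    the center is farther than R from the plane.  'beads': area of the
    x-y bounding disks of NP beads lying within one bead of the plane
    (a discrete alternative for sensitivity checks).
    """
    box = np.asarray(box, dtype=float)
    meta = topology.np_meta[np_index]
    R = float(meta["radius"])
    beads = np.asarray(topology.nps[np_index])
    pts = unwrap_group(positions[beads], box)
    center = pts.mean(axis=0)
    z_up, z_lo = interface_planes(positions, topology, box)
    zc = water_midplane(positions, topology, box)
    rel = _rel_z(np.array([center[2]]), zc, float(box[2]))[0]
    plane = z_up if rel >= 0 else z_lo
    d = abs(_rel_z(np.array([center[2]]), plane, float(box[2]))[0])
    if method == "geometric":
        if d >= R:
            return 0.0
        return float(np.pi * (R * R - d * d))
    elif method == "beads":
        relz = _rel_z(pts[:, 2].copy(), plane, float(box[2]))
        sel = np.abs(relz) < 1.0
        if not sel.any():
            return 0.0
        rad = np.linalg.norm(pts[sel, :2] - center[:2], axis=1)
        rmax = rad.max() + 0.5
        return float(np.pi * rmax * rmax)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# lipid loss


def lipid_loss(positions: np.ndarray, topology: Topology, box,
               contact_cutoff: float = 1.0):
    """Count lipids lost from the monolayers (n_L^w) and label each lipid.

    A lipid is 'lost' when it is not part of the largest tail-contact
    cluster of its leaflet (detached micelles, translocated lipids) or
    when all of its tail beads touch nanoparticle beads (coating).
    Returns (n_lost, status array: 0 in-layer, 1 detached, 2 coating).
    """
    box = np.asarray(box, dtype=float)
    lipids = topology.lipids
    n = len(lipids)
    if n == 0:
        return 0, np.zeros(0, dtype=int)
    tail_types = (TYPE_INDEX["C"],)
    tail_beads = []
    tail_owner = []
    zc = water_midplane(positions, topology, box)
    leaflet = np.zeros(n, dtype=int)
    for i, beads in enumerate(lipids):
        beads = np.asarray(beads)
        relz = _rel_z(np.array([positions[beads[1], 2]]), zc, box[2])[0]
        leaflet[i] = 1 if relz >= 0 else -1
        for bidx in beads:
            if topology.types[bidx] in tail_types:
                tail_beads.append(bidx)
                tail_owner.append(i)
    tail_beads = np.asarray(tail_beads)
    tail_owner = np.asarray(tail_owner)
    wrapped = positions[tail_beads] % box
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
    li = tail_owner[pairs[:, 0]] if len(pairs) else np.zeros(0, dtype=int)
    lj = tail_owner[pairs[:, 1]] if len(pairs) else np.zeros(0, dtype=int)
    sel = li != lj
    adj = coo_matrix((np.ones(sel.sum()), (li[sel], lj[sel])), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    status = np.zeros(n, dtype=int)
    for leaf in (1, -1):
        members = np.flatnonzero(leaflet == leaf)
        if members.size == 0:
            continue
        labs, counts = np.unique(labels[members], return_counts=True)
        main = labs[np.argmax(counts)]
        for i in members:
            if labels[i] != main:
                status[i] = 1
    # coating: all tail beads within contact range of NP beads
    np_beads = np.concatenate([np.asarray(b) for b in topology.nps]) \
        if topology.nps else np.zeros(0, dtype=int)
    if np_beads.size:
        nptree = cKDTree(positions[np_beads] % box, boxsize=box)
        d, _ = nptree.query(wrapped, k=1)
        near = d < contact_cutoff
        for i in range(n):
            mine = near[tail_owner == i]
            if mine.size and mine.all():
                status[i] = 2
    return int((status > 0).sum()), status


# ---------------------------------------------------------------------------
# effective area


@dataclass
class AreaStats:
    A_I: float
    n_lost: int
    n_res: int
    a_eff: float           # R_c^2
    a_eff_nm2: float


def effective_area(Lx_Ly: float, A_I: float, n_lipids: int, n_lost: int,
                   units=None) -> AreaStats:
    """Effective area per lipid a_eff = (Lx*Ly - A_I) / (n_L - n_L^w).

    ``n_lipids`` is the per-leaflet count and A_I the per-leaflet
    nanoparticle footprint.
    """
    n_res = n_lipids - n_lost
    if n_res <= 0:
        raise ValueError("no residual lipids at the interface")
    a_eff = (Lx_Ly - A_I) / n_res
    if a_eff <= 0:
        raise ValueError("non-positive effective area")
    a_nm2 = a_eff * units.R_c**2 if units is not None else float("nan")
    return AreaStats(A_I=A_I, n_lost=n_lost, n_res=n_res,
                     a_eff=float(a_eff), a_eff_nm2=float(a_nm2))


# ---------------------------------------------------------------------------
# frame-level analysis


def analyze_frames(traj_pos, traj_box, topology: Topology, units,
                   times=None, lc_threshold: float = 0.6,
                   contact_cutoff: float = 1.0) -> pd.DataFrame:
    """Structural observables for each stored frame.

    Returns a table with per-frame orientation angle (when a Janus
    particle is present), nanoparticle interfacial area, lost-lipid count,
    order statistics and effective area per lipid.
    """
    rows = []
    n_frames = len(traj_pos)
    has_np = bool(topology.nps)
    mixed_np = False
    if has_np:
        t0 = topology.types[np.asarray(topology.nps[0])]
        mixed_np = (t0 == TYPE_INDEX["K"]).any() and (t0 == TYPE_INDEX["L"]).any()
    n_leaflet = len(topology.lipids) // 2 if topology.lipids else 0
    for f in range(n_frames):
        pos = traj_pos[f]
        box = traj_box[f]
        row = {"frame": f, "time": times[f] if times is not None else float(f)}
        A_I = 0.0
        if has_np:
            A_I = np_interfacial_area(pos, topology, box)
            if mixed_np:
                row["theta_deg"] = orientation(pos, topology, box).theta_deg
        row["A_I"] = A_I
        if topology.lipids:
            n_lost, status = lipid_loss(pos, topology, box, contact_cutoff)
            ps = tail_order(pos, topology, box, lc_threshold=lc_threshold,
                            A_I=A_I, exclude=status > 0)
            area = effective_area(float(box[0] * box[1]), A_I, n_leaflet,
                                  n_lost // 2 if n_lost else 0, units)
            row.update(n_lost=n_lost, S_mean=float(ps.S.mean()),
                       f_lc=ps.f_lc, a_eff=area.a_eff,
                       a_eff_nm2=area.a_eff_nm2)
        rows.append(row)
    return pd.DataFrame(rows)


def block_average(x, nblocks: int = 5):
    """Mean and block-averaged standard error of a (correlated) series."""
    x = np.asarray(x, dtype=float)
    n = (len(x) // nblocks) * nblocks
    if n == 0 or nblocks < 2:
        return float(np.mean(x)), float("nan")
    blocks = x[len(x) - n:].reshape(nblocks, -1).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=1) / np.sqrt(nblocks))
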