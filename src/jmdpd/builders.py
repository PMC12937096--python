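"""System builders: Janus nanoparticles, DPPC lipids, monolayer systems.

Everything the pipeline consumes is constructed here deterministically from
a spec and a seed: cubic-lattice Janus nanoparticles with a hydrophobic
spherical cap, 14-bead DPPC lipids, and double-monolayer systems — a water
slab in the x-y plane covered by a lipid monolayer on each face, gas slabs
outside, and optionally one nanoparticle in the gas phase above each
leaflet (keeping the system symmetric in z).  Initial packing uses
jittered lattices with seeded noise; the soft DPD cores plus the staged
(frozen-mass) equilibration remove any residual overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .forcefield import ForceField
from .state import SystemState
from .topology import TYPE_INDEX, Topology, empty_topology


@dataclass
class JNPSpec:
    """Cubic-lattice Janus nanoparticle.

    The hydrophobic coverage phi_L is the hydrophobic cap area fraction,
    equal to cap height over diameter: phi_L = A_cap/A_sphere = h/D.
    Beads whose axial coordinate (along the cap axis) exceeds R - h are
    hydrophobic (L), the rest hydrophilic (K); nearest lattice neighbors
    are linked by strong harmonic bonds.
    """

    radius: float = 3.0
    phi_L: float = 0.5
    lattice_spacing: float = 1.0
    bond_k: float | None = None  # k_BT/R_c^2; default from the force field

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_L <= 1.0:
            raise ValueError("phi_L must lie in [0, 1]")
        if self.lattice_spacing <= 0:
            raise ValueError("lattice spacing must be positive")
        if self.radius < 2 * self.lattice_spacing:
            raise ValueError("nanoparticle radius below 2 lattice spacings")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def cap_height(self) -> float:
        return self.phi_L * self.diameter


@dataclass
class MonolayerSpec:
    """Double-monolayer system geometry (lengths in R_c except a_L)."""

    n_lipids: int = 1400  # per leaflet
    area_per_lipid_nm2: float = 0.6
    water_thickness: float = 10.0
    gas_thickness: float = 8.0
    lipid_height: float = 4.6

    def lateral_length(self, ff: ForceField) -> float:
        a_L = ff.units.area_from_nm2(self.area_per_lipid_nm2)
        return float(np.sqrt(self.n_lipids * a_L))


@dataclass
class PlacementMode:
    """Initial nanoparticle orientation relative to the monolayer.

    'la' (lipophile adhesion): hydrophobic cap faces the monolayer,
    orientation angle ~0 degrees.  'ha' (hydrophile adhesion): hydrophilic
    cap faces it, ~180 degrees.
    """

    mode: str = "la"
    gap: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("la", "ha"):
            raise ValueError("placement mode must be 'la' or 'ha'")


def build_jnp(spec: JNPSpec, ff: ForceField, seed: int = 0):
    """Construct a Janus NP; returns (Topology, local coordinates).

    Coordinates are centered on the particle center with the cap axis
    along +z (hydrophobic cap on top).  The topology's ``np_meta`` holds
    the surface-bead indices (beads with at least one missing lattice
    neighbor), radius and phi_L.
    """
    s = spec.lattice_spacing
    m = int(np.ceil(spec.radius / s)) + 1
    grid = np.arange(-m, m + 1) * s + 0.5 * s  # bead-centered cells
    X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = np.linalg.norm(pts, axis=1) <= spec.radius
    pts = pts[inside]
    n = len(pts)
    types = np.full(n, TYPE_INDEX["K"], dtype=np.int64)
    # solid cap region above the plane z = R - h is hydrophobic
    types[pts[:, 2] >= spec.radius - spec.cap_height] = TYPE_INDEX["L"]
    # lattice bonds: nearest neighbors plus the face-diagonal shell —
    # central-force bonds on the 6-neighborhood alone leave the cubic
    # lattice shear-floppy and the particle would slowly deform; the
    # sqrt(2) shell restores rigidity (radius of gyration constant)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(s * np.sqrt(2.0) * 1.001, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("nanoparticle lattice has no bonds; spacing too large")
    bond_len = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    bk = spec.bond_k
    if bk is None:
        bk = float(ff.nanoparticle.get("bond_k", 500.0))
    bk = bk * ff.energy_scale
    # connectivity check
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError("nanoparticle bond graph is not connected")
    # surface beads: at least one of the 6 nearest lattice neighbors missing
    neigh_count = np.zeros(n, dtype=int)
    near = bond_len < s * 1.001
    for i, j in pairs[near]:
        neigh_count[i] += 1
        neigh_count[j] += 1
    surface = np.flatnonzero(neigh_count < 6)
    top = Topology(
        types=types,
        bonds=pairs.astype(np.int64),
        bond_k=np.full(len(pairs), bk),
        bond_r0=bond_len,
        mol_id=np.zeros(n, dtype=np.int64),
        nps=[np.arange(n)],
        np_meta=[{"radius": spec.radius, "phi_L": spec.phi_L,
                  "surface_beads": surface, "cap_axis": np.array([0.0, 0.0, 1.0])}],
    )
    return top, pts


def surface_hydrophobic_fraction(topology: Topology, np_index: int = 0) -> float:
    """Census of the L fraction among nanoparticle surface beads."""
    meta = topology.np_meta[np_index]
    surf = np.asarray(meta["surface_beads"])
    if surf.size == 0:
        return float("nan")
    return float(np.mean(topology.types[surf] == TYPE_INDEX["L"]))


def build_dppc(ff: ForceField, with_charges: bool | None = None):
    """Build one 14-bead DPPC lipid; returns (Topology, local coordinates).

    The conformation is extended with the tails along +z: choline (N) and
    phosphate (P) below the two glycerol beads, each glycerol anchoring a
    5-bead alkyl tail.  Charges (+1 on N, -1 on P) are set only when
    electrostatics is enabled in the force field.
    """
    tpl = ff.dppc
    labels = tpl["beads"]
    types = np.array([TYPE_INDEX[l] for l in labels], dtype=np.int64)
    bonds = np.asarray(tpl["bonds"], dtype=np.int64)
    angles = np.asarray(tpl["angles"], dtype=np.int64)
    esc = ff.energy_scale
    bl = ff.bonds.get("lipid", {"k": 128.0, "r0": 0.6})
    ak = ff.angles.get("tail", {"k": 6.0, "theta0_deg": 180.0})
    charges = np.zeros(len(labels))
    if with_charges is None:
        with_charges = bool(ff.electrostatics.get("enabled", False))
    if with_charges:
        for lab, q in tpl.get("charges", {}).items():
            charges[np.array(labels) == lab] = q
    r0 = float(bl["r0"])
    coords = np.zeros((14, 3))
    coords[0] = (0.0, 0.0, -2.0 * r0)   # N
    coords[1] = (0.0, 0.0, -r0)         # P
    coords[2] = (-0.25, 0.0, 0.0)       # G1
    coords[3] = (0.25, 0.0, 0.0)        # G2
    for t, (anchor, sign) in enumerate(((2, -1), (3, 1))):
        beads = tpl["tails"][t]
        for k, idx in enumerate(beads):
            coords[idx] = (sign * 0.25, 0.0, r0 * (k + 1))
    top = Topology(
        types=types,
        bonds=bonds,
        bond_k=np.full(len(bonds), float(bl["k"]) * esc),
        bond_r0=np.full(len(bonds), r0),
        angles=angles,
        angle_k=np.full(len(angles), float(ak["k"]) * esc),
        angle_theta0=np.full(len(angles), np.deg2rad(float(ak["theta0_deg"]))),
        charges=charges,
        mol_id=np.zeros(14, dtype=np.int64),
        lipids=[np.arange(14)],
    )
    return top, coords


def replicate_molecule(top: Topology, n: int) -> Topology:
    """Concatenate ``n`` copies of a single-molecule topology efficiently."""
    nb = top.n_beads
    offs = np.repeat(np.arange(n) * nb, len(top.bonds))
    offs_a = np.repeat(np.arange(n) * nb, len(top.angles))
    is_lipid = bool(top.lipids)
    return Topology(
        types=np.tile(top.types, n),
        bonds=(np.tile(top.bonds, (n, 1)).T + offs).T.astype(np.int64)
        if len(top.bonds) else np.zeros((0, 2), dtype=np.int64),
        bond_k=np.tile(top.bond_k, n),
        bond_r0=np.tile(top.bond_r0, n),
        angles=(np.tile(top.angles, (n, 1)).T + offs_a).T.astype(np.int64)
        if len(top.angles) else np.zeros((0, 3), dtype=np.int64),
        angle_k=np.tile(top.angle_k, n),
        angle_theta0=np.tile(top.angle_theta0, n),
        charges=np.tile(top.charges, n),
        mol_id=np.repeat(np.arange(n), nb),
        lipids=[np.arange(nb) + i * nb for i in range(n)] if is_lipid else [],
        nps=[np.arange(nb) + i * nb for i in range(n)] if top.nps else [],
        np_meta=[dict(m, surface_beads=np.asarray(m["surface_beads"]) + i * nb)
                 for i in range(n) for m in top.np_meta],
    )


def _rotation_to(axis_to: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto axis_to (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    b = np.asarray(axis_to, dtype=float)
    b = b / np.linalg.norm(b)
    v = np.cross(z, b)
    c = float(np.dot(z, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_system(ff: ForceField, mono: MonolayerSpec,
                 jnp: JNPSpec | None = None,
                 mode: PlacementMode | None = None,
                 seed: int = 0) -> SystemState:
    """Assemble a double-monolayer (optionally + Janus NP) SystemState.

    Geometry along z: gas | lipids | water | lipids | gas, periodic.  When
    a nanoparticle spec is given, one copy is placed in the gas phase above
    each leaflet at the requested orientation so the system stays
    z-symmetric.
    """
    rng = np.random.default_rng(seed)
    L = mono.lateral_length(ff)
    g = mono.gas_thickness
    lh = mono.lipid_height
    w = mono.water_thickness
    Lz = 2 * g + 2 * lh + w
    if jnp is not None:
        mode = mode or PlacementMode()
        np_room = 2 * jnp.radius + mode.gap + 1.0
        if np_room > g:
            raise ValueError(
                f"gas slab ({g} R_c) cannot accommodate the nanoparticle "
                f"(needs {np_room:.1f} R_c)")
    z_wlo = g + lh
    z_whi = g + lh + w
    top = empty_topology()
    coords = np.zeros((0, 3))

    # --- lipids on a jittered lattice at both interfaces
    lip_top, lip_local = build_dppc(ff)
    nside = int(np.ceil(np.sqrt(mono.n_lipids)))
    pitch = L / nside
    sites = [(ix + 0.5, iy + 0.5) for ix in range(nside) for iy in range(nside)]
    sites = np.asarray(sites[:mono.n_lipids]) * pitch
    leaflet_coords = []
    for z_if, orient in ((z_whi, 1.0), (z_wlo, -1.0)):
        jit = rng.uniform(-0.15, 0.15, size=(mono.n_lipids, 2)) * pitch
        for il in range(mono.n_lipids):
            local = lip_local.copy()
            local[:, 2] *= orient
            ang = rng.uniform(0, 2 * np.pi)
            ca, sa = np.cos(ang), np.sin(ang)
            rot = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
            local = local @ rot.T
            xy = sites[il] + jit[il]
            local[:, 0] += xy[0]
            local[:, 1] += xy[1]
            local[:, 2] += z_if
            leaflet_coords.append(local)
    top = top.merge(replicate_molecule(lip_top, 2 * mono.n_lipids))
    coords = np.vstack([coords] + leaflet_coords)

    # --- nanoparticles in the gas phase (one per leaflet, mirrored)
    if jnp is not None:
        np_top, np_local = build_jnp(jnp, ff, seed=seed)
        tail_top = z_whi + 0.35 * lh  # approximate top of the tail region
        for orient in (1.0, -1.0):
            # LA: hydrophobic cap toward the monolayer; the cap is +z in
            # local coordinates, so point it against the outward normal
            cap_dir = -orient if mode.mode == "la" else orient
            R = _rotation_to(np.array([0.0, 0.0, cap_dir]))
            pts = np_local @ R.T
            zc = (tail_top + mode.gap + jnp.radius) if orient > 0 else \
                (Lz - (tail_top + mode.gap + jnp.radius))
            if orient < 0:
                # mirror: lower interface sits at z_wlo
                zc = z_wlo - 0.35 * lh - mode.gap - jnp.radius
            pts = pts + np.array([L / 2, L / 2, zc])
            top = top.merge(np_top)
            coords = np.vstack([coords, pts])

    # --- water slab
    n_w = int(round(ff.units.rho_W * L * L * w))
    wpos = np.column_stack([
        rng.uniform(0, L, n_w), rng.uniform(0, L, n_w),
        rng.uniform(z_wlo, z_whi, n_w)])
    # carve out head-group volume
    heads = [i for i, t in enumerate(top.types)
             if t in (TYPE_INDEX["N"], TYPE_INDEX["P"], TYPE_INDEX["G"])]
    if heads:
        ht = cKDTree(coords[heads])
        d, _ = ht.query(wpos, k=1)
        wpos = wpos[d > 0.4]
    w_top = Topology(types=np.full(len(wpos), TYPE_INDEX["W"], dtype=np.int64))
    top = top.merge(w_top)
    coords = np.vstack([coords, wpos])

    # --- gas slabs
    rho_B = float(ff.gas.get("rho_B", 1.0))
    zones = [(0.0, z_wlo - 0.2), (z_whi + 0.2, Lz)]
    gpos_all = []
    occupied = cKDTree(coords) if len(coords) else None
    for z0, z1 in zones:
        n_g = int(round(rho_B * L * L * (z1 - z0)))
        gpos = np.column_stack([
            rng.uniform(0, L, n_g), rng.uniform(0, L, n_g),
            rng.uniform(z0, z1, n_g)])
        if occupied is not None and len(gpos):
            d, _ = occupied.query(gpos, k=1)
            gpos = gpos[d > 0.6]
        gpos_all.append(gpos)
    gpos = np.vstack(gpos_all)
    g_top = Topology(types=np.full(len(gpos), TYPE_INDEX["B"], dtype=np.int64))
    top = top.merge(g_top)
    coords = np.vstack([coords, gpos])

    state = SystemState(
        positions=coords,
        velocities=np.zeros_like(coords),
        box=np.array([L, L, Lz]),
        topology=top,
        provenance={"seed": seed, "n_lipids": mono.n_lipids,
                    "area_per_lipid_nm2": mono.area_per_lipid_nm2,
                    "phi_L": None if jnp is None else jnp.phi_L,
                    "mode": None if mode is None else mode.mode},
    )
    state.thermalize(ff.units.T_DPD, seed=seed + 1)
    return state


def build_water_box(ff: ForceField, L: float = 10.0, seed: int = 0,
                    species: str = "W", rho: float | None = None,
                    Lz: float | None = None) -> SystemState:
    """Periodic bulk box of a single bead species at density rho."""
    rng = np.random.default_rng(seed)
    if rho is None:
        rho = ff.units.rho_W if species != "B" else float(ff.gas.get("rho_B", 1.0))
    Lz = L if Lz is None else Lz
    n = int(round(rho * L * L * Lz))
    pos = np.column_stack([rng.uniform(0, L, n), rng.uniform(0, L, n),
                           rng.uniform(0, Lz, n)])
    top = Topology(types=np.full(n, TYPE_INDEX[species], dtype=np.int64))
    st = SystemState(positions=pos, velocities=np.zeros((n, 3)),
                     box=np.array([L, L, Lz]), topology=top,
                     provenance={"seed": seed, "species": species, "rho": rho})
    st.thermalize(ff.units.T_DPD, seed=seed + 1)
    return st


def build_water_slab(ff: ForceField, L: float = 10.0, water_thickness: float = 10.0,
                     gas_thickness: float = 8.0, seed: int = 0) -> SystemState:
    """Water slab with gas above and below: the bare air-water interface."""
    rng = np.random.default_rng(seed)
    Lz = water_thickness + 2 * gas_thickness
    z0, z1 = gas_thickness, gas_thickness + water_thickness
    n_w = int(round(ff.units.rho_W * L * L * water_thickness))
    wpos = np.column_stack([rng.uniform(0, L, n_w), rng.uniform(0, L, n_w),
                            rng.uniform(z0, z1, n_w)])
    rho_B = float(ff.gas.get("rho_B", 1.0))
    gpos = []
    for a, b in ((0.0, z0 - 0.2), (z1 + 0.2, Lz)):
        n_g = int(round(rho_B * L * L * (b - a)))
        gpos.append(np.column_stack([rng.uniform(0, L, n_g),
                                     rng.uniform(0, L, n_g),
                                     rng.uniform(a, b, n_g)]))
    gpos = np.vstack(gpos)
    types = np.concatenate([
        np.full(len(wpos), TYPE_INDEX["W"], dtype=np.int64),
        np.full(len(gpos), TYPE_INDEX["B"], dtype=np.int64)])
    pos = np.vstack([wpos, gpos])
    st = SystemState(positions=pos, velocities=np.zeros_like(pos),
                     box=np.array([L, L, Lz]),
                     topology=Topology(types=types),
                     provenance={"seed": seed, "kind": "water-slab"})
    st.thermalize(ff.units.T_DPD, seed=seed + 1)
    return st


def scale_system(mono: MonolayerSpec, jnp: JNPSpec | None, factor: float):
    """Scale the full-size system down by an area factor.

    Lipid count and interfacial area shrink by ``factor`` (area per lipid
    preserved); the nanoparticle radius shrinks by sqrt(factor) so its
    footprint stays proportional to the interface.
    """
    if factor < 1:
        raise ValueError("scale factor must be >= 1")
    mono2 = replace(mono, n_lipids=int(round(mono.n_lipids / factor)))
    jnp2 = None
    if jnp is not None:
        r = jnp.radius / np.sqrt(factor)
        jnp2 = replace(jnp, radius=r)  # JNPSpec validates the 2-spacing floor
    return mono2, jnp2
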