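"""The DPD engine: pairwise forces, bonded terms, integrator, barostat.

Forces
------
Linear soft repulsion F = a_ij (1 - r/R_ij) r_hat for r < R_ij, plus the
pairwise dissipative force -gamma w(r)^2 (v_ij . r_hat) r_hat and random
force sigma w(r) theta_ij r_hat / sqrt(dt) with w = 1 - r/R_ij and
sigma^2 = 2 T gamma (fluctuation-dissipation).  Gas (B) pairs replace the
linear conservative term by the exponential law

    F_exp = a (e^{b r/R} - e^b) / (1 - e^b) r_hat,

which rises much more steeply at contact and supports a stable
gas-liquid interface.  Bonds and angles are restrained harmonically
(angles through the regular 1 - cos(theta - theta0) bending form).
Charged beads, when enabled, interact through a smeared-charge Coulomb
force that stays finite at r = 0.

Integration uses the modified velocity-Verlet with a lambda = 0.65
velocity prediction for the dissipative force; plain velocity-Verlet
(lambda = 0.5) is available by configuration.  The random noise is
counter-based — a hash of (seed, step, i, j) — so trajectories are
bit-reproducible and theta_ij = theta_ji holds exactly.  Pair search uses
a cell-binned Verlet list with a skin, rebuilt when any bead has moved
half the skin; periodic-image shifts are stored with each pair so the
minimum image stays exact between rebuilds.

The virial entering the pressure tensor is accumulated from the
conservative interactions only (pair + bonded + electrostatic); the
dissipative and random forces form the thermostat and average to zero
stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

SQRT3 = 1.7320508075688772

# ---------------------------------------------------------------------------
# counter-based pair noise


@njit(cache=True, fastmath=True, inline="always")
def _pair_noise(seed, step, i, j):
    """Zero-mean unit-variance uniform noise, symmetric in (i, j)."""
    if i > j:
        i, j = j, i
    h = np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
    h = (h + np.uint64(step)) * np.uint64(0xBF58476D1CE4E5B9)
    h ^= np.uint64(i) * np.uint64(0x94D049BB133111EB)
    h = (h ^ (h >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    h ^= np.uint64(j) * np.uint64(0x9E3779B97F4A7C15)
    h = (h ^ (h >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    h ^= h >> np.uint64(31)
    u = np.float64(h) * 5.421010862427522e-20  # / 2^64 -> [0, 1)
    return SQRT3 * (2.0 * u - 1.0)


@njit(cache=True, fastmath=True, inline="always")
def _tiebreak_dir(i, j):
    """Deterministic unit vector for exactly overlapping beads."""
    h = np.uint64(i * 73856093) ^ np.uint64(j * 19349663)
    h = (h ^ (h >> np.uint64(13))) * np.uint64(0x9E3779B97F4A7C15)
    x = np.float64(h & np.uint64(0xFFFF)) / 65535.0 - 0.5
    y = np.float64((h >> np.uint64(16)) & np.uint64(0xFFFF)) / 65535.0 - 0.5
    z = np.float64((h >> np.uint64(32)) & np.uint64(0xFFFF)) / 65535.0 - 0.5
    n = np.sqrt(x * x + y * y + z * z)
    if n < 1e-12:
        return 1.0, 0.0, 0.0
    return x / n, y / n, z / n


# ---------------------------------------------------------------------------
# Verlet-list construction (cell-binned, with stored image shifts)


@njit(cache=True, fastmath=True)
def _bin_beads(pos, box, cut):
    n = pos.shape[0]
    ncx = max(1, int(box[0] / cut))
    ncy = max(1, int(box[1] / cut))
    ncz = max(1, int(box[2] / cut))
    ncell = ncx * ncy * ncz
    count = np.zeros(ncell + 1, dtype=np.int64)
    cidx = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = min(max(int(pos[i, 0] / box[0] * ncx), 0), ncx - 1)
        iy = min(max(int(pos[i, 1] / box[1] * ncy), 0), ncy - 1)
        iz = min(max(int(pos[i, 2] / box[2] * ncz), 0), ncz - 1)
        c = ix + ncx * (iy + ncy * iz)
        cidx[i] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        c = cidx[i]
        order[fill[c]] = i
        fill[c] += 1
    return ncx, ncy, ncz, count, order


# forward half-stencil of 13 neighbor cells
_STENCIL = np.array([
    (1, 0, 0), (-1, 1, 0), (0, 1, 0), (1, 1, 0),
    (-1, -1, 1), (0, -1, 1), (1, -1, 1), (-1, 0, 1),
    (0, 0, 1), (1, 0, 1), (-1, 1, 1), (0, 1, 1), (1, 1, 1)],
    dtype=np.int64)


@njit(cache=True, fastmath=True)
def _build_pairs(pos, box, rlist, pair_i, pair_j, pair_shift):
    """Fill the Verlet list with all pairs closer than rlist.

    pair_shift holds the integer periodic-image multiples (sx, sy, sz) such
    that dr = r_i - r_j - s * L is the minimum image chosen at build time.
    Returns the number of pairs, or -1 if capacity was exceeded.
    """
    n = pos.shape[0]
    cap = pair_i.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    r2max = rlist * rlist
    np_count = 0
    ncx = int(box[0] / rlist)
    ncy = int(box[1] / rlist)
    ncz = int(box[2] / rlist)
    if ncx >= 3 and ncy >= 3 and ncz >= 3:
        ncx, ncy, ncz, start, order = _bin_beads(pos, box, rlist)
        for cz in range(ncz):
            for cy in range(ncy):
                for cx in range(ncx):
                    c = cx + ncx * (cy + ncy * cz)
                    for ii in range(start[c], start[c + 1]):
                        i = order[ii]
                        for jj in range(ii + 1, start[c + 1]):
                            j = order[jj]
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if dx * dx + dy * dy + dz * dz < r2max:
                                if np_count >= cap:
                                    return -1
                                pair_i[np_count] = i
                                pair_j[np_count] = j
                                pair_shift[np_count, 0] = 0
                                pair_shift[np_count, 1] = 0
                                pair_shift[np_count, 2] = 0
                                np_count += 1
                    for s in range(13):
                        nx = cx + _STENCIL[s, 0]
                        ny = cy + _STENCIL[s, 1]
                        nz = cz + _STENCIL[s, 2]
                        sx = 0
                        sy = 0
                        sz = 0
                        if nx < 0:
                            nx += ncx
                            sx = -1
                        elif nx >= ncx:
                            nx -= ncx
                            sx = 1
                        if ny < 0:
                            ny += ncy
                            sy = -1
                        elif ny >= ncy:
                            ny -= ncy
                            sy = 1
                        if nz < 0:
                            nz += ncz
                            sz = -1
                        elif nz >= ncz:
                            nz -= ncz
                            sz = 1
                        c2 = nx + ncx * (ny + ncy * nz)
                        shx = sx * lx
                        shy = sy * ly
                        shz = sz * lz
                        for ii in range(start[c], start[c + 1]):
                            i = order[ii]
                            pix = pos[i, 0] - shx
                            piy = pos[i, 1] - shy
                            piz = pos[i, 2] - shz
                            for jj in range(start[c2], start[c2 + 1]):
                                j = order[jj]
                                dx = pix - pos[j, 0]
                                dy = piy - pos[j, 1]
                                dz = piz - pos[j, 2]
                                if dx * dx + dy * dy + dz * dz < r2max:
                                    if np_count >= cap:
                                        return -1
                                    pair_i[np_count] = i
                                    pair_j[np_count] = j
                                    pair_shift[np_count, 0] = sx
                                    pair_shift[np_count, 1] = sy
                                    pair_shift[np_count, 2] = sz
                                    np_count += 1
    else:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                kx = np.round(dx / lx)
                ky = np.round(dy / ly)
                kz = np.round(dz / lz)
                dx -= lx * kx
                dy -= ly * ky
                dz -= lz * kz
                if dx * dx + dy * dy + dz * dz < r2max:
                    if np_count >= cap:
                        return -1
                    pair_i[np_count] = i
                    pair_j[np_count] = j
                    pair_shift[np_count, 0] = np.int8(kx)
                    pair_shift[np_count, 1] = np.int8(ky)
                    pair_shift[np_count, 2] = np.int8(kz)
                    np_count += 1
    return np_count


@njit(cache=True, fastmath=True)
def _pair_forces(pos, vel, types, box, pair_i, pair_j, pair_shift, npairs,
                 A, RT, GAM, SIG, BEXP, inv_sqrt_dt, seed, step,
                 forces, out):
    forces[:] = 0.0
    wxx = wyy = wzz = pe = 0.0
    lx, ly, lz = box[0], box[1], box[2]
    for p in range(npairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0] - pair_shift[p, 0] * lx
        dy = pos[i, 1] - pos[j, 1] - pair_shift[p, 1] * ly
        dz = pos[i, 2] - pos[j, 2] - pair_shift[p, 2] * lz
        r2 = dx * dx + dy * dy + dz * dz
        ti = types[i]
        tj = types[j]
        Rij = RT[ti, tj]
        if r2 >= Rij * Rij:
            continue
        r = np.sqrt(r2)
        if r < 1e-10:
            ex, ey, ez = _tiebreak_dir(i, j)
            r = 0.0
        else:
            inv_r = 1.0 / r
            ex = dx * inv_r
            ey = dy * inv_r
            ez = dz * inv_r
        w = 1.0 - r / Rij
        a = A[ti, tj]
        b = BEXP[ti, tj]
        if b != 0.0:
            eb = np.exp(b)
            ebr = np.exp(b * r / Rij)
            fc = a * (ebr - eb) / (1.0 - eb)
            pe += a / (1.0 - eb) * ((r - Rij) * eb + Rij / b * (eb - ebr))
        else:
            fc = a * w
            pe += 0.5 * a * Rij * w * w
        vdotr = ((vel[i, 0] - vel[j, 0]) * ex + (vel[i, 1] - vel[j, 1]) * ey
                 + (vel[i, 2] - vel[j, 2]) * ez)
        fd = -GAM[ti, tj] * w * w * vdotr
        fr = SIG[ti, tj] * w * _pair_noise(seed, step, i, j) * inv_sqrt_dt
        ftot = fc + fd + fr
        fx = ftot * ex
        fy = ftot * ey
        fz = ftot * ez
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        wxx += fc * ex * dx
        wyy += fc * ey * dy
        wzz += fc * ez * dz
    out[0] = wxx
    out[1] = wyy
    out[2] = wzz
    out[3] = pe


@njit(cache=True, fastmath=True)
def _bonded_forces(pos, box, bonds, bond_k, bond_r0,
                   angles, angle_k, angle_t0, forces, out):
    """Harmonic bonds and 1-cos(theta-theta0) bending; adds to forces/out."""
    lx, ly, lz = box[0], box[1], box[2]
    wxx = wyy = wzz = pe = 0.0
    for nb in range(bonds.shape[0]):
        i = bonds[nb, 0]
        j = bonds[nb, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= lx * np.round(dx / lx)
        dy -= ly * np.round(dy / ly)
        dz -= lz * np.round(dz / lz)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-10:
            ex, ey, ez = _tiebreak_dir(i, j)
            r = 1e-10
        else:
            ex, ey, ez = dx / r, dy / r, dz / r
        k = bond_k[nb]
        dr = r - bond_r0[nb]
        f = -k * dr
        forces[i, 0] += f * ex
        forces[i, 1] += f * ey
        forces[i, 2] += f * ez
        forces[j, 0] -= f * ex
        forces[j, 1] -= f * ey
        forces[j, 2] -= f * ez
        wxx += f * ex * dx
        wyy += f * ey * dy
        wzz += f * ez * dz
        pe += 0.5 * k * dr * dr
    for na in range(angles.shape[0]):
        i = angles[na, 0]
        j = angles[na, 1]
        k2 = angles[na, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k2, 0] - pos[j, 0]
        by = pos[k2, 1] - pos[j, 1]
        bz = pos[k2, 2] - pos[j, 2]
        ax -= lx * np.round(ax / lx)
        ay -= ly * np.round(ay / ly)
        az -= lz * np.round(az / lz)
        bx -= lx * np.round(bx / lx)
        by -= ly * np.round(by / ly)
        bz -= lz * np.round(bz / lz)
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rb = np.sqrt(bx * bx + by * by + bz * bz)
        if ra < 1e-10 or rb < 1e-10:
            continue
        ct = (ax * bx + ay * by + az * bz) / (ra * rb)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-6:
            st = 1e-6
        ka = angle_k[na]
        t0 = angle_t0[na]
        pe += ka * (1.0 - np.cos(theta - t0))
        # dU/d(cos theta) = -k sin(theta - t0) / sin(theta); regular at
        # theta -> t0 = pi, the only equilibrium used by the templates
        dudc = -ka * np.sin(theta - t0) / st
        gix = (bx / (ra * rb)) - ct * ax / (ra * ra)
        giy = (by / (ra * rb)) - ct * ay / (ra * ra)
        giz = (bz / (ra * rb)) - ct * az / (ra * ra)
        gkx = (ax / (ra * rb)) - ct * bx / (rb * rb)
        gky = (ay / (ra * rb)) - ct * by / (rb * rb)
        gkz = (az / (ra * rb)) - ct * bz / (rb * rb)
        fix = -dudc * gix
        fiy = -dudc * giy
        fiz = -dudc * giz
        fkx = -dudc * gkx
        fky = -dudc * gky
        fkz = -dudc * gkz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k2, 0] += fkx
        forces[k2, 1] += fky
        forces[k2, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        wxx += fix * ax + fkx * bx
        wyy += fiy * ay + fky * by
        wzz += fiz * az + fkz * bz
    out[0] += wxx
    out[1] += wyy
    out[2] += wzz
    out[3] += pe


@njit(cache=True, fastmath=True)
def _coulomb_forces(pos, box, charges, coul_const, lam, rcut, forces, out):
    """Direct-sum smeared-charge Coulomb (Slater smearing), finite at r=0."""
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    wxx = wyy = wzz = pe = 0.0
    for i in range(n):
        qi = charges[i]
        if qi == 0.0:
            continue
        for j in range(i + 1, n):
            qj = charges[j]
            if qj == 0.0:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= lx * np.round(dx / lx)
            dy -= ly * np.round(dy / ly)
            dz -= lz * np.round(dz / lz)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rcut * rcut or r2 < 1e-20:
                continue
            r = np.sqrt(r2)
            x = r / lam
            damp = 1.0 - np.exp(-2.0 * x) * (1.0 + 2.0 * x * (1.0 + x))
            f = coul_const * qi * qj / r2 * damp
            pe += coul_const * qi * qj / r * (1.0 - np.exp(-2.0 * x) * (1.0 + x))
            fx = f * dx / r
            fy = f * dy / r
            fz = f * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            wxx += fx * dx
            wyy += fy * dy
            wzz += fz * dz
    out[0] += wxx
    out[1] += wyy
    out[2] += wzz
    out[3] += pe


@njit(cache=True, fastmath=True)
def _wrap(pos, box):
    n = pos.shape[0]
    for i in range(n):
        for d in range(3):
            pos[i, d] -= box[d] * np.floor(pos[i, d] / box[d])


@njit(cache=True)
def _state_sane(pos, vel):
    # deliberately compiled without fastmath: the nnan/ninf assumptions
    # would let LLVM fold isfinite checks to a constant.  Velocities far
    # beyond any thermal scale are treated as a blow-up as well.
    s = 0.0
    m = 0.0
    for i in range(pos.shape[0]):
        s += pos[i, 0] + pos[i, 1] + pos[i, 2]
        for d in range(3):
            a = abs(vel[i, d])
            if a > m:
                m = a
    return np.isfinite(s) and np.isfinite(m) and m < 1e6


@njit(cache=True, fastmath=True)
def _max_disp2(pos, ref):
    m = 0.0
    for i in range(pos.shape[0]):
        d2 = ((pos[i, 0] - ref[i, 0]) ** 2 + (pos[i, 1] - ref[i, 1]) ** 2
              + (pos[i, 2] - ref[i, 2]) ** 2)
        if d2 > m:
            m = d2
    return m


@njit(cache=True, fastmath=True)
def _integrate(pos, vel, mass, types, box,
               A, RT, GAM, SIG, BEXP,
               bonds, bond_k, bond_r0, angles, angle_k, angle_t0,
               charges, use_coulomb, coul_const, coul_lam, coul_rcut,
               dt, lam, nsteps, seed, step0,
               npt_mode, p_target, tau_p, skin,
               sample_every, obs, traj_every, traj_pos, traj_box):
    """Main integration loop; fills obs and trajectory arrays in place.

    npt_mode: 0 = NVT, 1 = isotropic Berendsen, 2 = semi-isotropic (x=y
    coupled to the lateral pressure, z to the normal component).
    Returns (status, n_obs, n_traj); status 1 flags non-finite coordinates.
    """
    n = pos.shape[0]
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    max_cut = RT.max()
    rlist = max_cut + skin
    cap = max(64, int(n * 40))
    pair_i = np.empty(cap, dtype=np.int32)
    pair_j = np.empty(cap, dtype=np.int32)
    pair_shift = np.zeros((cap, 3), dtype=np.int8)
    forces = np.zeros((n, 3))
    fold = np.zeros((n, 3))
    vtil = np.zeros((n, 3))
    out = np.zeros(4)
    _wrap(pos, box)
    ref = pos.copy()
    npairs = _build_pairs(pos, box, rlist, pair_i, pair_j, pair_shift)
    if npairs < 0:
        return 2, 0, 0
    _pair_forces(pos, vel, types, box, pair_i, pair_j, pair_shift, npairs,
                 A, RT, GAM, SIG, BEXP, inv_sqrt_dt, seed, step0, forces, out)
    _bonded_forces(pos, box, bonds, bond_k, bond_r0, angles, angle_k,
                   angle_t0, forces, out)
    if use_coulomb:
        _coulomb_forces(pos, box, charges, coul_const, coul_lam, coul_rcut,
                        forces, out)
    n_obs = 0
    n_traj = 0
    half_skin2 = (0.5 * skin) ** 2
    for s in range(nsteps):
        step = step0 + s
        for i in range(n):
            im = 1.0 / mass[i]
            for d in range(3):
                pos[i, d] += dt * vel[i, d] + 0.5 * dt * dt * forces[i, d] * im
                vtil[i, d] = vel[i, d] + lam * dt * forces[i, d] * im
                fold[i, d] = forces[i, d]
        if _max_disp2(pos, ref) > half_skin2:
            _wrap(pos, box)
            ref[:] = pos
            npairs = _build_pairs(pos, box, rlist, pair_i, pair_j, pair_shift)
            if npairs < 0:
                return 2, n_obs, n_traj
        _pair_forces(pos, vtil, types, box, pair_i, pair_j, pair_shift,
                     npairs, A, RT, GAM, SIG, BEXP, inv_sqrt_dt, seed,
                     step + 1, forces, out)
        _bonded_forces(pos, box, bonds, bond_k, bond_r0, angles, angle_k,
                       angle_t0, forces, out)
        if use_coulomb:
            _coulomb_forces(pos, box, charges, coul_const, coul_lam,
                            coul_rcut, forces, out)
        for i in range(n):
            im = 1.0 / mass[i]
            for d in range(3):
                vel[i, d] += 0.5 * dt * (fold[i, d] + forces[i, d]) * im
        vol = box[0] * box[1] * box[2]
        kxx = kyy = kzz = 0.0
        for i in range(n):
            kxx += mass[i] * vel[i, 0] * vel[i, 0]
            kyy += mass[i] * vel[i, 1] * vel[i, 1]
            kzz += mass[i] * vel[i, 2] * vel[i, 2]
        pxx = (kxx + out[0]) / vol
        pyy = (kyy + out[1]) / vol
        pzz = (kzz + out[2]) / vol
        if npt_mode > 0:
            if npt_mode == 1:
                pinst = (pxx + pyy + pzz) / 3.0
                mu = 1.0 - dt / tau_p * (p_target - pinst)
                mu = min(max(mu, 0.999), 1.001) ** (1.0 / 3.0)
                for d in range(3):
                    box[d] *= mu
                for i in range(n):
                    for d in range(3):
                        pos[i, d] *= mu
                        ref[i, d] *= mu
            else:
                # mode 2: x=y from the lateral pressure; mode 3: z only
                # (constant interfacial area, the relaxation used for
                # monolayer systems built at fixed area per lipid)
                if npt_mode == 2:
                    plat = 0.5 * (pxx + pyy)
                    mul = np.sqrt(min(max(1.0 - dt / tau_p * (p_target - plat),
                                          0.999), 1.001))
                else:
                    mul = 1.0
                muz = min(max(1.0 - dt / tau_p * (p_target - pzz),
                              0.999), 1.001)
                box[0] *= mul
                box[1] *= mul
                box[2] *= muz
                for i in range(n):
                    pos[i, 0] *= mul
                    pos[i, 1] *= mul
                    pos[i, 2] *= muz
                    ref[i, 0] *= mul
                    ref[i, 1] *= mul
                    ref[i, 2] *= muz
        if sample_every > 0 and (s + 1) % sample_every == 0 and n_obs < obs.shape[0]:
            px = py = pz = ke = 0.0
            for i in range(n):
                px += mass[i] * vel[i, 0]
                py += mass[i] * vel[i, 1]
                pz += mass[i] * vel[i, 2]
                ke += mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                 + vel[i, 2] ** 2)
            obs[n_obs, 0] = step + 1
            obs[n_obs, 1] = ke / (3.0 * n)
            obs[n_obs, 2] = pxx
            obs[n_obs, 3] = pyy
            obs[n_obs, 4] = pzz
            obs[n_obs, 5] = out[3]
            obs[n_obs, 6] = px
            obs[n_obs, 7] = py
            obs[n_obs, 8] = pz
            obs[n_obs, 9] = box[0]
            obs[n_obs, 10] = box[1]
            obs[n_obs, 11] = box[2]
            n_obs += 1
            if not _state_sane(pos, vel):
                return 1, n_obs, n_traj
        if traj_every > 0 and (s + 1) % traj_every == 0 and n_traj < traj_pos.shape[0]:
            for i in range(n):
                for d in range(3):
                    traj_pos[n_traj, i, d] = pos[i, d]
            for d in range(3):
                traj_box[n_traj, d] = box[d]
            n_traj += 1
    _wrap(pos, box)
    if not _state_sane(pos, vel):
        return 1, n_obs, n_traj
    return 0, n_obs, n_traj


# ---------------------------------------------------------------------------
# public API

OBS_COLUMNS = ["step", "T_kin", "Pxx", "Pyy", "Pzz", "PE",
               "px", "py", "pz", "Lx", "Ly", "Lz"]


@dataclass
class EngineConfig:
    """Integration settings (reduced units).

    ``pressure`` is the barostat target in k_BT/R_c^3 (the convention in
    which bulk water sits at 23.7); it is converted to internal units with
    the force field's energy scale.  ``skin`` is the Verlet-list margin
    beyond the largest pair cutoff.  ``semi_isotropic`` couples x=y to the
    lateral pressure and z to the normal component, appropriate once
    interfaces are present.
    """

    dt: float = 0.01
    lambda_v: float = 0.65
    seed: int = 0
    ensemble: str = "nvt"
    pressure: float = 23.7
    tau_p: float = 1.0
    barostat_coupling: str = "iso"  # 'iso' | 'semi' | 'z'
    skin: float = 0.3
    sample_every: int = 50
    traj_every: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        if self.ensemble not in ("nvt", "npt"):
            raise ValueError("ensemble must be 'nvt' or 'npt'")
        if self.barostat_coupling not in ("iso", "semi", "z"):
            raise ValueError("barostat_coupling must be iso, semi or z")


@dataclass
class PressureTensor:
    """Diagonal pressure tensor with kinetic/virial split (internal units)."""

    kinetic: np.ndarray
    virial: np.ndarray
    time: float = 0.0

    @property
    def total(self) -> np.ndarray:
        return self.kinetic + self.virial

    @property
    def isotropic(self) -> float:
        return float(self.total.mean())


def pair_conservative(r: float, a: float, R: float = 1.0) -> float:
    """Magnitude of the linear soft repulsion at separation r."""
    if r >= R:
        return 0.0
    return a * (1.0 - r / R)


def pair_exponential(r: float, a: float, b: float, R: float = 1.0) -> float:
    """Magnitude of the exponential gas force at separation r."""
    if b == 0.0:
        raise ValueError("b=0 is degenerate for the exponential force")
    if r >= R:
        return 0.0
    eb = np.exp(b)
    return a * (np.exp(b * r / R) - eb) / (1.0 - eb)


def pair_dissipative_random(r, v_rel_along_r, gamma, sigma, theta, dt, R=1.0):
    """Combined dissipative + random magnitude along r_hat at separation r."""
    if r >= R:
        return 0.0
    w = 1.0 - r / R
    return -gamma * w * w * v_rel_along_r + sigma * w * theta / np.sqrt(dt)


class DPDEngine:
    """Drives a SystemState forward in time under a force field."""

    def __init__(self, state, forcefield, config: EngineConfig | None = None):
        self.state = state
        self.ff = forcefield
        self.config = config or EngineConfig()
        es = forcefield.electrostatics or {}
        self._use_coulomb = bool(es.get("enabled", False)) and bool(
            np.any(state.topology.charges != 0.0))
        self._coul_const = float(es.get("coulomb_constant", 13.87)) * \
            forcefield.energy_scale
        self._coul_lam = float(es.get("smearing_length", 0.67))
        self._coul_rcut = float(es.get("cutoff", 3.0))
        if self._use_coulomb and abs(float(np.sum(state.topology.charges))) > 1e-9:
            import warnings

            warnings.warn("system carries a net charge; direct-sum "
                          "electrostatics will be conditionally convergent")
        self._step_count = 0

    def run(self, nsteps: int, ensemble: str | None = None,
            sample_every: int | None = None, traj_every: int | None = None,
            mass_scale: np.ndarray | None = None):
        """Advance ``nsteps``; returns (obs DataFrame, (traj_pos, traj_box)).

        ``mass_scale`` multiplies per-bead masses for the duration of the
        call (the 'freeze' trick used during staged equilibration).
        Observable pressures/energies are reported in k_BT units.
        """
        import pandas as pd

        st = self.state
        top = st.topology
        cfg = self.config
        ens = ensemble or cfg.ensemble
        se = cfg.sample_every if sample_every is None else sample_every
        te = cfg.traj_every if traj_every is None else traj_every
        mass = st.masses.copy()
        if mass_scale is not None:
            mass = mass * mass_scale
        n_obs = nsteps // se if se > 0 else 0
        n_traj = nsteps // te if te > 0 else 0
        obs = np.zeros((max(n_obs, 1), len(OBS_COLUMNS)))
        traj_pos = np.zeros((max(n_traj, 1), st.n_beads, 3))
        traj_box = np.zeros((max(n_traj, 1), 3))
        npt_mode = 0 if ens == "nvt" else \
            {"iso": 1, "semi": 2, "z": 3}[cfg.barostat_coupling]
        tab = self.ff.table
        status, got_obs, got_traj = _integrate(
            st.positions, st.velocities, mass, st.types, st.box,
            tab.a, tab.R, tab.gamma, tab.sigma, tab.b,
            top.bonds, top.bond_k, top.bond_r0,
            top.angles, top.angle_k, top.angle_theta0,
            top.charges, self._use_coulomb, self._coul_const,
            self._coul_lam, self._coul_rcut,
            cfg.dt, cfg.lambda_v, nsteps, cfg.seed, self._step_count,
            npt_mode, cfg.pressure * self.ff.energy_scale, cfg.tau_p,
            cfg.skin, se, obs, te, traj_pos, traj_box)
        self._step_count += nsteps
        st.time += nsteps * cfg.dt
        if status == 2:
            raise RuntimeError("Verlet-list capacity exceeded; the system "
                               "has collapsed to unphysical density")
        if status != 0:
            raise RuntimeError(
                f"non-finite coordinates after step {self._step_count}; "
                "the timestep or parameterization is unstable")
        df = pd.DataFrame(obs[:got_obs], columns=OBS_COLUMNS)
        df["time"] = df["step"] * cfg.dt
        # report energies/pressures in k_BT units
        esc = self.ff.energy_scale
        for col in ("Pxx", "Pyy", "Pzz", "PE"):
            df[col] = df[col] / esc
        return df, (traj_pos[:got_traj], traj_box[:got_traj])

    def compute_forces(self):
        """One-shot deterministic force evaluation (no noise).

        Returns (forces, PressureTensor in k_BT units).
        """
        st = self.state
        top = st.topology
        tab = self.ff.table
        n = st.n_beads
        forces = np.zeros((n, 3))
        out = np.zeros(4)
        cap = max(64, int(n * 60))
        pair_i = np.empty(cap, dtype=np.int32)
        pair_j = np.empty(cap, dtype=np.int32)
        pair_shift = np.zeros((cap, 3), dtype=np.int8)
        npairs = _build_pairs(st.positions, st.box, tab.max_cutoff,
                              pair_i, pair_j, pair_shift)
        if npairs < 0:
            raise RuntimeError("pair capacity exceeded")
        _pair_forces(st.positions, st.velocities, st.types, st.box,
                     pair_i, pair_j, pair_shift, npairs,
                     tab.a, tab.R, tab.gamma, np.zeros_like(tab.sigma),
                     tab.b, 1.0, 0, 0, forces, out)
        _bonded_forces(st.positions, st.box, top.bonds, top.bond_k,
                       top.bond_r0, top.angles, top.angle_k,
                       top.angle_theta0, forces, out)
        if self._use_coulomb:
            _coulomb_forces(st.positions, st.box, top.charges,
                            self._coul_const, self._coul_lam,
                            self._coul_rcut, forces, out)
        vol = float(np.prod(st.box))
        esc = self.ff.energy_scale
        kin = np.array([
            np.sum(st.masses * st.velocities[:, 0] ** 2),
            np.sum(st.masses * st.velocities[:, 1] ** 2),
            np.sum(st.masses * st.velocities[:, 2] ** 2),
        ]) / vol
        vir = out[:3] / vol
        return forces, PressureTensor(kinetic=kin / esc, virial=vir / esc)


def neighbor_pairs(positions: np.ndarray, box: np.ndarray, cutoff: float) -> set:
    """All periodic-image pairs within ``cutoff``.

    Uses the engine's cell-binned pair search (zero skin); raises if the
    box is smaller than the cutoff in any dimension.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box < cutoff):
        raise ValueError("box smaller than the interaction cutoff")
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    n = positions.shape[0]
    if n == 0:
        return set()
    wrapped = positions - box * np.floor(positions / box)
    cap = max(64, n * 200)
    pair_i = np.empty(cap, dtype=np.int32)
    pair_j = np.empty(cap, dtype=np.int32)
    pair_shift = np.zeros((cap, 3), dtype=np.int8)
    npairs = _build_pairs(wrapped, box, cutoff, pair_i, pair_j, pair_shift)
    if npairs < 0:
        raise RuntimeError("pair capacity exceeded")
    return {(min(int(pair_i[p]), int(pair_j[p])),
             max(int(pair_i[p]), int(pair_j[p]))) for p in range(npairs)}
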