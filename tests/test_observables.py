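"""Orientation, tension, order-parameter, area and lipid-loss observables."""

import numpy as np
import pandas as pd
import pytest

from jmdpd.builders import (JNPSpec, MonolayerSpec, PlacementMode, build_dppc,
                            build_jnp, build_system, replicate_molecule)
from jmdpd.observables import (AreaStats, block_average, effective_area,
                               lipid_loss, np_interfacial_area, orientation,
                               surface_tension, tail_order, tension_series)
from jmdpd.state import SystemState
from jmdpd.topology import TYPE_INDEX, Topology
from jmdpd.units import UnitSystem


def _np_in_water(ff, theta_deg, radius=3.0, phi=0.5, z_np=16.0):
    """Synthetic scene: water slab below, a tilted Janus NP above."""
    top_np, pts = build_jnp(JNPSpec(radius=radius, phi_L=phi), ff)
    t = np.deg2rad(180.0 - theta_deg)  # cap axis is the L side (=-u)
    rot = np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0],
                    [-np.sin(t), 0, np.cos(t)]])
    pts = pts @ rot.T + np.array([10.0, 10.0, z_np])
    nW = 600
    rng = np.random.default_rng(0)
    wpos = np.column_stack([rng.uniform(0, 20, nW), rng.uniform(0, 20, nW),
                            rng.uniform(4.0, 10.0, nW)])
    top_w = Topology(types=np.full(nW, TYPE_INDEX["W"], dtype=np.int64))
    top = top_w.merge(top_np)
    pos = np.vstack([wpos, pts])
    return SystemState(positions=pos, velocities=np.zeros_like(pos),
                       box=np.array([20.0, 20.0, 24.0]), topology=top)


class TestOrientation:
    @pytest.mark.parametrize("theta", [0.0, 90.0, 180.0])
    def test_angle_recovered(self, ff, theta):
        st = _np_in_water(ff, theta)
        o = orientation(st.positions, st.topology, st.box, np_index=0)
        assert o.theta_deg == pytest.approx(theta, abs=2.0)

    def test_uniform_particle_is_undefined(self, ff):
        st = _np_in_water(ff, 0.0, phi=0.0)
        with pytest.raises(ValueError, match="uniform"):
            orientation(st.positions, st.topology, st.box, np_index=0)

    def test_director_is_unit(self, ff):
        st = _np_in_water(ff, 37.0)
        o = orientation(st.positions, st.topology, st.box, np_index=0)
        assert np.linalg.norm(o.director) == pytest.approx(1.0, rel=1e-9)


class TestSurfaceTension:
    def test_isotropic_tensor_gives_zero(self):
        u = UnitSystem()
        rec = surface_tension(2.0, 2.0, 2.0, L_z=30.0, units=u)
        assert rec.gamma_m == pytest.approx(0.0)

    def test_arithmetic_example(self):
        u = UnitSystem()
        rec = surface_tension(0.0, 0.0, 1.0, L_z=10.0, units=u)
        assert rec.gamma_m == pytest.approx(5.0)

    def test_pressure_tension_identity(self):
        """Pi + gamma_m = gamma0 identically, per record."""
        u = UnitSystem(gamma0_reduced=7.55)
        for pzz in (0.0, 0.3, -1.1):
            rec = surface_tension(0.1, 0.2, pzz, L_z=25.0, units=u)
            assert rec.Pi + rec.gamma_m == pytest.approx(7.55, rel=1e-12)

    def test_series_matches_scalar(self):
        u = UnitSystem(gamma0_reduced=7.55)
        obs = pd.DataFrame({"time": [0.0, 1.0], "step": [0, 50],
                            "Pxx": [0.1, 0.2], "Pyy": [0.1, 0.0],
                            "Pzz": [0.5, 0.4], "Lz": [20.0, 20.0]})
        ts = tension_series(obs, u)
        rec = surface_tension(0.1, 0.1, 0.5, 20.0, u)
        assert ts["gamma_m"].iloc[0] == pytest.approx(rec.gamma_m)


def _monolayer_scene(ff, tilt_deg=0.0, n=16):
    """Small double monolayer with deterministic straight lipids."""
    mono = MonolayerSpec(n_lipids=n, water_thickness=5.0, gas_thickness=5.0)
    st = build_system(ff, mono, seed=4)
    return st, mono


class TestTailOrder:
    def test_straight_tails_have_unit_order(self, ff):
        st, _ = _monolayer_scene(ff)
        ps = tail_order(st.positions, st.topology, st.box)
        # builder places perfectly straight vertical tails
        assert ps.S.min() == pytest.approx(1.0, abs=1e-9)

    def test_perpendicular_tails(self, ff):
        st, _ = _monolayer_scene(ff)
        pos = st.positions.copy()
        # rotate every lipid's beads about its phosphate to lie in-plane
        for beads in st.topology.lipids:
            beads = np.asarray(beads)
            ref = pos[beads[0]].copy()
            local = pos[beads] - ref
            local = local[:, [2, 1, 0]] * np.array([1.0, 1.0, 0.0])
            pos[beads] = ref + local
        ps = tail_order(pos, st.topology, st.box)
        assert np.allclose(ps.S, -0.5, atol=1e-9)

    def test_isotropic_tails_average_to_zero(self, rng):
        """Monte-Carlo oracle: <(3cos^2 t - 1)/2> = 0 for isotropic vectors."""
        v = rng.normal(size=(10000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        S = 0.5 * (3 * v[:, 2] ** 2 - 1)
        assert S.mean() == pytest.approx(0.0, abs=0.02)

    def test_f_lc_rises_when_area_shrinks(self, ff):
        """Excluded area raises the LC density at fixed LC count."""
        st, _ = _monolayer_scene(ff)
        a = tail_order(st.positions, st.topology, st.box, A_I=0.0)
        b = tail_order(st.positions, st.topology, st.box, A_I=10.0)
        assert b.f_lc > a.f_lc
        assert b.A_res == pytest.approx(a.A_res - 10.0)


class TestInterfacialArea:
    def _scene(self, ff, d):
        """NP center displaced d above the (upper) interface plane."""
        mono = MonolayerSpec(n_lipids=16, water_thickness=5.0,
                             gas_thickness=8.0)
        st = build_system(ff, mono, JNPSpec(radius=2.5, phi_L=0.5),
                          PlacementMode(), seed=5)
        top = st.topology
        beads = np.asarray(top.nps[0])
        from jmdpd.observables import interface_planes, unwrap_group
        z_up, _ = interface_planes(st.positions, top, st.box)
        pts = unwrap_group(st.positions[beads], st.box)
        shift = (z_up + d) - pts[:, 2].mean()
        st.positions[beads, 2] = pts[:, 2] + shift
        return st

    def test_center_on_plane_gives_great_circle(self, ff):
        st = self._scene(ff, 0.0)
        A = np_interfacial_area(st.positions, st.topology, st.box)
        assert A == pytest.approx(np.pi * 2.5**2, rel=0.05)

    def test_far_particle_occupies_nothing(self, ff):
        st = self._scene(ff, 4.0)
        assert np_interfacial_area(st.positions, st.topology, st.box) == 0.0

    def test_half_radius_cross_section(self, ff):
        st = self._scene(ff, 1.25)
        A = np_interfacial_area(st.positions, st.topology, st.box)
        assert A == pytest.approx(0.75 * np.pi * 2.5**2, rel=0.08)

    def test_bead_method_same_order_of_magnitude(self, ff):
        st = self._scene(ff, 0.0)
        Ag = np_interfacial_area(st.positions, st.topology, st.box)
        Ab = np_interfacial_area(st.positions, st.topology, st.box,
                                 method="beads")
        assert 0.5 * Ag < Ab < 2.5 * Ag


class TestLipidLoss:
    def test_intact_monolayer_loses_nothing(self, ff):
        st, _ = _monolayer_scene(ff, n=25)
        n_lost, status = lipid_loss(st.positions, st.topology, st.box)
        assert n_lost == 0
        assert (status == 0).all()

    def test_single_detached_lipid_counted(self, ff):
        st, _ = _monolayer_scene(ff, n=25)
        pos = st.positions.copy()
        beads = np.asarray(st.topology.lipids[0])
        pos[beads, 2] -= 5.0  # push into the water slab
        pos[beads, 0] += 2.0
        n_lost, status = lipid_loss(pos, st.topology, st.box)
        assert n_lost == 1
        assert status[0] == 1

    def test_synthetic_micelle_counted_entirely(self, ff):
        """20 lipids clustered mid-water are all lost (cluster census)."""
        lip, coords = build_dppc(ff)
        n_mic = 20
        top = replicate_molecule(lip, n_mic)
        rng = np.random.default_rng(6)
        pts = []
        for i in range(n_mic):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            c = coords.copy()
            # point tails inward to mimic a micelle core
            z = c[:, 2].copy()
            c = np.column_stack([c[:, 0], c[:, 1], np.zeros(14)]) + \
                np.outer(-z, u)
            # keep the whole micelle in the upper half of the water slab so
            # every member competes with the monolayer's leaflet cluster
            pts.append(c + np.array([10.0, 10.0, 13.0]) + u * 1.2)
        mic_pos = np.vstack(pts)
        # large monolayer far above acts as the main cluster
        mono_top = replicate_molecule(lip, 30)
        mono_pos = []
        for i in range(30):
            c = coords.copy()
            c[:, 0] += (i % 6) * 0.9 + 2.0
            c[:, 1] += (i // 6) * 0.9 + 2.0
            c[:, 2] += 16.0
            mono_pos.append(c)
        nW = 300
        w = np.column_stack([rng.uniform(0, 20, nW), rng.uniform(0, 20, nW),
                             rng.uniform(6, 14, nW)])
        topW = Topology(types=np.full(nW, TYPE_INDEX["W"], dtype=np.int64))
        top_all = topW.merge(top).merge(mono_top)
        pos = np.vstack([w, mic_pos, np.vstack(mono_pos)])
        st = SystemState(positions=pos, velocities=np.zeros_like(pos),
                         box=np.array([20.0, 20.0, 22.0]), topology=top_all)
        n_lost, status = lipid_loss(st.positions, st.topology, st.box)
        assert n_lost == n_mic
        assert (status[:n_mic] == 1).all()


class TestEffectiveArea:
    def test_reduces_to_plain_area_per_lipid(self):
        u = UnitSystem()
        a = effective_area(840 / u.R_c**2, 0.0, 1400, 0, units=u)
        assert a.a_eff_nm2 == pytest.approx(0.6, rel=1e-9)

    def test_np_footprint_shrinks_area(self):
        """12-nm particle equator (~113 nm^2) on the full system."""
        u = UnitSystem()
        A_I = 113.0 / u.R_c**2
        a = effective_area(840 / u.R_c**2, A_I, 1400, 0, units=u)
        assert a.a_eff_nm2 == pytest.approx((840 - 113) / 1400, rel=1e-9)
        assert a.a_eff_nm2 == pytest.approx(0.519, abs=5e-4)

    def test_lipid_loss_grows_area(self):
        u = UnitSystem()
        a = effective_area(840 / u.R_c**2, 0.0, 1400, 100, units=u)
        assert a.a_eff_nm2 == pytest.approx(840 / 1300, rel=1e-9)
        assert a.a_eff_nm2 == pytest.approx(0.646, abs=5e-4)

    def test_no_residual_lipids_rejected(self):
        with pytest.raises(ValueError):
            effective_area(100.0, 0.0, 10, 10)


class TestBlockAverage:
    def test_constant_series(self):
        m, e = block_average(np.full(100, 3.3))
        assert m == pytest.approx(3.3)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_error_shrinks_with_length(self, rng):
        x = rng.normal(size=4000)
        _, e1 = block_average(x[:400])
        _, e2 = block_average(x)
        assert e2 < e1
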