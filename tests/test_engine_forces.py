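"""Pairwise, bonded and electrostatic force laws, and the pair search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jmdpd import DPDEngine, EngineConfig, SystemState
from jmdpd.engine import (neighbor_pairs, pair_conservative,
                          pair_dissipative_random, pair_exponential)
from jmdpd.forcefield import load_forcefield
from jmdpd.surface_energy import potential_exponential, potential_linear
from jmdpd.topology import TYPE_INDEX, Topology


class TestPairLaws:
    @pytest.mark.parametrize("r,expected", [(0.0, 25.0), (1.0, 0.0),
                                            (0.5, 12.5), (1.5, 0.0)])
    def test_linear_repulsion(self, r, expected):
        assert pair_conservative(r, a=25.0) == pytest.approx(expected)

    def test_exponential_at_contact_and_cutoff(self):
        assert pair_exponential(0.0, a=3.7, b=2.0) == pytest.approx(3.7)
        assert pair_exponential(1.0, a=3.7, b=2.0) == 0.0

    def test_exponential_midpoint_value(self):
        # (e^1 - e^2)/(1 - e^2) = 0.731058...
        assert pair_exponential(0.5, a=1.0, b=2.0) == pytest.approx(
            (np.e - np.e**2) / (1 - np.e**2), rel=1e-12)
        assert pair_exponential(0.5, a=1.0, b=2.0) == pytest.approx(0.7311, abs=1e-4)

    def test_exponential_b_zero_rejected(self):
        with pytest.raises(ValueError):
            pair_exponential(0.5, a=1.0, b=0.0)

    def test_exponential_strictly_decreasing_and_steeper_than_linear(self):
        r = np.linspace(0, 0.999, 200)
        f = np.array([pair_exponential(x, a=1.0, b=3.0) for x in r])
        assert (np.diff(f) < 0).all()
        # rises more steeply than the linear law upon contact (approaching
        # the cutoff from inside): slope magnitude b/(1-e^-b) > 1 at r=R
        eps = 1e-4
        slope_exp = pair_exponential(1.0 - eps, a=1.0, b=3.0) / eps
        slope_lin = pair_conservative(1.0 - eps, a=1.0) / eps
        assert slope_exp > 2.5 * slope_lin

    @settings(max_examples=80, derandomize=True)
    @given(r=st.floats(0.0, 2.0), a=st.floats(0.1, 400.0),
           b=st.floats(0.1, 8.0))
    def test_exponential_force_bounded_and_repulsive(self, r, a, b):
        """0 <= F_exp <= a for any b > 0; identically 0 beyond the cutoff."""
        f = pair_exponential(r, a=a, b=b)
        if r >= 1.0:
            assert f == 0.0
        else:
            assert 0.0 <= f <= a + 1e-9

    @settings(max_examples=80, derandomize=True)
    @given(r=st.floats(0.0, 2.0), a=st.floats(0.1, 200.0))
    def test_linear_force_bounded_and_repulsive(self, r, a):
        f = pair_conservative(r, a=a)
        if r >= 1.0:
            assert f == 0.0
        else:
            assert 0.0 <= f <= a

    def test_dissipative_random_vanish_at_cutoff(self):
        assert pair_dissipative_random(1.0, 0.3, 4.5, 2.42, 0.7, 0.01) == 0.0
        # the combined value at r < R is -gamma w^2 v + sigma w theta/sqrt(dt)
        val = pair_dissipative_random(0.5, 1.0, 4.5, 0.0, 0.0, 0.01)
        assert val == pytest.approx(-4.5 * 0.25)


class TestForcePotentialConsistency:
    def test_exponential_force_is_minus_gradient(self):
        """The gas force equals -dV/dr of the gas potential to < 1e-3."""
        a, b, R = 120.0, 3.0, 1.2
        r = np.linspace(0.01, R - 0.01, 400)
        h = 1e-6
        num = -(potential_exponential(r + h, a, b, R)
                - potential_exponential(r - h, a, b, R)) / (2 * h)
        ana = np.array([pair_exponential(x, a, b, R) for x in r])
        rel = np.abs(num - ana) / np.maximum(np.abs(ana), 1e-8)
        assert rel.max() < 1e-3

    def test_linear_force_is_minus_gradient(self):
        a, R = 25.0, 1.0
        r = np.linspace(0.01, R - 0.01, 200)
        h = 1e-6
        num = -(potential_linear(r + h, a, R)
                - potential_linear(r - h, a, R)) / (2 * h)
        ana = np.array([pair_conservative(x, a, R) for x in r])
        assert np.abs(num - ana).max() < 1e-3 * a


def _two_bead_state(ff, labels, r, box=20.0):
    pos = np.array([[10.0, 10.0, 10.0], [10.0 + r, 10.0, 10.0]])
    types = np.array([TYPE_INDEX[l] for l in labels], dtype=np.int64)
    top = Topology(types=types)
    return SystemState(positions=pos, velocities=np.zeros((2, 3)),
                       box=np.array([box, box, box]), topology=top)


class TestBondedForces:
    def test_bond_at_equilibrium_is_force_free(self, ff):
        st = _two_bead_state(ff, ["C", "C"], 0.6)
        st.topology.bonds = np.array([[0, 1]])
        st.topology.bond_k = np.array([128.0])
        st.topology.bond_r0 = np.array([0.6])
        # isolate the bond: move beads out of pair cutoff is impossible at
        # r=0.6, so subtract the nonbonded part measured without the bond
        eng = DPDEngine(st, ff)
        f_with, _ = eng.compute_forces()
        st2 = _two_bead_state(ff, ["C", "C"], 0.6)
        f_without, _ = DPDEngine(st2, ff).compute_forces()
        assert np.allclose(f_with, f_without, atol=1e-10)

    def test_bond_force_matches_numeric_gradient(self, ff):
        k, r0 = 77.0, 0.5
        rs = np.linspace(0.2, 1.4, 13)

        def energy(r):
            return 0.5 * k * (r - r0) ** 2

        for r in rs:
            st = _two_bead_state(ff, ["W", "W"], r)
            st.topology.bonds = np.array([[0, 1]])
            st.topology.bond_k = np.array([k])
            st.topology.bond_r0 = np.array([r0])
            base = _two_bead_state(ff, ["W", "W"], r)
            f = (DPDEngine(st, ff).compute_forces()[0]
                 - DPDEngine(base, ff).compute_forces()[0])
            h = 1e-6
            num = -(energy(r + h) - energy(r - h)) / (2 * h)
            assert f[1, 0] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_angle_at_equilibrium_is_torque_free(self, ff):
        pos = np.array([[9.0, 10.0, 10.0], [10.0, 10.0, 10.0],
                        [11.0, 10.0, 10.0]])  # straight: theta = pi
        types = np.full(3, TYPE_INDEX["C"], dtype=np.int64)
        top = Topology(types=types, angles=np.array([[0, 1, 2]]),
                       angle_k=np.array([6.0]),
                       angle_theta0=np.array([np.pi]))
        st = SystemState(positions=pos, velocities=np.zeros((3, 3)),
                         box=np.full(3, 20.0), topology=top)
        base = SystemState(positions=pos.copy(), velocities=np.zeros((3, 3)),
                           box=np.full(3, 20.0),
                           topology=Topology(types=types.copy()))
        f = (DPDEngine(st, ff).compute_forces()[0]
             - DPDEngine(base, ff).compute_forces()[0])
        assert np.abs(f).max() < 1e-10

    def test_angle_force_matches_numeric_gradient(self, ff):
        k, t0 = 6.0, np.pi

        def make(theta):
            pos = np.array([
                [10.0 + np.cos(theta), 10.0 + np.sin(theta), 10.0],
                [10.0, 10.0, 10.0],
                [11.0, 10.0, 10.0]])
            types = np.full(3, TYPE_INDEX["W"], dtype=np.int64)
            top = Topology(types=types, angles=np.array([[0, 1, 2]]),
                           angle_k=np.array([k]),
                           angle_theta0=np.array([t0]))
            base_top = Topology(types=types.copy())
            a = SystemState(positions=pos, velocities=np.zeros((3, 3)),
                            box=np.full(3, 40.0), topology=top)
            b = SystemState(positions=pos.copy(), velocities=np.zeros((3, 3)),
                            box=np.full(3, 40.0), topology=base_top)
            return a, b

        def energy(theta):
            # the geometric angle at bead 1 equals the placement angle of
            # bead 0 in this construction
            return k * (1 - np.cos(theta - t0))

        for theta in (0.3, 0.7, 1.2):
            a, b = make(theta)
            ff_ = load_forcefield("default")
            f = (DPDEngine(a, ff_).compute_forces()[0]
                 - DPDEngine(b, ff_).compute_forces()[0])
            h = 1e-6
            num = -(energy(theta + h) - energy(theta - h)) / (2 * h)
            # tangential direction of bead 0 motion
            tang = np.array([-np.sin(theta), np.cos(theta), 0.0])
            assert float(f[0] @ tang) == pytest.approx(num, rel=1e-3, abs=1e-6)


class TestSmearedCoulomb:
    def _charged_state(self, r, q0=1.0, q1=-1.0, box=40.0):
        cfg = {
            "types": ["N", "P"], "units": {},
            "pairs": {"N N": {"a": 0.0}, "P P": {"a": 0.0}, "N P": {"a": 0.0}},
            "electrostatics": {"enabled": True, "coulomb_constant": 13.87,
                               "smearing_length": 0.67, "cutoff": 10.0},
        }
        ff = load_forcefield(cfg)
        pos = np.array([[20.0, 20.0, 20.0], [20.0 + r, 20.0, 20.0]])
        types = np.array([TYPE_INDEX["N"], TYPE_INDEX["P"]], dtype=np.int64)
        top = Topology(types=types, charges=np.array([q0, q1]))
        st = SystemState(positions=pos, velocities=np.zeros((2, 3)),
                         box=np.full(3, box), topology=top)
        return DPDEngine(st, ff)

    def test_opposite_charges_attract_finite_at_contact(self):
        f_mid, _ = self._charged_state(1.0).compute_forces()
        assert f_mid[0, 0] > 0  # bead 0 pulled toward bead 1 (+x)
        f_close, _ = self._charged_state(1e-4).compute_forces()
        assert np.isfinite(f_close).all()
        assert np.abs(f_close).max() < 1.0  # smearing kills the divergence

    def test_zero_charges_zero_force(self):
        f, _ = self._charged_state(1.0, q0=0.0, q1=0.0).compute_forces()
        assert np.abs(f).max() == 0.0

    def test_matches_point_coulomb_far_beyond_smearing(self):
        lam, const = 0.67, 13.87 * 0.65  # internal units
        r = 6.0  # ~9 smearing lengths
        f, _ = self._charged_state(r).compute_forces()
        point = const * 1.0 * -1.0 / r**2
        assert abs((f[1, 0] - point) / point) < 0.01

    def test_net_charge_warns(self):
        import warnings

        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            self._charged_state(1.0, q0=1.0, q1=1.0)
            assert any("net charge" in str(x.message) for x in w)


class TestNeighborSearch:
    def test_matches_brute_force_on_random_configs(self, rng):
        """Cell-binned pair search equals the O(N^2) scan, 50 configs."""
        for trial in range(50):
            n = int(rng.integers(2, 120))
            box = rng.uniform(3.5, 8.0, size=3)
            pos = rng.uniform(0, 1, size=(n, 3)) * box
            cutoff = float(rng.uniform(0.5, 1.1))
            got = neighbor_pairs(pos, box, cutoff)
            want = set()
            for i in range(n):
                for j in range(i + 1, n):
                    d = pos[i] - pos[j]
                    d -= box * np.round(d / box)
                    if d @ d < cutoff * cutoff:
                        want.add((i, j))
            assert got == want

    def test_minimum_image_across_boundary(self):
        box = np.array([10.0, 10.0, 10.0])
        pos = np.array([[0.05, 5.0, 5.0], [9.95, 5.0, 5.0]])
        assert neighbor_pairs(pos, box, 1.0) == {(0, 1)}

    def test_empty_system(self):
        assert neighbor_pairs(np.zeros((0, 3)), np.full(3, 10.0), 1.0) == set()

    def test_box_smaller_than_cutoff_rejected(self):
        with pytest.raises(ValueError):
            neighbor_pairs(np.zeros((2, 3)), np.array([0.5, 10.0, 10.0]), 1.0)
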