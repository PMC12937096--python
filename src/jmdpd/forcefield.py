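"""Force-field parameter management.

A force field bundles the unit system, the pairwise interaction table
(linear soft repulsions plus the exponential gas law), bonded-term
parameters and molecule templates.  Parameter bundles are flat YAML files
keyed by pair labels; every pair over the declared bead alphabet must be
present — there is no silent mixing rule.

Two bundles ship with the package:

``default``
    A fully documented parameter set in the spirit of standard
    soft-repulsion coarse-grained water (a_WW = 25 k_BT/R_c at bead density
    3/R_c^3), with the gas-phase exponential parameters calibrated so that
    the bulk gas matches the water reference pressure and the bare
    air-water interface reproduces the laboratory surface tension under
    the unit mapping.  Nanoparticle K beads are water-like (weakly
    attracted to water) and L beads are tail-like.

``si``
    A stub with the same schema intended to be filled with an externally
    published parameter table; loading it raises until the values are
    supplied.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .topology import BEAD_TYPES, TYPE_INDEX
from .units import UnitSystem


class ForceFieldError(ValueError):
    pass


@dataclass
class InteractionTable:
    """Dense symmetric pair tables over the declared bead alphabet.

    ``b[i, j] != 0`` marks a gas pair using the exponential conservative
    law with parameters (a, b, R); otherwise the linear soft repulsion
    a*(1 - r/R) applies.  ``sigma`` is slaved to the fluctuation-
    dissipation theorem sigma^2 = 2*T*gamma and is recomputed whenever the
    temperature or a friction entry changes.
    """

    types: tuple
    a: np.ndarray
    R: np.ndarray
    gamma: np.ndarray
    b: np.ndarray
    T: float
    #: repulsion table in k_BT units as declared in the bundle; ``a`` holds
    #: the internal absolute values (a_kT * energy_scale)
    a_kT: np.ndarray | None = None
    energy_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.a_kT is None:
            self.a_kT = self.a / self.energy_scale
        for name in ("a", "R", "gamma", "b"):
            m = getattr(self, name)
            if not np.allclose(m, m.T):
                raise ForceFieldError(f"{name} table is not symmetric")
        if np.any(self.R <= 0):
            raise ForceFieldError("all interaction cutoffs must be positive")
        self._update_sigma()

    def _update_sigma(self) -> None:
        self.sigma = np.sqrt(2.0 * self.T * self.gamma)

    def set_temperature(self, T: float) -> None:
        if T <= 0:
            raise ForceFieldError("temperature must be positive")
        self.T = T
        self._update_sigma()

    def set_friction(self, ti: int, tj: int, gamma: float) -> None:
        self.gamma[ti, tj] = self.gamma[tj, ti] = gamma
        self._update_sigma()

    @property
    def max_cutoff(self) -> float:
        return float(self.R.max())

    def pair(self, ti, tj) -> dict:
        i = TYPE_INDEX[ti] if isinstance(ti, str) else ti
        j = TYPE_INDEX[tj] if isinstance(tj, str) else tj
        return {
            "a": float(self.a_kT[i, j]),
            "a_internal": float(self.a[i, j]),
            "R": float(self.R[i, j]),
            "gamma": float(self.gamma[i, j]),
            "sigma": float(self.sigma[i, j]),
            "b": float(self.b[i, j]),
            "exponential": bool(self.b[i, j] != 0.0),
        }


@dataclass
class ForceField:
    units: UnitSystem
    table: InteractionTable
    bonds: dict
    angles: dict
    dppc: dict
    nanoparticle: dict
    gas: dict
    electrostatics: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def T(self) -> float:
        return self.units.T_DPD

    @property
    def energy_scale(self) -> float:
        """Internal energy per declared k_BT unit (T_DPD in the per-k_BT
        convention, 1 otherwise)."""
        return self.table.energy_scale


def _parse_pair_key(key: str) -> tuple[str, str]:
    parts = key.replace("-", " ").split()
    if len(parts) != 2:
        raise ForceFieldError(f"malformed pair key {key!r}")
    return parts[0], parts[1]


def _build_table(cfg: dict, T: float, energy_scale: float = 1.0) -> InteractionTable:
    declared = tuple(cfg.get("types", BEAD_TYPES))
    for t in declared:
        if t not in TYPE_INDEX:
            raise ForceFieldError(f"unknown bead type {t!r}")
    n = len(BEAD_TYPES)
    default_gamma = float(cfg.get("defaults", {}).get("gamma", 4.5))
    a = np.zeros((n, n))
    R = np.ones((n, n))
    gamma = np.full((n, n), default_gamma)
    b = np.zeros((n, n))
    seen: dict[tuple[int, int], dict] = {}
    for key, entry in cfg.get("pairs", {}).items():
        t1, t2 = _parse_pair_key(key)
        if t1 not in TYPE_INDEX or t2 not in TYPE_INDEX:
            raise ForceFieldError(f"unknown bead type in pair {key!r}")
        i, j = sorted((TYPE_INDEX[t1], TYPE_INDEX[t2]))
        prev = seen.get((i, j))
        if prev is not None and prev != entry:
            raise ForceFieldError(
                f"asymmetric duplicate entry for pair {BEAD_TYPES[i]}-{BEAD_TYPES[j]}")
        seen[(i, j)] = dict(entry)
        if entry.get("R", 1.0) <= 0:
            raise ForceFieldError(f"negative or zero cutoff for pair {key!r}")
        a[i, j] = a[j, i] = float(entry["a"])
        R[i, j] = R[j, i] = float(entry.get("R", 1.0))
        gamma[i, j] = gamma[j, i] = float(entry.get("gamma", default_gamma))
        bij = float(entry.get("b", 0.0))
        if entry.get("law", "linear") == "exp" and bij == 0.0:
            raise ForceFieldError(f"exponential pair {key!r} with b=0 is degenerate")
        b[i, j] = b[j, i] = bij
    # every pair over the declared alphabet must be present
    missing = []
    for ii, t1 in enumerate(declared):
        for t2 in declared[ii:]:
            i, j = sorted((TYPE_INDEX[t1], TYPE_INDEX[t2]))
            if (i, j) not in seen:
                missing.append(f"{t1}-{t2}")
    if missing:
        raise ForceFieldError("missing pair entries: " + ", ".join(missing))
    return InteractionTable(types=declared, a=a * energy_scale, R=R, gamma=gamma,
                            b=b, T=T, a_kT=a, energy_scale=energy_scale)


def load_forcefield(source: str | Path | dict) -> ForceField:
    """Load a force field from a YAML path, a bundle name, or a dict."""
    if isinstance(source, dict):
        cfg = source
    else:
        p = Path(source)
        if not p.exists():
            res = importlib.resources.files("jmdpd.data").joinpath(f"{source}.yaml")
            if not res.is_file():
                raise ForceFieldError(f"no such force-field file or bundle: {source}")
            cfg = yaml.safe_load(res.read_text())
        else:
            cfg = yaml.safe_load(p.read_text())
    if cfg.get("incomplete"):
        raise ForceFieldError(
            "this bundle is a schema stub; fill in the parameter table before use")
    ucfg = cfg.get("units", {})
    units = UnitSystem(**ucfg)
    convention = cfg.get("meta", {}).get("a_convention", "per_kBT")
    if convention not in ("per_kBT", "absolute"):
        raise ForceFieldError(f"unknown a_convention {convention!r}")
    # In the per-k_BT convention (the standard one: a_WW = 25 k_BT/R_c at
    # rho = 3 gives the reference pressure 23.7 k_BT/R_c^3) declared
    # energies are multiplied by T_DPD to obtain internal absolute values.
    scale = units.T_DPD if convention == "per_kBT" else 1.0
    table = _build_table(cfg, units.T_DPD, energy_scale=scale)
    return ForceField(
        units=units,
        table=table,
        bonds=cfg.get("bonds", {}),
        angles=cfg.get("angles", {}),
        dppc=cfg.get("dppc", {}),
        nanoparticle=cfg.get("nanoparticle", {}),
        gas=cfg.get("gas", {}),
        electrostatics=cfg.get("electrostatics", {"enabled": False}),
        meta=cfg.get("meta", {}),
    )
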