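"""Scenario orchestration: staged protocols, mechanism classification,
coverage scans.

A Scenario bundles a builder spec, a staged run protocol and the analysis
set, and is fully determined by its configuration plus a seed.  The
staged protocol follows the equilibration recipe for interfacial systems:
a short isobaric stage with heavily massed (~50x) lipid/NP beads so the
water and gas subphases relax around them, an isobaric stage with actual
masses, then the isochoric production run.

Desk-scale defaults divide the full-size system (1400 lipids per leaflet,
12 nm particle) by an area factor of 7: 200 lipids per leaflet and a
4-5 nm particle.  Production lengths are correspondingly shortened;
scaled runs probe mechanisms and trends, not converged full-scale
statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .builders import (JNPSpec, MonolayerSpec, PlacementMode, build_system,
                       build_water_box, build_water_slab, scale_system)
from .engine import DPDEngine, EngineConfig
from .forcefield import ForceField, load_forcefield
from .observables import (analyze_frames, block_average, orientation,
                          tension_series, water_midplane, _rel_z,
                          interface_planes, unwrap_group)
from .topology import TYPE_INDEX

SCENARIO_NAMES = ("translocation", "intercalation", "coating",
                  "pure-monolayer", "water-eos", "water-slab-tension")


@dataclass
class Stage:
    ensemble: str            # 'nvt' | 'npt'
    steps: int
    mass_scale: float = 1.0  # applied to NP + lipid beads
    # 'z' keeps the interfacial area (hence a_L) fixed while the normal
    # extent relaxes to the reference pressure
    coupling: str = "z"


def default_protocol(scale: float = 7.0, production_steps: int = 120000):
    """Freeze -> relax -> production, scaled down from the full recipe."""
    s = max(1.0, scale)
    return [
        Stage("npt", int(20000 / s) * 2, mass_scale=50.0),
        Stage("npt", int(50000 / s) * 2, mass_scale=1.0),
        Stage("nvt", production_steps, mass_scale=1.0),
    ]


@dataclass
class Scenario:
    """A named, fully reproducible end-to-end run."""

    name: str = "intercalation"
    phi_L: float = 0.5
    mode: str = "la"
    scale: float = 7.0
    seed: int = 1
    production_steps: int = 120000
    dt: float = 0.02
    sample_every: int = 100
    traj_every: int = 2000
    traj_stages: int = 2   # record relaxation + production frames
    forcefield: str = "default"
    with_np: bool = True
    area_per_lipid_nm2: float = 0.6
    water_thickness: float = 8.0
    gas_thickness: float = 8.0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ScenarioResult:
    scenario: Scenario
    state: object
    obs: pd.DataFrame          # engine time series (pressures in k_BT)
    tension: pd.DataFrame      # gamma_m / Pi series
    metrics: pd.DataFrame      # per-frame structural observables
    traj: tuple                # (positions, boxes, times)
    summary: dict


def run_protocol(state, ff: ForceField, stages, cfg: EngineConfig,
                 traj_every: int = 0, traj_stages: int = 1):
    """Run a staged protocol.

    Returns (engine, obs, (traj_pos, traj_box, traj_time)); trajectory
    frames are recorded during the final ``traj_stages`` stages (the flip
    of a Janus particle often begins during the relaxation stage, so
    recording only production would miss the orientation transient).
    """
    eng = DPDEngine(state, ff, cfg)
    top = state.topology
    movable = np.zeros(state.n_beads, dtype=bool)
    for lip in top.lipids:
        movable[np.asarray(lip)] = True
    for npb in top.nps:
        movable[np.asarray(npb)] = True
    obs_all = []
    tps, tbs, tts = [], [], []
    step0 = 0
    for k, st in enumerate(stages):
        scale = np.where(movable, st.mass_scale, 1.0)
        eng.config.barostat_coupling = st.coupling
        record = k >= len(stages) - traj_stages
        obs, (tp, tb) = eng.run(
            st.steps, ensemble=st.ensemble,
            mass_scale=scale if st.mass_scale != 1.0 else None,
            traj_every=traj_every if record else 0)
        obs["stage"] = k
        obs_all.append(obs)
        if record and len(tp):
            tps.append(tp)
            tbs.append(tb)
            tts.append((step0 + np.arange(1, len(tp) + 1) * traj_every)
                       * cfg.dt)
        step0 += st.steps
    if tps:
        traj = (np.concatenate(tps), np.concatenate(tbs), np.concatenate(tts))
    else:
        traj = (np.zeros((0, state.n_beads, 3)), np.zeros((0, 3)),
                np.zeros(0))
    return eng, pd.concat(obs_all, ignore_index=True), traj


def classify_mechanism(result_frames: pd.DataFrame, state, ff,
                       theta_final: float | None,
                       window: int = 5) -> str:
    """Assign translocation / coating / intercalation from the final state.

    translocation: particle center sank below its interface plane by more
    than its radius.  coating: the particle stayed on the gas side with
    lipid contacts and essentially no water contact on its hydrophobic
    beads.  intercalation: otherwise, with a flipped director
    (theta > 150 deg) or a sustained interfacial position.
    """
    from scipy.spatial import cKDTree

    top = state.topology
    meta = top.np_meta[0]
    R = float(meta["radius"])
    pos = state.positions
    box = state.box
    beads = np.asarray(top.nps[0])
    pts = unwrap_group(pos[beads], box)
    center = pts.mean(axis=0)
    z_up, z_lo = interface_planes(pos, top, box)
    zc = water_midplane(pos, top, box)
    rel_center = _rel_z(np.array([center[2]]), zc, float(box[2]))[0]
    plane = z_up if rel_center >= 0 else z_lo
    # signed distance toward water (negative = submerged)
    d = _rel_z(np.array([center[2]]), plane, float(box[2]))[0]
    toward_water = -d if rel_center >= 0 else d
    if toward_water > R:
        return "translocation"
    # contacts of hydrophobic beads with water / any NP bead with tails
    wrapped = pos % box
    isW = top.types == TYPE_INDEX["W"]
    isC = top.types == TYPE_INDEX["C"]
    np_mask = np.zeros(top.n_beads, dtype=bool)
    np_mask[beads] = True
    Lb = beads[top.types[beads] == TYPE_INDEX["L"]]
    n_LW = 0
    if len(Lb) and isW.any():
        tw = cKDTree(wrapped[isW], boxsize=box)
        n_LW = int(sum(len(x) for x in
                       tw.query_ball_point(wrapped[Lb], 1.0)))
    n_lip = 0
    if isC.any():
        tc = cKDTree(wrapped[isC & ~np_mask], boxsize=box)
        n_lip = int(sum(len(x) for x in
                        tc.query_ball_point(wrapped[beads], 1.0)))
    on_gas_side = toward_water < 0
    # a flipped director is decisive: a lipid-coated particle keeps its
    # initial orientation (its hydrophilic cap stays far from water)
    if theta_final is not None and theta_final > 150.0:
        return "intercalation"
    # coating: lipid contacts dominate overwhelmingly over water contacts
    # on the hydrophobic beads (a ratio, robust to the few grazing water
    # contacts a desk-scale particle picks up at a rough interface)
    if on_gas_side and n_lip > 0 and n_LW < 0.1 * n_lip:
        return "coating"
    if abs(toward_water) < R:
        return "intercalation"
    return "coating" if on_gas_side else "intercalation"


def run_scenario(sc: Scenario, ff: ForceField | None = None) -> ScenarioResult:
    """Build, run and analyze one scenario end to end."""
    ff = ff or load_forcefield(sc.forcefield)
    if sc.name == "water-eos":
        return _run_water_eos(sc, ff)
    if sc.name == "water-slab-tension":
        return _run_water_slab(sc, ff)
    mono_full = MonolayerSpec(area_per_lipid_nm2=sc.area_per_lipid_nm2,
                              water_thickness=sc.water_thickness,
                              gas_thickness=sc.gas_thickness)
    jnp_full = JNPSpec(radius=9.3, phi_L=sc.phi_L) if sc.with_np else None
    mono, jnp = scale_system(mono_full, jnp_full, sc.scale)
    mode = PlacementMode(mode=sc.mode) if jnp is not None else None
    state = build_system(ff, mono, jnp, mode, seed=sc.seed)
    cfg = EngineConfig(dt=sc.dt, seed=sc.seed, sample_every=sc.sample_every,
                       pressure=ff.units.reference_pressure)
    stages = default_protocol(sc.scale, sc.production_steps)
    eng, obs, traj = run_protocol(state, ff, stages, cfg,
                                  traj_every=sc.traj_every,
                                  traj_stages=sc.traj_stages)
    tens = tension_series(obs[obs["stage"] == len(stages) - 1], ff.units)
    metrics = analyze_frames(traj[0], traj[1], state.topology, ff.units,
                             times=traj[2])
    nwin = max(3, len(metrics) // 5)
    tail = metrics.tail(nwin)
    theta_final = float(tail["theta_deg"].mean()) \
        if "theta_deg" in metrics.columns else None
    Pi_mean, Pi_err = block_average(tens["Pi_mNm"].to_numpy()[len(tens) // 3:])
    summary = {
        "name": sc.name, "phi_L": sc.phi_L, "mode": sc.mode,
        "seed": sc.seed, "config_hash": sc.config_hash(),
        "theta_final_deg": theta_final,
        "Pi_mNm": Pi_mean, "Pi_err_mNm": Pi_err,
        "f_lc": float(tail["f_lc"].mean()) if "f_lc" in tail else None,
        "a_eff_nm2": float(tail["a_eff_nm2"].mean()) if "a_eff_nm2" in tail else None,
        "n_lost": int(round(tail["n_lost"].mean())) if "n_lost" in tail else None,
    }
    if sc.with_np:
        summary["mechanism"] = classify_mechanism(metrics, state, ff,
                                                  theta_final)
    return ScenarioResult(scenario=sc, state=state, obs=obs, tension=tens,
                          metrics=metrics, traj=traj, summary=summary)


def _run_water_eos(sc: Scenario, ff: ForceField) -> ScenarioResult:
    state = build_water_box(ff, L=10.0, seed=sc.seed)
    cfg = EngineConfig(dt=sc.dt, seed=sc.seed, sample_every=sc.sample_every)
    eng = DPDEngine(state, ff, cfg)
    eng.run(max(2000, sc.production_steps // 6))
    obs, (tp, tb) = eng.run(sc.production_steps)
    traj = (tp, tb, np.zeros(len(tp)))
    P = obs[["Pxx", "Pyy", "Pzz"]].to_numpy().mean(axis=1)
    mean, err = block_average(P)
    summary = {"name": sc.name, "seed": sc.seed, "pressure_kBT": mean,
               "pressure_err": err, "T_kin": float(obs["T_kin"].mean()),
               "config_hash": sc.config_hash()}
    return ScenarioResult(sc, state, obs, pd.DataFrame(), pd.DataFrame(),
                          traj, summary)


def _run_water_slab(sc: Scenario, ff: ForceField) -> ScenarioResult:
    state = build_water_slab(ff, L=10.0, seed=sc.seed)
    cfg = EngineConfig(dt=sc.dt, seed=sc.seed, sample_every=sc.sample_every)
    eng = DPDEngine(state, ff, cfg)
    eng.run(max(2000, sc.production_steps // 6))
    obs, (tp, tb) = eng.run(sc.production_steps)
    traj = (tp, tb, np.zeros(len(tp)))
    tens = tension_series(obs, ff.units)
    g_mean, g_err = block_average(tens["gamma_m"].to_numpy())
    summary = {"name": sc.name, "seed": sc.seed,
               "gamma_reduced": g_mean, "gamma_err": g_err,
               "gamma_mNm": ff.units.tension_to_mNm(g_mean),
               "config_hash": sc.config_hash()}
    return ScenarioResult(sc, state, obs, tens, pd.DataFrame(), traj, summary)


def coverage_scan(phi_list, mode: str = "la", scale: float = 7.0,
                  seeds=(1,), ff: ForceField | None = None,
                  production_steps: int = 120000) -> pd.DataFrame:
    """Pi, f_LC and a_eff versus hydrophobic coverage.

    Runs one scenario per (phi_L, seed); phi 0 and 1 run as uniform
    particles.  Returns one row per run with block-averaged errors, ready
    for peak detection and the Pi(a_eff) collapse check.
    """
    if len(phi_list) == 0:
        raise ValueError("empty coverage list")
    ff = ff or load_forcefield("default")
    rows = []
    for phi in phi_list:
        for seed in seeds:
            sc = Scenario(name="coverage", phi_L=float(phi), mode=mode,
                          scale=scale, seed=seed,
                          production_steps=production_steps)
            res = run_scenario(sc, ff)
            row = dict(res.summary)
            row["phi_L"] = phi
            row["seed"] = seed
            rows.append(row)
    return pd.DataFrame(rows)
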