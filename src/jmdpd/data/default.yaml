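# Default force-field bundle (reduced units: lengths in R_c, energies in
# k_BT, bead mass 1).
#
# Conventions: repulsion parameters a_ij (and bonded constants) are in
# k_BT/R_c — the standard convention in which a_WW = 25 at bead density
# 3/R_c^3 gives the reference bulk water pressure 23.7 k_BT/R_c^3.  The
# loader multiplies them by T_DPD to obtain internal absolute values, so
# the thermostatted kinetic temperature is T_DPD while reported pressures,
# tensions and energies stay in k_BT units.  Head beads (N, P, G) are water-like; tails (C) are
# strongly repelled by water.  Nanoparticle K beads are water-like with a
# weak net attraction to water (a_KW < (a_KK + a_WW)/2) and L beads are
# tail-like with a weak net attraction to tails, reproducing the expected
# sign pattern of the bead-bead contact energies.  Gas (B) pairs use the
# exponential law; a_BB is set so the bulk gas at the density below matches
# the reference pressure, and a_BW is calibrated so the bare air-water
# interface reproduces gamma0 under the unit mapping.
meta:
  name: default
  a_convention: per_kBT

units:
  R_c: 0.646
  rho_W: 3.0
  T_DPD: 0.65
  T_real: 293.0
  reference_pressure: 23.7
  gamma0_mNm: 72.8
  tension_scale_mode: kT_real
  gamma0_reduced: 7.55   # in-model bare air-water tension (calibrated)

defaults:
  gamma: 4.5

pairs:
  W W: {a: 25.0}
  W N: {a: 25.0}
  W P: {a: 25.0}
  W G: {a: 25.0}
  W C: {a: 75.0}
  W K: {a: 21.5}
  W L: {a: 75.0}
  N N: {a: 25.0}
  N P: {a: 25.0}
  N G: {a: 25.0}
  N C: {a: 60.0}
  N K: {a: 25.0}
  N L: {a: 75.0}
  P P: {a: 25.0}
  P G: {a: 25.0}
  P C: {a: 60.0}
  P K: {a: 25.0}
  P L: {a: 75.0}
  G G: {a: 25.0}
  G C: {a: 35.0}
  G K: {a: 25.0}
  G L: {a: 60.0}
  C C: {a: 25.0}
  C K: {a: 75.0}
  C L: {a: 22.8}
  K K: {a: 25.0}
  K L: {a: 50.0}
  L L: {a: 25.0}
  B B: {a: 14.2, b: 2.0, law: exp}
  B W: {a: 120.0, b: 3.0, R: 1.2, law: exp}
  B N: {a: 120.0, b: 3.0, R: 1.2, law: exp}
  B P: {a: 120.0, b: 3.0, R: 1.2, law: exp}
  B G: {a: 120.0, b: 3.0, R: 1.2, law: exp}
  B C: {a: 112.0, b: 2.0, R: 1.018, law: exp}
  B K: {a: 120.0, b: 3.0, R: 1.2, law: exp}
  B L: {a: 112.0, b: 2.0, R: 1.018, law: exp}

bonds:
  lipid: {k: 128.0, r0: 0.6}
  np: {k: 500.0, r0: 1.0}

angles:
  tail: {k: 6.0, theta0_deg: 180.0}

dppc:
  # 14-bead DPPC: choline N, phosphate P, two glycerol G, two 5-bead tails
  beads: [N, P, G, G, C, C, C, C, C, C, C, C, C, C]
  bonds: [[0, 1], [1, 2], [2, 3],
          [2, 4], [4, 5], [5, 6], [6, 7], [7, 8],
          [3, 9], [9, 10], [10, 11], [11, 12], [12, 13]]
  angles: [[2, 4, 5], [4, 5, 6], [5, 6, 7], [6, 7, 8],
           [3, 9, 10], [9, 10, 11], [10, 11, 12], [11, 12, 13]]
  tails: [[4, 5, 6, 7, 8], [9, 10, 11, 12, 13]]
  charges: {N: 1.0, P: -1.0}

nanoparticle:
  lattice_spacing: 1.0
  bond_k: 500.0

gas:
  rho_B: 3.0
  slab_thickness: 8.0

electrostatics:
  enabled: false
  coulomb_constant: 13.87
  smearing_length: 0.67
  cutoff: 3.0
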