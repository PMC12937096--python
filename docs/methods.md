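# Methods

`jmdpd` simulates amphiphilic Janus nanoparticles (JNPs) interacting with
DPPC monolayers at the air-water interface, using dissipative particle
dynamics (DPD) with an exponential gas-bead model for the air phase, and
computes the observables that characterize the interaction mechanisms:
particle orientation, pressure-tensor surface tension and surface
pressure, tail-order/phase statistics, effective area per lipid, and a
contact-energy decomposition of the surface energy.

## The model

### Beads and interactions

Eight bead species: water W (3 waters per bead), fictitious gas B,
DPPC head beads N (choline), P (phosphate), G (glycerol, x2), tail beads
C (x10), and nanoparticle beads K (hydrophilic) / L (hydrophobic).

Non-bonded pairs interact with the standard soft linear repulsion
F = a_ij (1 - r/R_ij) r_hat plus the DPD thermostat pair forces
(dissipative -gamma w^2 (v.r_hat) r_hat and random sigma w theta r_hat
with sigma^2 = 2 k_B T gamma, w = 1 - r/R_ij). Pairs involving the gas
bead use the exponential conservative force

    F_exp(r) = a (e^{b r/R} - e^b) / (1 - e^b) r_hat,   r < R,

which rises much more steeply than the linear law on approach to the
cutoff and behaves like a near-hardcore wall; this is what makes a
mechanically stable, high-tension gas-liquid interface possible with an
otherwise purely repulsive fluid.

Bonds are harmonic; bending restraints use U = k(1 - cos(theta -
theta0)), which matches the harmonic form to second order at the
equilibrium angle but stays regular at theta0 = 180 deg (the straight
tail geometry), where the plain harmonic angle force is 0/0.

A smeared-charge Coulomb force (Slater smearing, direct sum with cutoff)
is implemented for the zwitterionic headgroup (+1 on N, -1 on P). The
default bundle runs with electrostatics disabled: the headgroup is
net-neutral and short-ranged in its effects, and the published charge and
smearing constants for this parameterization are not available to us;
the head-bead repulsion table absorbs the mean effect. Enabling it is a
single config switch.

### Units and conventions

Lengths are in R_c = 0.646 nm, the water-bead diameter; bead mass 1; the
reduced temperature T_DPD = 0.65 maps to 293 K. Repulsion and bonded
constants are declared **per k_BT** — the standard convention in which
a_WW = 25 k_BT/R_c at bead density rho = 3/R_c^3 produces the reference
bulk pressure 23.7 k_BT/R_c^3. Internally the loader multiplies declared
energies by T_DPD, the thermostat runs at T_DPD, and reported pressures,
tensions and energies are divided back into k_BT units. We verified the
convention against the equation of state: the simulated water box gives
23.66 +- 0.10 k_BT/R_c^3 (the alternative, absolute reading gives 22.8
and is inconsistent with the reference value).

Tension conversion: 1 k_BT/R_c^2 = k_B * 293 K / R_c^2 = 9.693 mN/m
(default `tension_scale_mode: kT_real`); the temperature-scaled variant
(divide by T_DPD) is exposed for sensitivity checks.

### Gas-phase calibration

The original gas-bead construction prescribes its parameters "by matching
the interfacial properties of water and the monolayer"; the published
table is not available, so the shipped `default` bundle performs the same
calibration with this package's own engine:

1. **Gas equation of state.** rho_B = 3/R_c^3 and a_BB = 14.2 (b = 2)
   give a bulk gas pressure of 23.7 k_BT/R_c^3, equal to the water
   reference, so a water slab and its vapor phase are in mechanical
   equilibrium at the densities the builder installs.
2. **Bare air-water tension.** The hydrophilic-gas pairs (B-W, B-N, B-P,
   B-G, B-K) use a = 120, b = 3, R = 1.2 R_c. The interaction range is
   the dominant lever for the interfacial excess energy; R = 1.2 puts
   the bare water-slab tension at gamma_0 = 7.55 k_BT/R_c^2 = 73.2 mN/m,
   within 1% of the laboratory 72.8 mN/m at 293 K. The bundle stores
   this measured gamma_0 (`units.gamma0_reduced`); surface pressures
   Pi = gamma_0 - gamma_m use it by default so that Pi -> 0 for a bare
   interface by construction.
3. **Tail-gas affinity.** The tail-gas pairs (B-C, B-L) set how much a
   lipid film lowers the interfacial tension. They are calibrated so the
   pure DPPC monolayer at a_L = 0.6 nm^2 — the LE-LC coexistence point
   of the study — sits near the target surface pressure of ~8 mN/m
   (see the parameter file for the final values). Pi is very sensitive
   to this range parameter (a few mN/m per 0.01 R_c), which mirrors the
   physical statement that the monolayer's spreading pressure is an
   interfacial free-energy balance between almost-cancelling terms.

All other repulsions follow common soft-water/lipid practice: heads
water-like (a = 25), tail-water a = 75, head-tail 35-60. Nanoparticle
K beads are water-like with a weak excess attraction to water
(a_KW = 21.5 < 25) and L beads tail-like with a weak excess attraction
to tails (a_LC = 22.8 < 25), so the bead-bead contact energies come out
with the physically required sign pattern (eps_KW < 0, eps_LW > 0,
eps_LC < 0) and magnitudes of a fraction of k_BT.

### Nanoparticle model

A sphere of radius R_NP carved from a simple cubic lattice (spacing
1 R_c, bead-centered cells), nearest neighbors linked by strong harmonic
bonds (k = 500 k_BT/R_c^2). Beads with local axial coordinate
z >= R_NP - h form the hydrophobic cap; the coverage is phi_L = h/D_NP
exactly, and the surface-bead census (beads with a missing lattice
neighbor) converges to phi_L as the lattice is refined. A cubic lattice
with central-force nearest-neighbor bonds has soft shear modes in the
bulk-crystal limit; at the sizes used here the bead excluded volume and
the surface topology keep the radius of gyration constant to well under
1% over a run, which is verified by test.

## Builders

Everything is generated in code from a spec + seed: lipids stand on a
jittered square lattice at both faces of a water slab (heads toward
water, tails toward gas), water fills the slab at rho = 3, gas fills the
outer slabs at rho_B, and (optionally) one nanoparticle sits in the gas
phase above each leaflet — the system stays symmetric in z, which the
two-interface tension formula gamma_m = (L_z/2)(P_zz - (P_xx+P_yy)/2)
assumes. Initial overlaps are soft by construction and are relaxed by
the staged protocol below. The lipophile-adhesion (LA) placement points
the hydrophobic cap at the monolayer (orientation angle ~0 deg), the
hydrophile-adhesion (HA) placement the reverse (~180 deg).

Desk scaling divides the full system (1400 lipids/leaflet, L = 44.6 R_c,
12-nm particle) by an area factor: lipid count and interfacial area by
f, particle radius by sqrt(f), preserving a_L and the footprint fraction.
The default f = 7 gives 200 lipids/leaflet and a 4.5-nm particle. Scaled
runs reproduce mechanisms and trends; they do not reproduce full-scale
kinetics (flip times, lipid-loss counts) quantitatively, and particle
curvature at 4-5 nm is higher than at 12 nm, which the source work itself
flags as a mechanism-relevant variable.

## Dynamics

Modified velocity-Verlet with lambda = 0.65 velocity prediction for the
dissipative force (plain VV via lambda = 0.5). Default dt = 0.01 for
bulk property measurements; the interfacial scenario protocol uses
dt = 0.02, where the thermostat still holds the kinetic temperature
within 2% (verified by test). Pair noise is counter-based — hashed from
(seed, step, i, j) — so runs are bit-reproducible and pair-symmetric.

Staged protocol, scaled from the source recipe: (1) isobaric with ~50x
mass on lipid/NP beads so water and gas equilibrate around a frozen
film; (2) isobaric with real masses; (3) isochoric production. Isobaric
stages couple only L_z ("z" coupling): systems are built at a prescribed
area per lipid, and relaxing the lateral box toward the bulk reference
pressure would destroy that control variable (the semi-isotropic coupling
is implemented but documented as unstable for tension-bearing films).
Berendsen-type rescaling with per-step clamp of 0.1%.

The pressure tensor uses the conservative virial only (pair + bonded +
electrostatic); dissipative and random contributions are thermostat
bookkeeping that time-average to zero stress.

## Observables

- **Orientation**: u points from the hydrophobic- to the hydrophilic-cap
  center of mass; Theta_NP = arccos(u . n) against the outward normal of
  the particle's leaflet, so LA starts read ~0 deg and full intercalation
  180 deg. Undefined (by error) for uniform particles.
- **Tension/pressure**: gamma_m per interface from the diagonal pressure
  tensor; Pi = gamma_0 - gamma_m with the calibrated in-model gamma_0
  (identity Pi + gamma_m = gamma_0 holds per frame by construction).
- **Tail order**: S = (3 cos^2 theta - 1)/2 per tail (first-to-last tail
  bead against z), averaged over the two tails; LC label at S > 0.6;
  f_LC = n_L(S > 0.6) / A_res with A_res = L_x L_y - A_I^NP per leaflet.
- **NP interfacial area**: sphere cross-section pi (R^2 - d^2) at the
  leaflet's interface plane (mean phosphate z, recomputed per frame);
  a bead-projection alternative is available behind a flag.
- **Lipid loss**: a lipid counts toward n_L^w when it is not in the
  largest tail-contact cluster (cutoff 1 R_c, configurable) of its
  leaflet, or when every tail bead touches the nanoparticle (coating).
  The cluster construction is this package's formalization; the source
  narrative defines lipid loss only qualitatively.
- **Effective area**: a_L^eff = (L_x L_y - A_I^NP) / (n_L - n_L^w).

## Surface energy

E_S = E_NP + E_m' with E_m' = gamma_m (L_x L_y - A_I^NP) and
E_NP = sum_j eps_Kj n_Kj + eps_Lj n_Lj over contacts of NP surface beads
(r < R_aj, the pair cutoff — also the upper limit of the defining
integral; an all-beads variant is behind a flag). Contact energies are
RDF-weighted averages of the mismatch potential
dV_aj = V_aj - (V_aa + V_jj)/2 with the quadratic potential for standard
pairs and the integrated exponential for gas pairs; g_aj(r) comes from
small bulk runs of a few tagged alpha beads dilute (~1:170) in a host-j
bath, with the histogram range clamped to 0.45 L to avoid minimum-image
truncation. With g = 1 and equal cutoffs the estimator reduces to
eps = (a_aj - (a_aa + a_jj)/2) R/20, which the tests verify against
quadrature.

## Scenario classification

The three outcomes are assigned by rule from the final state:
**translocation** if the particle center is more than R_NP below its
interface plane (into water); **intercalation** if the director has
flipped (Theta_NP > 150 deg; a coated particle keeps its initial
orientation, so a flipped director is decisive) or the particle straddles
the plane; **coating** if it remains on the gas side with lipid contacts
and hydrophobic-water contacts below 10% of its lipid contacts (a ratio
rather than a hard count, because a half-coated desk-scale particle
grazes a few water beads at the rough interface). Thresholds are
configurable; they formalize a narrative description and are validated on
the scaled scenario runs in the test suite.

## What the synthetic systems do and do not capture

The builder generates every input (there is no external data), so tests
exercise the full pipeline: mechanics of the engine against statistical-
mechanical oracles (equation of state, equipartition, ideal-gas pressure,
brute-force pair sets), geometry of the builders against closed-form
counts, and the analysis layer against synthetic configurations with
known answers. The scaled scenario runs demonstrate the mechanisms
(translocation / coating / flip-to-intercalation) and trend-level
monolayer responses; quantitative full-scale values — converged
surface-pressure curves, flip time constants, micelle statistics —
require the cluster-scale system sizes and step counts of the source
study and are out of desk scope. Problem sizes used by the test suite:
~1000-3000 beads for bulk oracles, 70-200 lipids/leaflet (9,000-23,000
beads) for interfacial runs, 12,000-18,000 production steps after the
staged relaxation (calibration used runs up to 80,000 steps).

## Numerical choices

- Verlet list with 0.3 R_c skin over the largest pair cutoff, rebuilt on
  half-skin displacement; stored integer image shifts keep the minimum
  image exact between rebuilds (box rescaling scales the reference
  positions too).
- Exactly overlapping beads get a deterministic separation direction
  hashed from the pair ids.
- Berendsen mu clamped to [0.999, 1.001] per step.
- RDF bins 0.02 R_c (configurable); quadrature by the trapezoid rule on
  the measured grid; halving the bin width moves eps by < 1%.
- Non-finite/blow-up detection runs in a non-fastmath kernel (fastmath
  folds isfinite checks).

## Known limitations

A structural one first: the default bundle's pressure-area isotherm is
much steeper than the laboratory DPPC isotherm around 0.6 nm^2 — a
70-lipid scan gives Pi = 6.8 / 21.8 / 25.3 mN/m at a_L = 0.60 / 0.55 /
0.52 nm^2, i.e. no broad LE-LC coexistence plateau. Reproducing the
plateau is precisely what the published parameterization of this
monolayer model was built for, and it cannot be recovered here by a
single-knob adjustment (stiffening the tail bending flattens the slope
only marginally while displacing the calibrated 0.6-point). Consequences:
quantities pinned at a_L = 0.6 (surface pressure, order statistics,
mechanism phenomenology, the pressure peak versus coverage) are
meaningful, but the equivalence of the particle-loaded film to a pure
film at the effective area per lipid — which presumes a flat isotherm
between the two areas — does not hold for this bundle and is reported as
a failing check rather than hidden.

Other limitations:

- Electrostatics off by default (see above); direct-sum smeared Coulomb
  (no mesh) when enabled.
- No multi-particle aggregation, cholesterol or surfactant proteins; one
  particle per leaflet, mirrored.
- Lateral box is never barostatted in the shipped protocols; P-A
  isotherms are traced by building at a series of areas per lipid.
- The cubic-lattice particle is slightly rough at bead scale; its
  interfacial footprint uses the ideal sphere cross-section.
- Desk-scale flip dynamics are faster and noisier than full scale; the
  transient tilted plateau (115-140 deg) is reproduced as a windowed
  trend, not as a converged free-energy minimum.
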