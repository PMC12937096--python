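# jmdpd

Dissipative particle dynamics (DPD) of amphiphilic **J**anus
nanoparticles interacting with DPPC **m**onolayers at the air-water
interface.

Inhaled nanoparticles meet the lung surfactant film — a phospholipid
monolayer (mostly DPPC) that regulates the surface tension of the
alveolar air-water interface. How a particle with both hydrophilic and
hydrophobic surface regions (a Janus particle) adheres to, crosses, or
lodges itself in that film determines both its toxicity and its value as
a drug carrier. `jmdpd` is a self-contained simulator + analysis
pipeline for this problem at desk scale: it builds the systems, runs the
dynamics, and measures the observables that distinguish the three
interaction outcomes — translocation into the water subphase, monolayer
coating of the particle, and intercalation of the particle into the film
as another amphiphile.

## The model in brief

Coarse-grained beads (water W = 3 H2O, gas B, DPPC as 14 beads
N-P-G2-C10, nanoparticle K/L) interact by soft linear DPD repulsions
`F = a_ij (1 - r/R_ij) r_hat` with a pairwise dissipative + random
thermostat (`sigma^2 = 2 k_B T gamma`). The air phase is made of
fictitious gas beads with an exponential conservative force

    F_exp(r) = a_Bj (e^{b r/R} - e^b) / (1 - e^b) r_hat,

steep enough at contact to support a quantitative air-water interface:
the shipped parameter bundle is calibrated so bulk water sits at the
reference pressure 23.7 k_BT/R_c^3 and the bare interface at
gamma_0 = 7.55 k_BT/R_c^2 = 73 mN/m (lab value 72.8 at 293 K).

The Janus particle is a cubic-lattice sphere, hydrophobic over a
spherical cap of height `h`; its coverage is `phi_L = h / D_NP`. A
double-monolayer geometry (gas | lipids | water | lipids | gas, periodic)
keeps the system z-symmetric, so the monolayer tension follows from the
pressure tensor,

    gamma_m = (L_z / 2) (P_zz - (P_xx + P_yy)/2),    Pi = gamma_0 - gamma_m,

and the analysis layer adds: particle orientation
`Theta_NP = arccos(u . n)` (u pointing hydrophobic -> hydrophilic cap),
tail order `S = (3 cos^2 theta - 1)/2` with liquid-condensed fraction
`f_LC = n_L(S > 0.6)/A_res`, the particle's interfacial footprint
`A_I^NP`, lost-lipid counts, the effective area per lipid
`a_L^eff = (Lx Ly - A_I^NP)/(n_L - n_L^w)`, and a contact-energy
decomposition of the surface energy
`E_S = sum_aj eps_aj n_aj + gamma_m (Lx Ly - A_I^NP)` with RDF-weighted
contact energies `eps_aj`.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Bulk-water equation of state (the model's reference state point):

```python
from jmdpd import DPDEngine, EngineConfig, load_forcefield
from jmdpd.builders import build_water_box

ff = load_forcefield("default")
state = build_water_box(ff, L=10.0, seed=1)       # 3000 W beads, rho = 3
eng = DPDEngine(state, ff, EngineConfig(dt=0.01, seed=2))
eng.run(10000)                                     # equilibrate
obs, _ = eng.run(50000)
print(f"T_kin = {obs['T_kin'].mean():.4f}")
print(f"P = {obs[['Pxx','Pyy','Pzz']].to_numpy().mean():.2f} kBT/Rc^3")
```

prints

```
T_kin = 0.6507
P = 23.66 kBT/Rc^3
```

i.e. the thermostat holds the mapped temperature (0.65 ~ 293 K) and the
pressure reproduces the 23.7 reference of the parameterization. A
scaled-down Janus-particle scenario runs end to end from the shell:

```sh
jmdpd scenario run --name intercalation --phil 0.5 --mode la \
    --scale 20 --seed 1 --steps 30000 --outdir out/
```

which builds a 70-lipid-per-leaflet double monolayer with a ~2.7-nm
particle above each leaflet (hydrophobic cap facing the film), runs the
staged protocol (frozen-mass isobaric relax, isobaric, isochoric
production) and writes `metrics.tsv` (per-frame `Theta_NP`, `A_I`,
`f_LC`, `a_eff`, lost lipids), `tension.tsv` (`gamma_m`, `Pi`),
`summary.json` with the mechanism label, and the final configuration as
extended XYZ.

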