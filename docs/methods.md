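# Methods

`anionflux` studies how multivalent phosphate anions move through an FCC
superlattice of positively charged, ligand-functionalized nanoparticles (NPs)
under a uniform electric field. It couples a coarse-grained Brownian-dynamics
generator to a trajectory-analysis layer (compartment classification,
residence-time survival kinetics, transition matrices, ionic transport,
density maps). This note records the model, its assumptions, the default
parameters and why they were chosen, and the known limitations.

## System and units

Reduced units throughout: length in nm, energy in kBT (300 K), time in
tau = nm²/D₀, where D₀ = kBT/γ is the diffusion coefficient of a single bead
with friction γ. The default γ = 2 gives D₀ = 0.5 nm²/tau.

One conventional FCC cell (edge a = 10 nm, periodic) holds four fixed NPs of
radius 1.2 nm carrying +24 e each — divisible by 3, 4 and 6, so each of the
four canonical anion species neutralizes the cell with an integer count:

| species | shape | beads | total charge | n per cell |
|---------|-------|-------|-------------|------------|
| P2 (pyrophosphate) | linear | 2 | −4 | 24 |
| P3 (trimetaphosphate) | ring | 3 | −3 | 32 |
| P4 (tetraphosphate) | linear | 4 | −6 | 16 |
| P6 (hexametaphosphate) | ring | 6 | −6 | 16 |

Anions are rigid bodies of beads (diameter 0.6 nm, bond length 0.6 nm);
charge is spread uniformly over beads, preserving the valence that enters
the electrophoretic force F = qE. Linear species are collinear; rings are
regular polygons.

## Forces

* **Electrophoretic drive.** Each bead feels q_b·E along the field axis.
  Fields are given in V/nm and converted with a coupling constant
  (default 6.0 kBT per e·V). The physical conversion at 300 K is 38.68; the
  smaller default is a deliberate desk-scale compression: short runs compress
  the timescale separation between adsorption-well escape and drift, so the
  drive is compressed by the same factor to keep the competition between
  electrophoresis and interfacial trapping — the phenomenon of interest —
  inside the simulated window. Field values are therefore "V/nm-equivalent";
  both constants are exposed (`FIELD_COUPLING`, `FIELD_COUPLING_PHYSICAL`)
  and the coupling is configurable per run.
* **Screened electrostatics.** Yukawa pair interactions
  U = ℓ·q₁q₂·exp(−r/λ)/r between beads and NPs and between beads of
  different anions, with prefactor ℓ = 0.7 kBT·nm (the aqueous Bjerrum
  length) and Debye length λ = 0.6 nm; cutoff 4λ. No Ewald summation: at
  sub-nm screening the mechanism (charge-proportional drive plus interfacial
  trapping) is insensitive to the long-range tail.
* **Excluded volume.** WCA repulsion between beads (σ = bead diameter) and
  against NP surfaces (σ_s = σ/2 on the surface-offset distance). Pair
  forces are capped at 150 kBT/nm: the r⁻¹² core is stiffer than an
  Euler–Maruyama step resolves at the default timestep, and capping inside
  the core is the usual overdamped-integrator regularization; the potential
  is untouched outside the core.
* **Interfacial adsorption.** A Gaussian well of depth ε per bead and width
  0.30 nm centered at each NP surface stands in for the van der Waals and
  correlation attraction of the TMA ligand shell. The depth is
  topology-dependent: 0.55 kBT (linear) vs 3.5 kBT (ring), emulating the
  larger, flatter contact of rigid rings. **The well is angularly
  corrugated**: its depth is modulated by a smooth cosine lattice
  (1 + β·cos kx·cos ky·cos kz with β = 1, spacing 0.5 nm), representing the
  discrete cationic ligand sites. This term is essential, not cosmetic: a
  radially symmetric well exerts no tangential force, so an adsorbed anion
  would slide frictionlessly around the sphere and detach downstream —
  adsorption would then never retard drift, and ring and linear species
  would be equally mobile. The corrugation creates hop barriers proportional
  to the number of engaged beads, which is what lets a six-bead ring (P6)
  resist the field more than a three-bead ring (P3) of identical per-bead
  charge.

## Integration

Euler–Maruyama: the geometric center moves by (D_t/kBT)·F·dt plus Gaussian
noise of variance 2·D_t·dt; the orientation quaternion is rotated by an
analogous angular update with isotropic D_r. Free-draining rigid-body
coefficients: D_t = D₀/n_beads and D_r = kBT/(γ·Σ|b_i|²) over body-frame
bead arms. The rotation vector is applied in the world frame; for an
isotropic rotational tensor this is statistically identical to body-frame
application. The default timestep 1.8×10⁻³ tau keeps the per-step RMS bead
displacement below 0.05σ. Orientations are renormalized every step; runs
abort on non-finite coordinates, quarter-box single-step jumps, or bead
overlaps below 0.1σ. Given a seed, trajectories are bit-reproducible; the
compiled (numba) and pure-numpy force kernels agree to ~1e-15 and either can
be forced.

Default runs are 30 000 steps (54 tau) saving every 30 steps (1001 frames),
32 anions for P3 — about 7 s on one core. These sizes are the package's
standard study conditions: long enough that interface residences
(~3 tau) decorrelate dozens of times per run, small enough that a full
species × field × seed sweep stays interactive.

## Compartments

Anion geometric centers are classified per frame by radial distance with
minimum-image convention: tetrahedral if within 2.0 nm of a corner site,
else octahedral if within 2.5 nm of a face-center site, else interface
(remaining void). Tetrahedral takes precedence when both conditions hold
(configurable). Points inside the NP core follow the same rule; the
simulator's excluded volume keeps them out in practice.

## Residence kinetics

Residence events are maximal uninterrupted frame runs inside one compartment
(a single frame outside ends the event; a `gap_tolerance` is available but
defaults to 0). Events touching the last frame are censored. Survival
curves C(t) = N(t)/N₀ align events at t = 0; censored events count as
surviving until their censoring time and then leave both numerator and
denominator (reduced-sample handling — this keeps C non-increasing and
avoids the upward bias of counting censored events as complete). The fit
C(t) = A₁e^(−t/λ₁) + A₂e^(−t/λ₂) uses bounded nonlinear least squares,
multi-start from a log-linear single-exponential fit (λ split into λ/3 and
3λ), restricted to grid points where at least 5 events survive; a
single-exponential alternative is always fitted and the better model by
small-sample AICc is reported (A₂ = 0 marks an effective single
exponential). The amplitude-weighted mean residence time is
τ = (A₁λ₁ + A₂λ₂)/(A₁ + A₂), a convex combination of the two time
constants. The amplitude sum is left free rather than constrained to
C(0) = 1, and is reported.

## Transitions and transport

Transition matrices pool (frame, frame+lag) label pairs over anions
(default lag 1 saved frame; matrices carry their lag), row-normalized;
rows without observations are reported as undefined rather than filled.
An event-mode alternative counts consecutive distinct-compartment
residences. Velocities are endpoint-based per anion
(Δx_unwrapped/elapsed); instantaneous per-frame velocities are available
for distributions. The ionic current is the box-averaged drift form
I = (1/L_x)·Σᵢ qᵢ·v_x,i (e per tau; anions moving −x carry conventional
current +x), J = I/(L_y·L_z), σ = J/E, ρ = 1/σ (undefined at E = 0).
Density maps bin wrapped centers on a 50³ grid (configurable), sum along z,
and divide every 2D map in a condition set by the single global maximum.

## What the generator does and does not emulate

It reproduces: charge-proportional electrophoresis; steric exclusion;
interfacial adsorption competing with the drive; periodic FCC confinement;
the resulting mobility ordering P2 > P4 > P3 > P6, field-gated superlinear
conduction, zero-field compartment confinement, and strong-field channelling
of anions through the interface void. It does not emulate: explicit water
(hydrodynamics are free-draining; no hydrodynamic interactions), ligand
flexibility or NP motion, Martini-level chemistry, polarization, or Ewald
electrostatics. Passing tests therefore validate the mechanism and the
analysis pipeline, not quantitative agreement with atomistic or experimental
magnitudes — velocities, currents and residence times are in reduced units
at a compressed field coupling.

## Known limitations

* **Tetrahedral vs octahedral residence.** In a perfect FCC all NP sites
  are crystallographically equivalent, so under the radial compartment rule
  the adsorbed layer at corner and face NPs is statistically identical; the
  2.5 nm octahedral ball then strictly contains the same bound layer as the
  2.0 nm tetrahedral ball plus an extra rebinding shell, and octahedral
  residences stochastically dominate tetrahedral ones (by a factor ~2 across
  every parameter regime explored). The package therefore reproduces the
  interface-first hierarchy (τ_interface > τ_tetrahedral) but not
  τ_tetrahedral > τ_octahedral; a real ligand shell breaks site equivalence
  in ways a purely radial rule cannot express; the estimator itself is
  unaffected.
* Adsorption depths per topology are emulation parameters calibrated to
  reproduce orderings, not magnitudes derived from chemistry.
* The reduced-sample survival estimator handles censoring without
  confidence bands; heavy censoring (runs much shorter than residence
  times) degrades tail estimates before it degrades τ.
* With 16–32 anions per cell, finite-size effects on absolute currents are
  present; orderings and ratios across conditions are robust to them.
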