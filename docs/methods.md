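# Model and methods

`shellcargo` simulates the assembly of an icosahedral microcompartment
shell around a two-species fluid cargo with a coarse-grained
patchy-particle model, and computes the binding thermodynamics of the
model by configurational integration.  This note documents the model, the
calibration of its under-determined constants, the numerical methods, the
conventions behind every reported free energy, and the limitations of the
desk-scale protocols.

## Units

Energies are in units of the thermal energy k_BT; lengths in units of the
cargo diameter r*, which equals the circumradius of the pentagonal subunit
and maps to about 13 nm for carboxysome-scale compartments.  Time is
reduced (timestep 0.005); masses count unit-mass pseudoatoms.  The 1 M
standard state corresponds to a volume per particle of
v0 = 1.661 nm^3 / (13 nm)^3 = 7.56e-4 r*^3, so all binding free energies
depend on the physical length mapping.

## Subunit model

Pentamers (circumradius 1) and hexamers (circumradius 1.176, the common
edge length) are rigid bodies carrying four classes of pseudoatoms
(`constants.py` is the single audited source of all coordinates):

* **Attractors** on the perimeter in the subunit plane.  Pentamer-facing
  edges carry 3 attractors (fractions 1/4, 1/2, 3/4 of the edge),
  hexamer-facing edges 4 (odd eighths).  Each position carries a
  registry-specific class; complementary classes pair only in the correct
  edge-to-edge registry, so shifted or flipped contacts have no attraction.
  Only three of the six hexamer edges are pentamer-compatible, and
  pentamer edges are mutually inert, which selects the T=3 target:
  12 pentamers + 20 hexamers in a truncated icosahedron with 90 edge
  contacts (60 pentamer-hexamer, 30 hexamer-hexamer).  Complementary pairs
  interact through a Morse potential with well depth eps_SS, rest length 0
  (attractors of bonded edges coincide in the ideal shell, which makes the
  blueprint an exact minimum of every bond) and inverse range
  alpha_SS = 22 (cutoff 0.35).
* **Edge Tops/Bottoms** just inside each edge midpoint at z = +-0.5.
  Cross-subunit WCA repulsions between them select the preferred dihedral
  angle: Top-Top engages when a bonded contact flattens, Bottom-Bottom
  when it over-bends.  Their diameters are *derived* from the ideal shell
  geometry so that neither engages within +-0.15 rad of hinge rotation
  about a bonded edge (the calibration is executed at import time from the
  blueprint and re-checked by the blueprint-is-a-minimum test).
* **Axial Tops/Bottoms** on the symmetry axis at z = +-0.5 provide central
  subunit-subunit excluded volume; the hexamer axial Bottom is the
  cargo-binding site (Morse, depth eps_SC identical for both cargo
  species, rest length 0.5 = cargo radius, inverse range 2.8).  Pentamer
  Bottoms are purely repulsive to cargo.
* **Excluders** in the Top plane (center + vertices) give the shell its
  cargo excluded volume.  They are massless interaction sites, so the
  center of mass and principal frame coincide with the geometric center.
  The excluder-cargo WCA diameter (0.8) makes every through-face path
  impassable (it comes within 0.59 r* of an excluder) while a
  missing-pentamer vacancy (rim clearance 1.0 r*) stays permeable, which
  the equilibrium-encapsulation protocol requires.

Cargo particles are points with species labels R/G, interacting through
cut-and-shifted 12-6 Lennard-Jones potentials (sigma 1, cutoff 3.0 - the
cutoff is calibrated against the printed vapor-liquid threshold, see
below) with well depths eps_RR, eps_GG, eps_RG by pair type.

## Calibration of the under-determined constants

The published description of this model fixes only the well depths; the
attractor layout, Morse ranges and Top/Bottom geometry are deferred to
appendices and prior work that print no coordinates.  We fixed them by
requiring the model's *computed* binding thermodynamics to reproduce the
reference table (dimerization free energy g_hh, per-subunit shell free
energy Delta g_shell, shell-cargo free energy g_SC):

* the slope of g_hh with eps_SS (-4.5 kT per 1.5 kT of well depth) fixes
  4 Morse bonds per hexamer-hexamer contact; the slope of Delta g_shell
  (-12 kT per 1.5 kT) then fixes 3 bonds per pentamer-hexamer contact
  ((60*3 + 30*4)/32 = 9.4 bonds per subunit);
* the *level* of g_hh (+4 kT at eps_SS = 2, i.e. binding is entropically
  prohibitive despite an 8 kT contact energy) fixes the basin volume and
  hence the Morse stiffness, alpha_SS ~ 22 (5 stiff relative-pose modes
  plus one hinge mode bounded by the +-0.15 rad window);
* g_SC = -14 kT at eps_SC = 6 fixes the shell-cargo Morse range (2.8):
  the bound cargo gains roughly -7.5 kT of energy (central site plus
  neighboring-site tails) and loses the rest to confinement.

A useful negative result: with *any* Morse stiffness, a bound-region
defined as "some attractor pair within the Morse cutoff" cannot reproduce
g_hh = +4.  The loosely-touching single-bond states then dominate the
configurational integral — their measure alone bounds g_hh below about
-7 kT.  Reproducing the table requires the tight-basin convention below.

## Binding free energies

All binding free energies use g = -ln(Z_b / (8 pi^2 v0)) with
Z_b = mult * int_D d^3r dOmega e^(-U) over the relative pose of the mobile
body and a basin D; Kd = (1 M) * exp(g).

* **Basin.** D is the fully engaged contact: *every* attractor pair of the
  contact registry within the half-depth radius of the Morse well
  (1.23/alpha ~ 0.056 r*).  The looser cluster-analysis bond criterion
  (any pair within the Morse cutoff) is deliberately not reused here (see
  the negative result above).
* **Multiplicity and convention.** g_hh is quoted per binding interface
  (one specific edge pair); symmetry-equivalent interfaces on other edges
  are not multiplied in.  The in-shell cell integrals include each
  subunit's own orientational multiplicity (5 for pentamers, 3 for
  hexamers), which is part of the cell partition function.
* **Evaluation.** Z_b is measured in two stages.  At coupling
  lambda_1 = eps/2 the integral is evaluated directly by importance
  sampling over a pose box, with rotations parametrized as rotation
  vectors about the contact-edge midpoint so that the soft hinge mode is
  axis-aligned (the Haar measure enters through the exact
  2(1-cos theta)/theta^2 Jacobian).  From lambda_1 to eps the well depth
  is switched on by thermodynamic integration, with Metropolis chains
  confined to D and Gauss-Legendre quadrature over the coupling.  The
  machinery is validated against a closed-form (1D quadrature) oracle for
  a single isotropic Morse well.
* **Per-subunit shell free energy.**  Delta g_shell = [U0 + sum_i f_i]/32
  + C + g_SC, where U0 is the relaxed-blueprint energy, f_i are
  independent-cell pose integrals (one per symmetry-distinct subunit in
  the field of its frozen neighbors), and C is the harmonic
  collective-mode correction (1/2)[ln det H - sum_i ln det H_ii] per free
  body, computed from a finite-difference Hessian over rigid-body
  coordinates with one body fixed.  By Fischer's inequality C <= 0: the
  independent-cell model ignores phonon softening and otherwise
  overestimates the shell free energy by ~1.2 kT per subunit.  Cargo-cargo
  contributions are excluded by construction (they would shift the
  effective shell stability depending on the cargo phase).
* **Shell-cargo free energy.** g_SC is the binding free energy of one
  cargo particle at the interior wall site of a hexamer of the complete
  shell (shell-cargo terms only), with the same machinery (no
  orientational degrees of freedom).

Monte Carlo errors are propagated from the importance-sampling stage and
the per-node thermodynamic-integration variances; estimates that do not
reach the requested precision raise an error carrying the running value.

## Dynamics

Rigid-body Langevin dynamics with a BAOAB splitting: half kicks,
symplectic Trotterized free-rotor drift (quaternion plus body-frame
angular momentum, axis sequence z-y-x-y-z), and an exact
Ornstein-Uhlenbeck velocity/angular-momentum update.  The OU step is
applied every 4th step with the compounded decay factor, which leaves the
stationary distribution unchanged and reduces the Gaussian-noise cost.
With zero friction the scheme is symplectic NVE (energy drift below 1e-4
over 1e4 steps is verified by regression).

`friction` is a per-body translational drag *coefficient* (default 1), so
every species has diffusion constant D = kT/friction and the Einstein
relation holds exactly in the diffusive regime.  A per-unit-mass friction
rate would make subunits ~35x slower than cargo and push every
diffusion-limited stage of assembly beyond desk-scale budgets; the choice
affects only the timescale mapping, not any equilibrium property.
Temperature is k_BT = 1 throughout (NVT).

Neighbor handling uses two cell-list Verlet structures (subunit-subunit
sites and cargo-interacting sites), linearized per-pair parameters,
displacement-triggered rebuilds (half-skin criterion) and wrapping at
every rebuild; pairs between two immobile bodies are skipped.  The
neighbor path is required by test to agree with the all-pairs double loop
to 1e-8.

## Scenario protocols and desk-scale sizes

The reference conditions are: assembly, 48 pentamers + 80 hexamers + 854
cargo (half R, half G) in a box of side 40 (about 1 uM hexamer and 10 uM
cargo at r* = 13 nm); bulk, 46,938 cargo in a box of side 160; permeable
shell, a fixed complete shell minus one pentamer (lowest index; immaterial
by symmetry) plus 854 cargo in a box of side 40.  All are overridable, and
`ScenarioSpec.scaled()` shrinks counts at fixed concentration.

The package's own desk-scale problem sizes are:

* **Vapor-liquid threshold.**  Homogeneous nucleation at the working
  concentration has a classical barrier of roughly 25 kT near the
  threshold and is unobservable in any affordable run, so the scan uses
  droplet direct coexistence: half the cargo is planted as a dense ball
  and the threshold is bracketed by whether the largest r < 1.2 contact
  cluster persistently exceeds 20% of the cargo (evaporation below
  coexistence, persistence above).  With N = 850 in a box of side 40,
  7e4 steps and three seeds per affinity, the bracket is [1.2, 1.3]
  (midpoint 1.25), consistent with the ~1.3 kT threshold.  The planted
  droplet carries a small Kelvin (curvature) bias, and the cargo LJ cutoff
  matters at this precision: at 2.5 sigma the measured threshold is ~1.45,
  which motivated the calibrated 3.0 sigma cutoff (constants.py).
* **Assembly.**  One-shell stoichiometry (12 + 20 + 214 cargo, box 25.2)
  with 2.5e5-step trials.  Under the calibrated tight-basin attractors,
  bond formation requires aligning an edge to ~0.06 r* and a few degrees;
  measured cluster growth reaches only 4-7 subunits by 1.6e6 steps, so
  complete shells are *not* expected at desk scale (see Limitations).
* **Permeable shell.**  2.5e5-step runs.  The measured cargo exchange rate
  through the single vacancy (~0.004 per tau) implies ~10^7 steps to
  equilibrate the interior census, so the desk-scale run documents the
  transient rather than the equilibrated composition.

## Synthetic data and fixtures

The planted fixtures (complete shell, geometrically filled shell, janus
and checkerboard globules, vapor) are deterministic configurations with
attached ground truth, used as oracles for shell detection, the
point-in-polyhedron census (validated against a winding-number oracle on
500 planted points) and phase classification.  The filled-shell lattice is
geometric (spacing chosen to fit the requested count) and not a physical
configuration.  None of the fixtures emulate thermal interface roughness,
vacancy defects, or polydispersity of real assemblies, so tests passing on
them validate the analysis operations, not the realism of the model.

## Numerical choices

* Potentials are cut and shifted to zero at their cutoffs (forces carry
  the standard small discontinuity at the cutoff).
* The Morse kernel uses the analytic r -> 0 force limit for rest length 0.
* Initial conditions reject any placement inside an interacting pair's
  repulsive core, so runs start essentially overlap-free; the brute-force
  minimum-separation property is tested.
* Quaternions are renormalized every free-rotor update; unit norm is
  asserted to 1e-9 after every run.
* The blueprint relaxation (adaptive rigid-body steepest descent) removes
  the ~1 kT/r* residual generalized forces that sub-cutoff Morse tails
  leave on the ideal polyhedron.
* Shell completeness requires the exact 12 + 20 stoichiometry *and* closed
  topology (pentamer degree 5, hexamer degree 6); sigma_R,shell uses the
  population normalization.
* Phase classification thresholds (condensate minimum size 20, purity
  bound 0.2, demixing threshold f_UL < -0.1) are exposed as arguments.

## Known limitations

* The thermodynamic calibration and the printed assembly timescales are
  mutually inconsistent: any model whose true two-body integral gives
  g_hh(3.5) = -0.5 kT has a dissociation-dominated dimer and an
  alignment-entropy bottleneck for bond formation, which makes spontaneous
  shell completion at desk scale (and, by the same estimate, within the
  reference 2e6-step budget) kinetically out of reach.  This package
  resolves the tension in favor of the thermodynamic table; the assembly
  and equilibrium-encapsulation scenario tests therefore run honest
  desk-scale protocols and may fail their target values.
* The shell interior (inradius ~2.7 r* at the stated subunit size) cannot
  hold ~150 unit-diameter cargo at liquid density; the geometric capacity
  is roughly 70-90.  The reference loading value appears to assume a
  larger shell-to-cargo size ratio than the stated unit mapping implies.
* The independent-cell + harmonic-collective treatment of the shell free
  energy neglects anharmonic mode coupling; the residual bias is absorbed
  by the calibration and is within the quoted tolerances.
* No electrostatics, hydrodynamics, solvent, scaffold-mediated
  interactions, or non-T=3 geometries.
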