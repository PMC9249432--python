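# shellcargo

Coarse-grained simulation and analysis of icosahedral microcompartment
shell assembly around a two-species fluid cargo.

Bacterial microcompartments (such as the carboxysome) are protein
organelles: an icosahedral shell of pentameric and hexameric subunits
assembles around a dense complex of enzymes and other cargo.  `shellcargo`
implements a minimal patchy-particle model of this process with two cargo
species, "R" and "G".  Rigid subunits carry perimeter **Attractor** sites
(short-range Morse attractions between complementary edges, well depth
ε_SS), **Top/Bottom** sites whose mutual repulsions set the preferred
dihedral angle so that the energy minimum is a T=3 shell (12 pentamers +
20 hexamers, 90 edge contacts), cargo-binding **Bottom** sites (Morse,
depth ε_SC, identical for both species) and **Excluder** sites.  Cargo
pairs interact through Lennard-Jones attractions with well depths ε_RR,
ε_GG, ε_RG.  All energies are in k_BT, lengths in the cargo diameter
r* ≈ 13 nm.

The package provides:

* `geometry` — subunit templates and the ideal T=3 shell blueprint;
* `interactions` — all pair potentials, complementarity, and total
  energy/force/torque evaluation (numba-accelerated, neighbor lists
  validated against an all-pairs oracle);
* `dynamics` — rigid-body Langevin dynamics (BAOAB with a symplectic
  quaternion free-rotor drift) in a periodic box;
* `thermo` — binding free energies by Monte Carlo configurational
  integration: hexamer dimerization g_hh and its dissociation constant
  K_d = (1 M)·exp(g/k_BT), the free energy per subunit in a complete shell
  Δg_shell, the shell–cargo free energy g_SC, and reduced-unit → molar
  conversion;
* `analysis` — subunit bond graph, shell detection/completeness, the
  encapsulated-cargo census (N_C, f_R), mixing metrics
  (f̄_UL = n_RG/(n_RR+n_GG+n_RG), f_rand = 2 f_R (1−f_R),
  f_UL = f̄_UL − f_rand), shell-to-shell variability σ_R,shell, and bulk
  phase classification;
* `scenarios` — the assembly, bulk-cargo and permeable-shell protocols plus
  planted test fixtures;
* a `shellcargo` command-line interface
  (`assemble | bulk | equilibrate | analyze | thermo | fixture | potentials`).

See `docs/methods.md` for the model constants, free-energy conventions,
calibration and limitations.

## Worked example

Binding thermodynamics of the shell at the two reference shell–shell
affinities:

```python
from shellcargo.interactions import InteractionTable
from shellcargo.thermo import (dimer_free_energy, dissociation_constant,
                               shell_site_free_energy, to_molar)

for eps_ss in (2.0, 3.5):
    t = InteractionTable(eps_ss=eps_ss, eps_sc=6.0)
    ghh = dimer_free_energy(t, n_samples=400_000, seed=1)
    dgs = shell_site_free_energy(table=t, n_samples=250_000, seed=1)
    print(f"eps_SS={eps_ss}: g_hh={ghh.g:+.2f} kT  "
          f"Kd_hh={dissociation_constant(ghh):.2g} uM  "
          f"dg_shell={dgs.g:+.2f} kT  "
          f"g_SC={dgs.metadata['shell_cargo_part']:+.2f} kT")

print("cargo concentration:", round(to_molar(854, 40.0), 1), "uM")
```

prints (seed 1):

```
eps_SS=2.0: g_hh=+4.03 kT  Kd_hh=5.6e+07 uM  dg_shell=-14.99 kT  g_SC=-14.61 kT
eps_SS=3.5: g_hh=-0.66 kT  Kd_hh=5.2e+05 uM  dg_shell=-27.10 kT  g_SC=-14.61 kT
cargo concentration: 10.1 uM
```

Read: at ε_SS = 2 k_BT a hexamer *dimer* is unbound (g_hh = +4 k_BT — the
entropic cost of aligning an edge contact exceeds the ~8 k_BT contact
energy), yet a subunit in the complete shell with its cargo layer is bound
by ≈ −15 k_BT — assembly is driven by cooperativity and by the shell–cargo
attraction (g_SC ≈ −14.6 k_BT per subunit at ε_SC = 6), not by pairwise
subunit affinity.  Raising ε_SS to 3.5 k_BT deepens the per-subunit shell
free energy to ≈ −27 k_BT.  The reference mixture (854 cargo, 80 hexamers,
48 pentamers in a box of side 40 r*) corresponds to ≈ 10, 1 and 0.6 µM.

Dynamical scenarios run from configs, e.g. a scaled-down assembly:

```sh
shellcargo assemble --config examples/assembly.yaml --seed 1 --trials 2 --out runs/
shellcargo thermo --eps-ss 2.0 --eps-ss 3.5 --out runs/
```

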