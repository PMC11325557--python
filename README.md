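# metim

Tools for the **12–6–4 Lennard-Jones nonbonded model** of metal ions
coordinating imidazole — the binding motif through which histidine side
chains hold Zn(II), Ni(II), Co(II) and other divalent ions in
metalloproteins — together with the complete free-energy-matched
parametrization and validation workflow around it, runnable at desk scale.

## The model

A spherical, nonbonded metal ion interacts with each ligand atom through

```
U(r) = A/r¹² − B/r⁶ − C4/r⁴ + k_e·Q_i·Q_j / r
```

the standard 12–6 Lennard-Jones plus Coulomb form augmented with an
attractive `C4/r⁴` ion-induced-dipole term.  The pair coefficient
`C4` (kcal/mol·Å⁴) is derived from the ligating atom type's
polarizability α₀ (Å³) through the induced-dipole closed form
`C4 = (k_e/2)·Q_i²·α₀·cos²θ` with θ = 0 and
`k_e = 332.0637 kcal·Å/(mol·e²)`.  α₀ of the ε-nitrogen (AMBER atom type
NB) is the single tuning knob: it is adjusted by secant iteration until
the simulated imidazole binding free energy matches the experimental
value within ±0.1 kcal/mol.

Around the potential the package provides

* **`metim.forcefield`** — ion/atom-type/ligand parameter objects, pair
  energy and force, polarizability→C4 mapping, total nonbonded energy;
* **`metim.toysim`** — a BAOAB Langevin engine for ion + rigid-ligand
  toys (implicit bath, NVT), harmonic umbrella restraints, steered
  seeding of windows, and 12-window linear-mixing thermodynamic
  integration (TI);
* **`metim.pmf`** — WHAM assembly of umbrella windows into a potential
  of mean force, the radial-entropy correction, and standard-state
  (1 M) binding free energies via the volume-corrected Boltzmann
  integral;
* **`metim.parametrize`** — the secant calibration loop against the
  packaged registry of 11 experimental metal–imidazole binding free
  energies;
* **`metim.thermocycle`** — thermodynamic-cycle closure ΔΔG, MAE over
  cycle sets, triplicate statistics;
* **`metim.saptc4`** — C4 from SAPT induction energies, by single-point
  evaluation `C4 = −E_ind·r⁴` or least squares over a 1.7–3.0 Å scan;
* **`metim.fixtures`** — exact-density synthetic umbrella windows drawn
  from analytic free-energy profiles (inverse-CDF sampling), for testing
  WHAM without sampler-convergence confounds;
* **`metim.io`** — mol2 (subset) and frcmod-style readers/writers, window
  series files, CSV registries.

## Worked example

Calibrate the ε-nitrogen polarizability for Zn(II) against its
experimental binding free energy (−3.48 kcal/mol) using the built-in
deterministic surrogate evaluator:

```
$ metim fit --ion "Zn(II)" --oracle surrogate
replicate 0: 3 iterations, alpha0 = 0.724445 Å³, C4 = 481.12 kcal/mol·Å⁴, ΔG = -3.5176 (target -3.48) kcal/mol
```

Three evaluations of the surrogate suffice: the secant proposals walk α₀
from the registry seed (0.5 Å³) to 0.724 Å³, where the simulated ΔG sits
0.038 kcal/mol from the target — inside the ±0.1 acceptance band.  The
corresponding C4 of 481 kcal/mol·Å⁴ is in the range typical of divalent
transition metals against imidazole nitrogen (e.g. 424 for Zn(II) in the
shipped parameter block).

Assemble a PMF from synthetic umbrella windows and pull out its
stationary structure:

```
$ metim fixtures --family double-well --out-dir wins/
$ metim pmf --windows wins/ --out-dir pmf_out/
{
  "n_windows": 20,
  ...
  "stationary_points": [
    {"position": 2.113, "value": 0.076, "kind": "min", "barrier": null},
    {"position": 2.963, "value": 3.932, "kind": "max", "barrier": 3.856},
    {"position": 3.988, "value": 2.490, "kind": "min", "barrier": null}
  ]
}
```

(positions/values abridged to 3 decimals).  The recovered profile shows
the bound well at 2.11 Å, the shallow outer minimum near 4 Å (the
analogue of the tilted cation-π intermediate that appears near the
second solvation shell under extended sampling), and the 3.9 kcal/mol
barrier between them — the generating double well has its minima at 2.1
and 4.0 Å.

`metim cycle` prints closure MAEs for the packaged cycle tables, and
`metim sapt-c4 --scan scan.csv` fits C4 to induction-energy scans.

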