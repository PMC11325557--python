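# Methods

## The potential

The nonbonded interaction between a metal ion *i* and a ligand atom *j* is

    U(r) = A/r¹² − B/r⁶ − C4/r⁴ + k_e·Q_i·Q_j/r

with A = ε·Rmin¹², B = 2ε·Rmin⁶ built by Lorentz–Berthelot combining
(arithmetic Rmin from the two Rmin/2 halves, geometric ε) — the AMBER
convention and the only combining rule supported.  The Coulomb constant
is fixed at k_e = 332.0637 kcal·Å/(mol·e²).  Units are global and not
negotiated in APIs: Å, kcal/mol, elementary charges, fs, amu.

The C4 coefficient (kcal/mol·Å⁴) scales the ion-induced-dipole
attraction.  Lookup is pair-specific: a tabulated (ion, atom-type) entry
wins; otherwise C4 is derived from the atom type's polarizability α₀
(Å³) through the induced-dipole closed form

    C4 = (k_e/2) · Q_i² · α₀ · cos²θ,   θ = 0,

i.e. the induced dipole is taken parallel to the ion–atom axis.  The
relation is linear and homogeneous in α₀, which is what makes α₀ a
clean one-dimensional tuning knob.  Atom types without a polarizability
get C4 = 0 and reduce exactly to 12–6 LJ + Coulomb.  The cutoff is a
hard truncation (default 10 Å); no switching or shifting is applied.

## The toy engine

`toysim` integrates an ion plus rigid ligands with BAOAB-split Langevin
dynamics in an implicit bath.  Defaults mirror a conventional aqueous
protocol: 2 fs timestep, 300 K, collision frequency 1 ps⁻¹.  The
ensemble is NVT: with no explicit solvent a barostat would couple to
nothing, so no pressure control is attempted — this is a deliberate
divergence from explicit-solvent NPT workflows and is the main reason
the engine's energetics are validated against closed forms and
surrogates rather than against solution experiments.

Ligands are rigid bodies in the restricted sense that they translate as
units (net nonbonded force applied to the centre of mass, total mass
default 68.1 amu) with frozen orientation; rotational Langevin dynamics
is not implemented.  For the validation targets exercised here —
equipartition, stiff-spring windows, TI closed forms, and cycle closure
with a single-site ligand — orientational freedom is immaterial; for
multi-atom ligands the frozen orientation is a known limitation.

Umbrella windows bias the ion–atom distance with U = k/2·(d − d₀)²;
window seeds derive as `seed + window index` so windows are decorrelated
but reproducible, and the first 10% of each window is discarded as
equilibration (configurable).  Steered runs move a stiff harmonic
restraint at constant velocity between two distances and emit snapshots
at evenly spaced restraint centers (default 120) to seed windows.

Thermodynamic integration mixes two parameter sets linearly,
U(λ) = (1−λ)U_A + λU_B over a 12-point λ schedule by default; dU/dλ =
U_B − U_A is sampled per window, ΔG comes from trapezoidal quadrature,
and the standard error propagates from 10-block averages per window.
Identical endpoints give exactly zero without sampling noise.

## PMF assembly and binding free energies

WHAM runs the textbook self-consistent equations on 1-D histograms
(default 200 bins over the sampled span) with harmonic biases, by direct
fixed-point iteration — no acceleration, for auditability — to a
tolerance of 1e-7 kcal/mol on the window offsets (max 1e5 iterations).
Adjacent windows sharing fewer than 5 samples trigger a warning;
disjoint windows are an error naming the gap.  Edge bins with fewer
than 10 total counts are trimmed: their free energies are dominated by
extreme-tail noise of the outermost windows.  Uncertainties come from a
per-window block bootstrap (default 50 resamples, block length set by an
integrated-autocorrelation-time estimate).

A distance PMF estimated from raw histograms in 3-D carries the
spherical-shell entropy −2k_BT·ln r and therefore drifts downward at
long range; `remove_radial_entropy` restores the centred profile before
binding-energy extraction.  The binding free energy is then

    ΔG = −k_BT · ln( ∫_bound 4πr² e^(−G(r)/k_BT) dr / V° )

with G referenced to the bulk plateau (linear fit over the outermost 20%
of the range; tail slope below 0.05 kcal/mol/Å required, relaxable for
noisy toy profiles) and V° the volume per molecule at the standard-state
concentration (1 M → 1660.5 Å³).  The integral treats the profile as
piecewise constant per bin, which makes it exact for bin-aligned square
wells and removes quadrature order as a concern.  A "well depth minus
plateau" estimator is available behind a flag for sensitivity checks.

Stationary-point extraction supports optional reflection-padded
moving-average smoothing and a prominence filter that prunes adjacent
extremum pairs below a free-energy contrast threshold (the CLI defaults
to a 7-bin window and 0.2 kcal/mol, roughly k_BT/3).

## Calibration loop

The polarizability of the ligating ε-nitrogen is calibrated per ion
against its experimental binding free energy.  Each iteration evaluates
ΔG(α₀); acceptance is |ΔG − ΔG_exp| ≤ 0.1 kcal/mol.  On rejection, the
next α₀ is the root of the secant line through the two most recent
(α₀, ΔG) points — the formalization of "linear extrapolation between
iterates" — clamped to α₀ ≥ 0.  A degenerate secant slope
(|ΔΔG| < 1e-6) or a repeated proposal falls back to bisecting the
tightest bracketing pair; with no bracket the loop raises.  The full
audit trail (α₀, C4, ΔG, SE, acceptance) is returned and serializable as
JSON-lines; for deterministic evaluators it is replayable bit-exactly.
When a stochastic evaluator's SE exceeds the tolerance, the loop warns
that the acceptance criterion is statistically unresolvable.

The packaged registry holds the 11 experimental metal–imidazole binding
free energies used as targets.  Its `alpha_seed_A3` column is a generic
starting guess (0.5 Å³ for divalent, 0.2 Å³ for monovalent ions) chosen
by this package, not a literature value.

The deterministic surrogate oracle ΔG(α) = a + b·α − c·s·log(1+e^((α−x0)/s))
(affine plus softplus; b < 0, c ≥ 0 enforce strict decrease) stands in
for a full umbrella-sampling evaluation when testing loop mechanics.
The default coefficients (a = 0, b = −4, c = 2, x0 = 0.5, s = 0.25) give
a smooth, monotone map whose values and slopes are of the magnitude the
real α₀ → ΔG relation exhibits for divalent ions (a few kcal/mol per
Å³); they were fixed once when the surrogate was designed.

## Thermodynamic cycles

A cycle joins two PMF binding legs (dg1: ion A, dg3: ion B, same
ligands) and two TI mutation legs (dg2: A→B bound, dg4: A→B aqueous).
The sign convention — binding legs point into the complex, mutation legs
A→B, closure = dg1 + dg2 − dg3 − dg4 — is fixed in code and printed in
every report.  Closure SE is the quadrature sum of leg SEs, the
within-uncertainty flag compares |closure| to 1σ by default (2σ
available), and the MAE over a cycle set is the mean absolute closure.

The desk-scale re-enactment (`metim.validation.toy_cycle_closure`) uses
two toy divalent ions differing only in C4 (250 vs 320 kcal/mol·Å⁴)
against one rigid single-site neutral ligand.  PMF legs use 28 windows
(0.15 Å spacing across the steep well from 1.6–3.2 Å, 0.3 Å outside, to
8.1 Å; k = 30 kcal/mol/Å², 8000 steps per window) in triplicate with
disjoint seed blocks, summarized as mean ± SE.  The bound-complex TI leg
adds a half-harmonic containment wall at the same 4.5 Å cutoff that
bounds the PMF integral, so both routes define the bound ensemble
identically and standard-state volume terms cancel in the closure.  The
aqueous leg is computed by TI on the lone ion and is exactly zero — an
isolated ion in an implicit bath has nothing to interact with.  These
problem sizes are the package's chosen desk-scale study conditions; the
closure test passes when |ΔΔG| ≤ 2× the combined SE.

## SAPT-derived C4

The induction component of a SAPT decomposition behaves as −C4/r⁴ at
long range.  Two estimators are provided: the single-point value
C4 = −E_ind·r⁴ at an equilibrium distance, and an unweighted least
squares of E_ind(r) ≈ −C4/r⁴ over a distance scan, with the closed form
C4 = −Σ E_i r_i⁻⁴ / Σ r_i⁻⁸ (an r⁴-weighted variant sits behind a
flag).  Unweighted-in-energy is the simplest defensible choice; no
weighting scheme is claimed for the reference data.  Averaging across
the two methods is disallowed because short-range effects (exchange
damping, charge transfer) push them apart systematically: damped
induction at short range pulls the scan fit below the equilibrium-point
value, which is exactly the pattern the packaged
Zn(imidazole)₆₋ₙ(H₂O)ₙ table shows (equilibrium-point column averaging
470.8, scan-fit column 411.9 kcal/mol·Å⁴).  Reported values round to
1 decimal; full precision is kept internally.  The mapping between
specific equilibrium distances and table rows is not packaged because it
is not recorded with the reference values; fixtures do not fabricate it.

## Synthetic data

`metim.fixtures` draws umbrella-window samples directly from the biased
Boltzmann density exp(−[G(r) + k/2(r−r₀)²]/k_BT) of an analytic profile
by inverse-CDF sampling on a 1e-3 Å grid spanning the restraint center
± 5σ.  Exactness is the point: when WHAM is tested against these
windows, any disagreement is attributable to WHAM, not to sampler
convergence.  The default study condition for the double-well recovery
check is 20 windows, k = 20 kcal/mol/Å², 5000 samples per window.

What the generator does *not* emulate: time correlation within windows
(samples are i.i.d., unlike MD), solvent degrees of freedom, the
3-D radial Jacobian (profiles are defined directly on the distance
coordinate), and barrier-crossing kinetics.  Passing these tests
therefore certifies the estimators' correctness on ideal input, not the
adequacy of any particular sampling length on real systems — that is
what the toy-engine cycle closure probes, at toy scale only.

## Numerical choices and degenerate inputs

- WHAM tolerance 1e-7 kcal/mol on offsets, max 1e5 direct iterations;
  exceeding them raises with the residual attached.
- Binding-energy extraction refuses profiles without a plateau and
  cutoffs below the sampled range.
- The Langevin engine raises a step-rejection error (with the step index
  and distance) when an ion–atom distance falls below 0.3 Å.
- Secant degeneracy threshold 1e-6 kcal/mol; proposals clamp to α₀ ≥ 0.
- TI requires a sorted λ schedule spanning [0, 1] with ≥ 2 points.
- Ties in stationary-point detection use strict/non-strict comparison
  pairs so flat plateaus do not generate duplicate extrema.

## Known limitations

- No explicit solvent, PME electrostatics, barostat, or multi-ion
  systems; protein-scale TI legs are consumed as data, not produced.
- Ligand orientation is frozen; intramolecular ligand energetics are out
  of scope (rigid bodies).
- MBAR is not implemented (WHAM only); 2-D PMFs are not supported.
- mol2 support is the MOLECULE/ATOM/BOND subset with required charges;
  general AMBER prmtop parsing is out of scope.
- The packaged imidazole mol2/frcmod files are synthetic stand-ins with
  plausible geometry and charges summing to the formal charge; they are
  not RESP-fitted deposited values and are labelled accordingly.
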