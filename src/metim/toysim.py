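"""Desk-scale stochastic dynamics for ion-ligand toys.

A BAOAB-discretized Langevin integrator propagates an ion plus rigid
ligands in an implicit bath (NVT; there is no solvent, so no pressure
coupling).  Ligands translate as rigid units — the net nonbonded force
acts on the centre of mass and the orientation is frozen.  On top of the
12-6-4 nonbonded energy the engine supports harmonic umbrella restraints
on the ion-atom distance, constant-velocity steering to seed windows, and
linear-mixing alchemical thermodynamic integration between two ion
parameter sets.

Internal units: Å, kcal/mol, amu, fs.  Accelerations use the conversion
1 kcal/mol/Å / amu = 4.184e-4 Å/fs².
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forcefield import Configuration, IonSpec, LigandTopology, lj_pair_coefficients, COULOMB_CONSTANT

__all__ = [
    "KB",
    "SimulationConfig",
    "UmbrellaRestraint",
    "DistanceSeries",
    "AlchemicalPath",
    "TIResult",
    "ToySystem",
    "HarmonicSystem",
    "StepRejectionError",
    "run_dynamics",
    "run_window",
    "steer",
    "ti_free_energy",
    "SurrogateOracle",
    "surrogate_binding_dg",
]

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: kcal/mol/Å per amu -> Å/fs².
FORCE_TO_ACC = 4.184e-4


class StepRejectionError(RuntimeError):
    """Raised when integration produces an unphysical overlap."""


@dataclass(frozen=True)
class SimulationConfig:
    """Langevin run settings.

    Defaults mirror a standard aqueous-simulation protocol: 2 fs timestep,
    300 K, collision frequency 1 ps⁻¹, 10 Å nonbonded cutoff.
    """

    timestep: float = 2.0  # fs
    temperature: float = 300.0  # K
    friction: float = 1.0  # ps^-1
    cutoff: float = 10.0  # Å
    seed: int = 0
    n_steps: int = 10000
    stride: int = 10
    equilibration_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction must be in [0, 1)")


@dataclass(frozen=True)
class UmbrellaRestraint:
    """Harmonic bias U = k/2 (d - center)² on an ion-atom distance.

    ``ligand_index``/``atom_name`` select the ligand atom; ``atom_name``
    None means the ligand's first atom.  On systems without ligands the
    distance is measured from the coordinate origin.
    """

    center: float  # Å
    spring_constant: float  # kcal/mol/Å²
    ligand_index: int = 0
    atom_name: str | None = None

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.center <= 0:
            raise ValueError("restraint center must be positive")

    def energy(self, d: float) -> float:
        return 0.5 * self.spring_constant * (d - self.center) ** 2

    def dUdd(self, d: float) -> float:
        return self.spring_constant * (d - self.center)


@dataclass
class DistanceSeries:
    """Restrained-distance record of one umbrella window."""

    values: np.ndarray  # Å
    sampling_interval: float  # fs
    restraint: UmbrellaRestraint

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("distances must be positive")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Systems
# ---------------------------------------------------------------------------

class ToySystem:
    """Ion + rigid ligand(s) interacting through the 12-6-4 potential.

    Bodies are the ion (index 0) and one centre-of-mass site per ligand;
    ligand atoms sit at fixed offsets from their body's position.
    """

    def __init__(
        self,
        ion: IonSpec,
        ligands: list[LigandTopology],
        ion_mass: float = 65.4,
        ligand_mass: float = 68.1,
        cutoff: float = 10.0,
        min_distance: float = 0.3,
    ) -> None:
        self.ion = ion
        self.ligands = ligands
        self.cutoff = cutoff
        self.min_distance = min_distance
        self.masses = np.array([ion_mass] + [ligand_mass] * len(ligands))
        self._offsets = []
        for topo in ligands:
            ref = topo.reference_coords()
            self._offsets.append(ref - ref.mean(axis=0))
        self._param_cache: dict[int, tuple] = {}

    @property
    def n_bodies(self) -> int:
        return 1 + len(self.ligands)

    def _atom_tables(self, ion: IonSpec):
        key = id(ion)
        if key not in self._param_cache:
            tables = []
            for topo in self.ligands:
                a = np.empty(topo.n_atoms)
                b = np.empty(topo.n_atoms)
                c4 = np.empty(topo.n_atoms)
                qq = np.empty(topo.n_atoms)
                for k, (_, tname, q, _) in enumerate(topo.atoms):
                    atype = topo.atom_types[tname]
                    a[k], b[k] = lj_pair_coefficients(ion, atype)
                    c4[k] = ion.c4_for(atype)
                    qq[k] = COULOMB_CONSTANT * ion.charge * q
                tables.append((a, b, c4, qq))
            self._param_cache[key] = tables
        return self._param_cache[key]

    def initial_coords(
        self, ion_ligand_distance: float = 2.1, atom_name: str | None = None
    ) -> np.ndarray:
        """Bodies on coordinate axes: ion at origin, each ligand placed so
        its anchor atom (``atom_name``, default the first atom) sits
        ``ion_ligand_distance`` Å from the ion."""
        x = np.zeros((self.n_bodies, 3))
        for li, topo in enumerate(self.ligands):
            direction = np.zeros(3)
            direction[li % 3] = 1.0
            idx = 0 if atom_name is None else topo.atom_index(atom_name)
            x[1 + li] = direction * ion_ligand_distance - self._offsets[li][idx]
        return x

    def atom_positions(self, x: np.ndarray, ligand_index: int) -> np.ndarray:
        return x[1 + ligand_index] + self._offsets[ligand_index]

    def distance(self, x: np.ndarray, ligand_index: int = 0, atom_name: str | None = None) -> float:
        topo = self.ligands[ligand_index]
        idx = 0 if atom_name is None else topo.atom_index(atom_name)
        pos = x[1 + ligand_index] + self._offsets[ligand_index][idx]
        return float(np.linalg.norm(pos - x[0]))

    def energy_and_forces(self, x: np.ndarray, params: IonSpec | None = None):
        """Total nonbonded energy and per-body forces for ion spec ``params``
        (default: the system's own ion)."""
        ion = self.ion if params is None else params
        tables = self._atom_tables(ion)
        u = 0.0
        forces = np.zeros_like(x)
        for li, (a, b, c4, qq) in enumerate(tables):
            pos = x[1 + li] + self._offsets[li]
            dr = pos - x[0]
            r = np.linalg.norm(dr, axis=1)
            if np.any(r < self.min_distance):
                raise StepRejectionError(
                    f"ion-atom overlap: min distance {r.min():.3f} Å < "
                    f"{self.min_distance} Å (ligand {li})"
                )
            mask = r <= self.cutoff
            if not mask.any():
                continue
            rm = r[mask]
            inv = 1.0 / rm
            inv2 = inv * inv
            inv4 = inv2 * inv2
            inv6 = inv4 * inv2
            u += float(
                np.sum(a[mask] * inv6 * inv6 - b[mask] * inv6 - c4[mask] * inv4 + qq[mask] * inv)
            )
            # dU/dr, then force on the atom along +dr
            dudr = (
                -12.0 * a[mask] * inv6 * inv6 * inv
                + 6.0 * b[mask] * inv6 * inv
                + 4.0 * c4[mask] * inv4 * inv
                - qq[mask] * inv2
            )
            fvec = (-dudr * inv)[:, None] * dr[mask]
            forces[1 + li] += fvec.sum(axis=0)
            forces[0] -= fvec.sum(axis=0)
        return u, forces

    def to_configuration(self, x: np.ndarray) -> Configuration:
        return Configuration(
            ion_position=x[0].copy(),
            ligand_positions=[self.atom_positions(x, li) for li in range(len(self.ligands))],
        )


class HarmonicSystem:
    """Single particle in an isotropic harmonic well U = k/2 |x - c|².

    The TI ``params`` argument is interpreted as the spring constant, so a
    path between two spring constants realizes the textbook two-oscillator
    free-energy difference ΔG = (3/2) k_B T ln(k₂/k₁).
    """

    def __init__(self, spring_constant: float, center=(0.0, 0.0, 0.0), mass: float = 40.0) -> None:
        self.spring_constant = spring_constant
        self.center = np.asarray(center, dtype=float)
        self.masses = np.array([mass])
        self.ligands: list = []

    @property
    def n_bodies(self) -> int:
        return 1

    def initial_coords(self, ion_ligand_distance: float = 0.0) -> np.ndarray:
        return self.center.copy().reshape(1, 3)

    def distance(self, x: np.ndarray, ligand_index: int = 0, atom_name: str | None = None) -> float:
        return float(np.linalg.norm(x[0]))

    def energy_and_forces(self, x: np.ndarray, params: float | None = None):
        k = self.spring_constant if params is None else float(params)
        dr = x[0] - self.center
        u = 0.5 * k * float(dr @ dr)
        forces = np.zeros_like(x)
        forces[0] = -k * dr
        return u, forces


# ---------------------------------------------------------------------------
# BAOAB Langevin integration
# ---------------------------------------------------------------------------

def _baoab(config, system, x0, bias_fn, observe, params=None):
    """Core BAOAB loop.

    ``bias_fn(x) -> (U_bias, F_bias)`` or None; ``observe(step, x)`` is
    called every ``config.stride`` steps after step >= 0.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.timestep
    kT = KB * config.temperature
    gamma = config.friction * 1e-3  # ps^-1 -> fs^-1
    m = system.masses[:, None]
    c1 = np.exp(-gamma * dt)
    sigma_v = np.sqrt(kT * FORCE_TO_ACC / m * (1.0 - c1 * c1)) if kT > 0 else 0.0

    x = np.array(x0, dtype=float)
    v = (
        rng.normal(0.0, np.sqrt(kT * FORCE_TO_ACC / m), size=x.shape)
        if kT > 0
        else np.zeros_like(x)
    )
    _, f = system.energy_and_forces(x, params)
    if bias_fn is not None:
        f = f + bias_fn(x)[1]
    for step in range(config.n_steps):
        v = v + 0.5 * dt * FORCE_TO_ACC * f / m
        x = x + 0.5 * dt * v
        if kT > 0:
            v = c1 * v + sigma_v * rng.normal(size=x.shape)
        else:
            v = c1 * v
        x = x + 0.5 * dt * v
        try:
            _, f = system.energy_and_forces(x, params)
        except StepRejectionError as exc:
            raise StepRejectionError(f"step {step + 1}: {exc}") from exc
        if bias_fn is not None:
            f = f + bias_fn(x)[1]
        v = v + 0.5 * dt * FORCE_TO_ACC * f / m
        if (step + 1) % config.stride == 0:
            observe(step + 1, x)
    return x


def _restraint_bias(system, restraint: UmbrellaRestraint):
    if len(system.ligands) > 0:
        offsets = system._offsets[restraint.ligand_index]
        topo = system.ligands[restraint.ligand_index]
        idx = 0 if restraint.atom_name is None else topo.atom_index(restraint.atom_name)
        body = 1 + restraint.ligand_index

        def bias(x):
            dr = (x[body] + offsets[idx]) - x[0]
            d = float(np.linalg.norm(dr))
            u = restraint.energy(d)
            g = restraint.dUdd(d) / d
            forces = np.zeros_like(x)
            forces[body] = -g * dr
            forces[0] = g * dr
            return u, forces

        def measure(x):
            return float(np.linalg.norm((x[body] + offsets[idx]) - x[0]))
    else:

        def bias(x):
            d = float(np.linalg.norm(x[0]))
            u = restraint.energy(d)
            forces = np.zeros_like(x)
            if d > 0:
                forces[0] = -restraint.dUdd(d) / d * x[0]
            return u, forces

        def measure(x):
            return float(np.linalg.norm(x[0]))

    return bias, measure


def run_dynamics(config: SimulationConfig, system, x0=None, bias_fn=None, params=None):
    """Propagate and return the strided coordinate trajectory
    (shape ``(n_frames, n_bodies, 3)``)."""
    if x0 is None:
        x0 = system.initial_coords()
    frames = []
    _baoab(config, system, x0, bias_fn, lambda s, x: frames.append(x.copy()), params)
    return np.array(frames)


def run_window(
    config: SimulationConfig,
    system,
    restraint: UmbrellaRestraint,
    x0=None,
) -> DistanceSeries:
    """Sample one umbrella window; returns the restrained-distance series
    after discarding the leading ``config.equilibration_fraction``."""
    bias, measure = _restraint_bias(system, restraint)
    if x0 is None:
        if len(system.ligands) == 0:
            x0 = system.initial_coords() + np.array([restraint.center, 0.0, 0.0])
        else:
            x0 = system.initial_coords(
                ion_ligand_distance=restraint.center, atom_name=restraint.atom_name
            )
    values = []
    _baoab(config, system, x0, bias, lambda s, x: values.append(measure(x)))
    values = np.asarray(values)
    n_skip = int(np.floor(config.equilibration_fraction * len(values)))
    return DistanceSeries(
        values=values[n_skip:],
        sampling_interval=config.timestep * config.stride,
        restraint=restraint,
    )


def steer(
    config: SimulationConfig,
    system,
    start: float,
    end: float,
    n_snapshots: int = 120,
    spring_constant: float = 200.0,
    ligand_index: int = 0,
    atom_name: str | None = None,
) -> list[np.ndarray]:
    """Constant-velocity steered run: a stiff harmonic restraint whose center
    moves linearly from ``start`` to ``end`` Å; returns ``n_snapshots`` body
    coordinate arrays at evenly spaced restraint centers (incl. endpoints).

    Use :meth:`ToySystem.to_configuration` to expand snapshots to Cartesian
    configurations, or feed them to :func:`run_window` as initial states.
    """
    if start == end:
        raise ValueError("start and end distances must differ")
    if n_snapshots < 2:
        raise ValueError("n_snapshots must be >= 2")
    base = UmbrellaRestraint(
        center=start, spring_constant=spring_constant,
        ligand_index=ligand_index, atom_name=atom_name,
    )
    n_steps = config.n_steps
    snap_steps = np.unique(np.round(np.linspace(0, n_steps, n_snapshots)).astype(int))
    snap_steps = snap_steps[snap_steps > 0]

    def moving_bias_factory():
        step_counter = {"i": 0}

        def bias(x):
            frac = min(step_counter["i"] / n_steps, 1.0)
            c = start + frac * (end - start)
            r = replace(base, center=max(c, 1e-6))
            b, _ = _restraint_bias(system, r)
            step_counter["i"] += 1
            return b(x)

        return bias

    if len(system.ligands) == 0:
        x0 = system.initial_coords() + np.array([start, 0.0, 0.0])
    else:
        x0 = system.initial_coords(ion_ligand_distance=start, atom_name=atom_name)
    snaps: list[np.ndarray] = [x0.copy()]
    cfg = replace(config, stride=1)
    want = set(snap_steps.tolist())

    def observe(step, x):
        if step in want:
            snaps.append(x.copy())

    _baoab(cfg, system, x0, moving_bias_factory(), observe)
    if len(snaps) > n_snapshots:
        snaps = snaps[:n_snapshots]
    return snaps


# ---------------------------------------------------------------------------
# Thermodynamic integration
# ---------------------------------------------------------------------------

@dataclass
class AlchemicalPath:
    """Linear-mixing path between two parameter sets (ion specs or, for
    harmonic test systems, spring constants): U(λ) = (1-λ)U_A + λU_B."""

    state_a: object
    state_b: object
    lambdas: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 12))

    def __post_init__(self) -> None:
        lam = tuple(float(v) for v in self.lambdas)
        if len(lam) < 2:
            raise ValueError("at least 2 lambda points required")
        if list(lam) != sorted(lam):
            raise ValueError("lambda schedule must be sorted")
        if abs(lam[0]) > 1e-12 or abs(lam[-1] - 1.0) > 1e-12:
            raise ValueError("lambda schedule must span [0, 1]")
        object.__setattr__(self, "lambdas", lam)


@dataclass
class TIResult:
    """ΔG (kcal/mol) with standard error and the per-λ ⟨dU/dλ⟩ table."""

    delta_g: float
    se: float
    lambdas: np.ndarray
    dudl_mean: np.ndarray
    dudl_se: np.ndarray


def _block_se(samples: np.ndarray, n_blocks: int = 10) -> float:
    n = len(samples)
    if n < 2 * n_blocks:
        n_blocks = max(2, n // 2)
    blocks = np.array_split(samples, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def ti_free_energy(
    config: SimulationConfig,
    system,
    path: AlchemicalPath,
    quadrature: str = "trapezoid",
    bias_fn=None,
    x0=None,
) -> TIResult:
    """Alchemical ΔG(A→B) by thermodynamic integration.

    Each λ window is an independent BAOAB run (seed = ``config.seed`` + index)
    under the mixed potential; dU/dλ = U_B − U_A is recorded every stride and
    the profile is integrated by trapezoidal quadrature.  Identical endpoint
    parameters give exactly zero.  ``bias_fn`` adds a λ-independent restraint
    (e.g. a containment wall for bound-complex mutations).
    """
    if quadrature != "trapezoid":
        raise ValueError(f"unsupported quadrature {quadrature!r}")
    lambdas = np.asarray(path.lambdas)

    class _Mixed:
        def __init__(self, lam):
            self.lam = lam
            self.masses = system.masses
            self.ligands = system.ligands

        @property
        def n_bodies(self):
            return system.n_bodies

        def initial_coords(self, **kw):
            return system.initial_coords(**kw)

        def energy_and_forces(self, x, params=None):
            ua, fa = system.energy_and_forces(x, path.state_a)
            ub, fb = system.energy_and_forces(x, path.state_b)
            return (1 - self.lam) * ua + self.lam * ub, (1 - self.lam) * fa + self.lam * fb

    dudl_mean = np.empty(len(lambdas))
    dudl_se = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        mixed = _Mixed(lam)
        cfg = replace(config, seed=config.seed + i)
        start = system.initial_coords() if x0 is None else np.array(x0, dtype=float)
        samples = []

        def observe(step, x):
            ua, _ = system.energy_and_forces(x, path.state_a)
            ub, _ = system.energy_and_forces(x, path.state_b)
            samples.append(ub - ua)

        _baoab(cfg, mixed, start, bias_fn, observe)
        arr = np.asarray(samples)
        n_skip = int(np.floor(config.equilibration_fraction * len(arr)))
        arr = arr[n_skip:]
        dudl_mean[i] = arr.mean()
        dudl_se[i] = _block_se(arr)

    dg = float(np.trapezoid(dudl_mean, lambdas))
    # trapezoid weights for error propagation
    w = np.zeros_like(lambdas)
    w[:-1] += np.diff(lambdas) / 2.0
    w[1:] += np.diff(lambdas) / 2.0
    se = float(np.sqrt(np.sum((w * dudl_se) ** 2)))
    return TIResult(delta_g=dg, se=se, lambdas=lambdas, dudl_mean=dudl_mean, dudl_se=dudl_se)


# ---------------------------------------------------------------------------
# Deterministic surrogate binding-free-energy oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateOracle:
    """Deterministic, strictly decreasing map α₀ (Å³) → ΔG_bind (kcal/mol).

    Closed form: ΔG(α) = a + b·α − c·s·log(1 + exp((α − x0)/s)), an affine
    term plus a softplus that steepens binding beyond x0.  Strict
    monotonicity (decreasing) requires b < 0 and c ≥ 0, checked at
    construction; c = 0 recovers the affine family.
    """

    a: float = 0.0
    b: float = -4.0
    c: float = 0.0
    x0: float = 0.5
    s: float = 0.25

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("softplus width s must be positive")
        if self.b >= 0 or self.c < 0:
            raise ValueError(
                "oracle must be strictly decreasing: require b < 0 and c >= 0"
            )

    def __call__(self, alpha0: float) -> float:
        z = (alpha0 - self.x0) / self.s
        softplus = np.logaddexp(0.0, z)  # log(1 + e^z), overflow-safe
        return float(self.a + self.b * alpha0 - self.c * self.s * softplus)


def surrogate_binding_dg(alpha0: float, oracle: SurrogateOracle) -> float:
    """Evaluate the surrogate oracle; a cheap, deterministic stand-in for a
    full umbrella-sampling PMF evaluation when exercising the
    parametrization loop."""
    if not isinstance(oracle, SurrogateOracle):
        raise TypeError("oracle must be a SurrogateOracle")
    return oracle(alpha0)
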