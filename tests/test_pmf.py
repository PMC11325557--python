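"""WHAM assembly, binding free energy extraction, stationary points."""

import numpy as np
import pytest

from metim.fixtures import (
    SyntheticPmfSpec,
    double_well,
    flat_profile,
    generate_windows,
    well_plus_shoulder,
)
from metim.pmf import (
    AnalysisError,
    EstimationError,
    PMFProfile,
    binding_free_energy,
    bootstrap_profile,
    remove_radial_entropy,
    stationary_points,
    wham,
)
from metim.toysim import KB, DistanceSeries, UmbrellaRestraint

KT = KB * 300.0
V0 = 1e27 / 6.02214076e23  # Å³ per molecule at 1 M


def _aligned_rmsd(profile, analytic):
    ref = analytic(profile.grid)
    d = profile.free_energy - (ref - ref.min())
    return float(np.sqrt(np.mean((d - d.mean()) ** 2)))


class TestWham:
    def test_recovers_analytic_double_well(self, double_well_windows, analytic_double_well):
        profile, solution = wham(double_well_windows, n_bins=200)
        assert solution.converged
        assert solution.residual <= 1e-7
        assert _aligned_rmsd(profile, analytic_double_well) <= 0.1

    def test_single_flat_window_gives_flat_profile(self):
        """An (effectively) unbiased window over a flat landscape unbiases
        to a profile that is flat within sampling noise."""
        spec = SyntheticPmfSpec(
            profile=flat_profile(2.0, 5.0), n_windows=1, spring_constant=1e-6,
            samples_per_window=20000, seed=3, centers=(3.5,),
        )
        windows = generate_windows(spec)
        profile, se = bootstrap_profile(windows, n_boot=30, seed=3, n_bins=25)
        dev = np.abs(profile.free_energy - profile.free_energy.mean())
        assert np.max(dev) < 4 * np.max(se)

    def test_window_order_invariance(self, double_well_windows):
        p1, _ = wham(double_well_windows, n_bins=100)
        p2, _ = wham(double_well_windows[::-1], n_bins=100)
        assert np.allclose(p1.grid, p2.grid)
        assert np.allclose(p1.free_energy, p2.free_energy, atol=1e-6)

    def test_equals_boltzmann_inversion_for_single_unbiased_window(self):
        spec = SyntheticPmfSpec(
            profile=double_well(), n_windows=1, spring_constant=1e-6,
            samples_per_window=20000, seed=7, centers=(4.0,),
        )
        windows = generate_windows(spec)
        profile, _ = wham(windows, n_bins=40, min_counts=1)
        edges = np.linspace(windows[0].values.min(), windows[0].values.max(), 41)
        counts, _ = np.histogram(windows[0].values, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mask = counts > 0
        direct = -KT * np.log(counts[mask].astype(float))
        direct -= direct.min()
        recovered = np.interp(centers[mask], profile.grid, profile.free_energy)
        assert np.allclose(recovered, direct, atol=1e-6)

    def test_more_samples_tighten_offsets(self, analytic_double_well):
        f = []
        for n in (2000, 8000):
            spec = SyntheticPmfSpec(
                profile=analytic_double_well, n_windows=12,
                samples_per_window=n, seed=5,
            )
            _, sol = wham(generate_windows(spec), n_bins=100)
            f.append(sol.offsets)
        assert np.allclose(f[0], f[1], atol=0.15)

    def test_disjoint_windows_rejected(self):
        r1 = UmbrellaRestraint(2.0, 100.0)
        r2 = UmbrellaRestraint(6.0, 100.0)
        w1 = DistanceSeries(np.random.default_rng(0).normal(2.0, 0.05, 500), 1.0, r1)
        w2 = DistanceSeries(np.random.default_rng(1).normal(6.0, 0.05, 500), 1.0, r2)
        with pytest.raises(EstimationError, match="overlap"):
            wham([w1, w2])


class TestBindingFreeEnergy:
    def _flat(self, lo=1.0, hi=8.0, n=700):
        h = (hi - lo) / n
        grid = np.linspace(lo + h / 2, hi - h / 2, n)
        return PMFProfile(grid=grid, free_energy=np.zeros(n), bin_width=h)

    def test_flat_profile_reduces_to_volume_term(self):
        profile = self._flat()
        rc = 4.0
        dg = binding_free_energy(profile, bound_cutoff=rc)
        lo_edge = profile.grid[0] - profile.bin_width / 2
        v_bound = 4 * np.pi / 3 * (rc**3 - lo_edge**3)
        assert dg == pytest.approx(-KT * np.log(v_bound / V0), abs=1e-9)

    def test_square_well_closed_form(self):
        lo, hi, n = 1.0, 9.0, 800
        h = (hi - lo) / n
        grid = np.linspace(lo + h / 2, hi - h / 2, n)
        depth, r1, r2, rc = 4.0, 2.0, 3.0, 4.0
        g = np.where((grid > r1) & (grid < r2), -depth, 0.0)
        profile = PMFProfile(grid=grid, free_energy=g, bin_width=h)
        dg = binding_free_energy(profile, bound_cutoff=rc)
        sphere = lambda a, b: 4 * np.pi / 3 * (b**3 - a**3)
        integral = (
            sphere(lo, r1) + np.exp(depth / KT) * sphere(r1, r2) + sphere(r2, rc)
        )
        assert dg == pytest.approx(-KT * np.log(integral / V0), abs=1e-6)

    def test_deepening_well_lowers_dg_linearly(self):
        lo, hi, n = 1.0, 9.0, 800
        h = (hi - lo) / n
        grid = np.linspace(lo + h / 2, hi - h / 2, n)
        well = (grid > 2.0) & (grid < 3.0)
        dgs = []
        for depth in (8.0, 9.0):
            profile = PMFProfile(grid=grid, free_energy=np.where(well, -depth, 0.0),
                                 bin_width=h)
            dgs.append(binding_free_energy(profile, bound_cutoff=4.0))
        assert dgs[1] - dgs[0] == pytest.approx(-1.0, abs=0.01)

    def test_invariant_to_constant_shift(self):
        lo, hi, n = 1.0, 9.0, 400
        h = (hi - lo) / n
        grid = np.linspace(lo + h / 2, hi - h / 2, n)
        g = -3.0 * np.exp(-((grid - 2.2) ** 2) / 0.1)
        p1 = PMFProfile(grid=grid, free_energy=g, bin_width=h)
        p2 = PMFProfile(grid=grid, free_energy=g + 7.5, bin_width=h)
        assert binding_free_energy(p1, 4.0) == pytest.approx(
            binding_free_energy(p2, 4.0), abs=1e-10
        )

    def test_no_plateau_detected(self):
        grid = np.linspace(1.0, 8.0, 200)
        profile = PMFProfile(grid=grid, free_energy=-1.0 * grid,
                             bin_width=grid[1] - grid[0])
        with pytest.raises(AnalysisError, match="plateau"):
            binding_free_energy(profile, 4.0)

    def test_well_depth_estimator(self):
        profile = self._flat()
        profile.free_energy[100] = -5.0
        dg = binding_free_energy(profile, 4.0, method="well_depth")
        assert dg == pytest.approx(-5.0, abs=0.05)

    def test_radial_entropy_removal_flattens_jacobian_tail(self):
        grid = np.linspace(2.0, 8.0, 300)
        g = -2 * KT * np.log(grid)  # pure 3-D shell entropy
        profile = PMFProfile(grid=grid, free_energy=g - g.min(),
                             bin_width=grid[1] - grid[0])
        corrected = remove_radial_entropy(profile)
        assert np.allclose(corrected.free_energy, 0.0, atol=1e-10)


class TestStationaryPoints:
    def _profile_from(self, analytic, lo, hi, n=300):
        grid = np.linspace(lo, hi, n)
        g = analytic(grid)
        return PMFProfile(grid=grid, free_energy=g - g.min(),
                          bin_width=grid[1] - grid[0])

    def test_monotone_profile_has_none(self):
        grid = np.linspace(1.0, 5.0, 100)
        profile = PMFProfile(grid=grid, free_energy=np.sort(np.exp(-grid)),
                             bin_width=grid[1] - grid[0])
        assert stationary_points(profile) == []

    def test_double_well_minima_and_barrier(self, analytic_double_well):
        p = self._profile_from(analytic_double_well, 1.6, 6.4)
        pts = stationary_points(p)
        minima = [q for q in pts if q.kind == "min"]
        maxima = [q for q in pts if q.kind == "max"]
        assert len(minima) == 2 and len(maxima) == 1
        assert minima[0].position == pytest.approx(2.1, abs=p.bin_width)
        assert minima[1].position == pytest.approx(4.0, abs=p.bin_width)
        assert maxima[0].barrier is not None and maxima[0].barrier > 0

    def test_shoulder_intermediate_detected(self):
        """The shallow outer minimum (the cation-π-intermediate analogue)
        is reported alongside the bound well."""
        p = self._profile_from(well_plus_shoulder(), 1.6, 6.9)
        minima = [q for q in stationary_points(p) if q.kind == "min"]
        assert any(abs(q.position - 4.5) < 0.1 for q in minima)

    def test_too_few_bins_rejected(self):
        grid = np.linspace(1.0, 2.0, 4)
        p = PMFProfile(grid=grid, free_energy=np.zeros(4), bin_width=0.33)
        with pytest.raises(ValueError):
            stationary_points(p)
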