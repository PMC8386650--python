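"""Metadynamics engine: deposition rules, FES reconstruction, well detection."""

import numpy as np
import pytest
from scipy import stats

from neurobias import (
    FreeEnergyProfile,
    HillsRecord,
    MetadParams,
    ToyPotential,
    convergence_series,
    find_wells_and_barriers,
    read_hills,
    reconstruct_fes,
    run_langevin_metadynamics,
    write_hills,
)
from neurobias.metadynamics import KB_KCAL_MOL_K


class TestDepositionRules:
    def test_first_hill_height_is_w0(self, double_well_run):
        _, hills = double_well_run
        first = hills.height[np.argmin(hills.time)]
        assert first == pytest.approx(0.1)

    def test_heights_bounded_and_decay(self, double_well_run):
        _, hills = double_well_run
        assert np.all(hills.height > 0)
        assert np.all(hills.height <= 0.1 + 1e-12)
        # well-tempered decay: late hills in revisited regions are far below w0
        assert hills.height.min() < 0.05

    def test_reproducible_with_fixed_seed(self):
        pot = ToyPotential.harmonic(k=2.0)
        kwargs = dict(n_steps=5000, seed=77, grid_range=(-4, 4))
        t1, h1 = run_langevin_metadynamics(pot, MetadParams(), **kwargs)
        t2, h2 = run_langevin_metadynamics(pot, MetadParams(), **kwargs)
        assert np.array_equal(t1, t2)
        assert np.array_equal(h1.center, h2.center)
        assert np.array_equal(h1.height, h2.height)

    def test_bias_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            MetadParams(bias_factor=1.0)

    def test_unstable_timestep_rejected(self):
        pot = ToyPotential.harmonic(k=500.0, timestep=0.02)
        with pytest.raises(ValueError, match="unstable"):
            run_langevin_metadynamics(pot, MetadParams(), n_steps=100)


class TestPlainLangevin:
    def test_boltzmann_distribution_in_harmonic_well(self):
        """With w0 = 0 the sampler reproduces the analytic Gaussian marginal."""
        k = 2.0
        pot = ToyPotential.harmonic(k=k)
        params = MetadParams(hill_height=0.0, n_walkers=50, temperature=300.0)
        traj, hills = run_langevin_metadynamics(
            pot, params, n_steps=20_000, seed=21, traj_stride=250, x0=0.0
        )
        assert len(hills) == 0
        samples = traj[20:].ravel()  # discard burn-in, thinned at ~2 correlation times
        sd = np.sqrt(KB_KCAL_MOL_K * 300.0 / k)
        _, p = stats.kstest(samples, "norm", args=(0.0, sd))
        assert p > 1e-3

    def test_wall_confines_flat_potential(self):
        pot = ToyPotential.flat()
        params = MetadParams(hill_height=0.0)
        traj, _ = run_langevin_metadynamics(
            pot, params, n_steps=300_000, seed=31, x0=0.0, traj_stride=10
        )
        assert np.mean(np.abs(traj) > 12.5) < 0.01


class TestReconstructFes:
    def test_single_hill_is_inverted_gaussian(self):
        gamma = 10.0
        hills = HillsRecord(
            time=[4.0], center=[0.5], sigma=[0.1], height=[0.08], walker=[0], bias_factor=gamma
        )
        grid = np.arange(0.0, 1.0, 0.01)
        fes = reconstruct_fes(hills, grid)
        depth = gamma / (gamma - 1.0) * 0.08
        assert fes.free_energy.min() == pytest.approx(0.0)
        assert fes.grid[np.argmin(fes.free_energy)] == pytest.approx(0.5)
        assert fes.free_energy.max() == pytest.approx(depth, rel=1e-3)

    def test_permutation_invariance(self, double_well_run, cv_grid):
        """Reordering deposition history leaves the reconstruction unchanged."""
        _, hills = double_well_run
        a = reconstruct_fes(hills, cv_grid).free_energy
        b = reconstruct_fes(hills.sorted_by_time(), cv_grid).free_energy
        assert np.allclose(a, b, atol=1e-10)

    def test_empty_hills_rejected(self):
        empty = HillsRecord(
            time=[], center=[], sigma=[], height=[], walker=[], bias_factor=10.0
        )
        with pytest.raises(ValueError):
            reconstruct_fes(empty, np.linspace(-1, 1, 11))


class TestOracleEquivalence:
    """For 1D Langevin the free energy along the CV equals U - min U."""

    def _rms(self, pot, hills, grid, accessible_kcal=2.0):
        fes = reconstruct_fes(hills, grid)
        u = pot.energy(grid)
        u = u - u.min()
        acc = u <= accessible_kcal
        return float(np.sqrt(np.mean((fes.free_energy[acc] - u[acc]) ** 2)))

    def test_double_well_fes_matches_potential(self, double_well_potential, double_well_run, cv_grid):
        _, hills = double_well_run
        assert self._rms(double_well_potential, hills, cv_grid) <= 0.3

    def test_harmonic_fes_matches_potential(self, harmonic_run, cv_grid):
        pot, _, hills = harmonic_run
        assert self._rms(pot, hills, cv_grid) <= 0.3

    def test_tilted_double_well_fes_matches_potential(self, tilted_double_well_run, cv_grid):
        pot, _, hills = tilted_double_well_run
        assert self._rms(pot, hills, cv_grid) <= 0.3

    def test_walker_count_invariance(self, double_well_potential, cv_grid):
        """1 vs 6 walkers agree on the converged FES at equal total hills."""
        _, h6 = run_langevin_metadynamics(
            double_well_potential, MetadParams(n_walkers=6), n_steps=400_000, seed=11,
            grid_range=(-4, 4),
        )
        _, h1 = run_langevin_metadynamics(
            double_well_potential, MetadParams(n_walkers=1), n_steps=2_400_000, seed=12,
            grid_range=(-4, 4),
        )
        assert len(h6) == len(h1)
        f6 = reconstruct_fes(h6, cv_grid).free_energy
        f1 = reconstruct_fes(h1, cv_grid).free_energy
        u = double_well_potential.energy(cv_grid)
        acc = (u - u.min()) <= 2.0
        rms = np.sqrt(np.mean((f6[acc] - f1[acc]) ** 2))
        assert rms <= 0.3


class TestConvergenceSeries:
    def test_block_larger_than_total_gives_single_full_profile(self, double_well_run, cv_grid):
        _, hills = double_well_run
        series = convergence_series(hills, block=len(hills) + 10, grid=cv_grid)
        assert len(series) == 1
        full = reconstruct_fes(hills, cv_grid)
        assert np.allclose(series[0].free_energy, full.free_energy, atol=1e-8)

    def test_final_element_equals_full_reconstruction(self, double_well_run, cv_grid):
        _, hills = double_well_run
        series = convergence_series(hills, block=2000, grid=cv_grid)
        full = reconstruct_fes(hills, cv_grid)
        assert np.allclose(series[-1].free_energy, full.free_energy, atol=1e-8)

    def test_profile_count(self, double_well_run, cv_grid):
        _, hills = double_well_run
        n = len(hills)
        block = 2000
        series = convergence_series(hills, block=block, grid=cv_grid)
        expected = n // block + (1 if n % block else 0)
        assert len(series) == expected

    def test_successive_profiles_stabilize(self, double_well_run, cv_grid):
        _, hills = double_well_run
        series = convergence_series(hills, block=2000, grid=cv_grid)
        diffs = [
            float(np.sqrt(np.mean((series[k].free_energy - series[k - 1].free_energy) ** 2)))
            for k in range(1, len(series))
        ]
        assert diffs[-1] < diffs[0]
        assert diffs[-1] < 0.2


class TestWellsAndBarriers:
    def test_symmetric_double_well_two_wells_equal_barriers(self):
        grid = np.arange(-2, 2.001, 0.01)
        u = 1.3 * (grid**2 - 1.0) ** 2
        fes = FreeEnergyProfile(grid=grid, free_energy=u - u.min())
        wells, barriers = find_wells_and_barriers(fes)
        assert len(wells) == 2
        locs = sorted(w[0] for w in wells)
        assert locs[0] == pytest.approx(-1.0, abs=0.02)
        assert locs[1] == pytest.approx(1.0, abs=0.02)
        b = barriers.to_numpy()
        assert b[0, 1] == pytest.approx(b[1, 0], abs=1e-9)
        assert b[0, 1] == pytest.approx(1.3, abs=0.02)

    def test_monotone_profile_single_well(self):
        grid = np.linspace(0, 5, 200)
        fes = FreeEnergyProfile(grid=grid, free_energy=grid.copy())
        wells, _ = find_wells_and_barriers(fes)
        assert len(wells) == 1
        assert wells[0][0] == pytest.approx(0.0)

    def test_tilted_well_barrier_matches_saddle(self):
        grid = np.arange(-2, 2.001, 0.005)
        u = 1.3 * (grid**2 - 1.0) ** 2 + 0.3 * grid
        fes = FreeEnergyProfile(grid=grid, free_energy=u - u.min())
        wells, barriers = find_wells_and_barriers(fes)
        assert len(wells) == 2
        # oracle: exhaustive saddle between the two minima on the same grid
        idx = [int(np.argmin(np.abs(grid - w[0]))) for w in wells]
        lo, hi = sorted(idx)
        saddle = np.max((u - u.min())[lo : hi + 1])
        expect = saddle - (u - u.min())[lo]
        assert barriers.to_numpy()[0, 1] == pytest.approx(expect, abs=0.01)

    def test_recovered_barrier_from_simulation(self, double_well_run, cv_grid):
        _, hills = double_well_run
        fes = reconstruct_fes(hills, cv_grid)
        wells, barriers = find_wells_and_barriers(fes)
        assert len(wells) == 2
        assert barriers.to_numpy()[0, 1] == pytest.approx(1.3, abs=0.3)


def test_hills_file_roundtrip(tmp_path, double_well_run):
    _, hills = double_well_run
    path = tmp_path / "HILLS"
    write_hills(path, hills)
    back = read_hills(path)
    assert back.bias_factor == hills.bias_factor
    assert np.allclose(back.center, hills.center, atol=1e-8)
    assert np.allclose(back.height, hills.height, rtol=1e-8)
    assert np.array_equal(back.walker, hills.walker)
    assert back.cv_label == hills.cv_label
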