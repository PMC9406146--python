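"""Multi-temperature reweighting against closed forms and an independent
convex-optimization implementation."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from pepagg.constants import KB_KCAL
from pepagg.ensemble import EnsembleSet, Frame, TemperatureLadder
from pepagg.wham import (ensemble_average, heat_capacity, solve_wham,
                         temperature_grid)
from ._reference import (mbar_free_energies, two_level_ensemble,
                         two_level_mean_energy)


def _flat_frames(energies, temp_indices, n_temps=2):
    coords = np.zeros((1, 2, 3))
    ladder = TemperatureLadder(tuple(280.0 + 20.0 * k for k in range(n_temps)))
    frames = [Frame(coords=coords, energy=float(e), temp_index=int(k),
                    traj_id=0, step=i)
              for i, (e, k) in enumerate(zip(energies, temp_indices))]
    return EnsembleSet(frames=frames, ladder=ladder)


class TestSolveWham:
    def test_single_temperature_uniform_weights(self, caplog):
        ens = _flat_frames([0.0, 1.0, 2.0, 3.0], [0, 0, 0, 0])
        with caplog.at_level("WARNING"):
            table = solve_wham(ens)
        w = table.weights(280.0)
        np.testing.assert_allclose(w, 0.25)
        assert "uniform" in caplog.text

    def test_two_level_closed_form(self):
        ens, eps = two_level_ensemble()
        table = solve_wham(ens, tol=1e-14)
        # exact free-energy difference: log Z ratio of the two-level system
        beta = 1.0 / (KB_KCAL * np.asarray(ens.ladder.temperatures))
        exact = -(np.log(1 + np.exp(-beta * eps))
                  - np.log(1 + np.exp(-beta[0] * eps)))
        np.testing.assert_allclose(table.free_energies, exact, atol=1e-6)
        for T in (250.0, 290.0, 340.0):
            mean_e = table.weights(T) @ table.energies
            assert mean_e == pytest.approx(two_level_mean_energy(eps, T),
                                           abs=1e-6)

    def test_matches_independent_optimizer(self, sampled_ensemble):
        table = solve_wham(sampled_ensemble)
        ref = mbar_free_energies(sampled_ensemble.energies,
                                 sampled_ensemble.temp_indices,
                                 np.asarray(sampled_ensemble.ladder.temperatures))
        np.testing.assert_allclose(table.free_energies, ref, atol=1e-6)

    def test_duplicating_snapshots_changes_nothing(self):
        ens, eps = two_level_ensemble(n_per_temp=40)
        doubled = EnsembleSet(frames=ens.frames + ens.frames,
                              ladder=ens.ladder)
        f1 = solve_wham(ens).free_energies
        f2 = solve_wham(doubled).free_energies
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_energy_gauge_invariance(self):
        ens, _ = two_level_ensemble(n_per_temp=40)
        shifted = EnsembleSet(
            frames=[Frame(coords=f.coords, energy=f.energy + 13.7,
                          temp_index=f.temp_index, traj_id=f.traj_id,
                          step=f.step) for f in ens.frames],
            ladder=ens.ladder)
        w1 = solve_wham(ens).weights(300.0)
        w2 = solve_wham(shifted).weights(300.0)
        np.testing.assert_allclose(w1, w2, atol=1e-10)

    def test_normalization_everywhere(self, sampled_ensemble):
        table = solve_wham(sampled_ensemble)
        for T in temperature_grid(260.0, 370.0, 5.0):
            assert abs(table.weights(T).sum() - 1.0) < 1e-12

    def test_reweighting_consistency_with_direct_means(self, sampled_ensemble,
                                                       oracle):
        """At every rung with >= 500 own samples the reweighted f8 agrees
        with the direct same-temperature block mean within 3 SE."""
        from pepagg.oligomers import frame_oligomer_fractions

        table = solve_wham(sampled_ensemble)
        f8 = frame_oligomer_fractions(sampled_ensemble)[:, -1]
        ti = sampled_ensemble.temp_indices
        for k, T in enumerate(sampled_ensemble.ladder.temperatures):
            sel = np.nonzero(ti == k)[0]
            if len(sel) < 500:
                continue
            direct = f8[sel]
            blocks = np.array_split(direct, 20)
            bm = np.array([b.mean() for b in blocks])
            se = bm.std(ddof=1) / np.sqrt(len(bm))
            wham_mean = table.weights(T) @ f8
            assert abs(wham_mean - direct.mean()) < max(3 * se, 0.02)


class TestProfiles:
    def test_constant_observable_is_flat(self, sampled_ensemble):
        table = solve_wham(sampled_ensemble)
        grid = temperature_grid(260.0, 370.0, 10.0)
        prof = ensemble_average(table, np.full(len(sampled_ensemble), 0.7),
                                grid)
        np.testing.assert_allclose(prof.values, 0.7, atol=1e-12)

    def test_two_level_occupancy_profile(self):
        ens, eps = two_level_ensemble()
        table = solve_wham(ens, tol=1e-14)
        upper = (ens.energies > 0).astype(float)
        grid = temperature_grid(240.0, 360.0, 5.0)
        prof = ensemble_average(table, upper, grid)
        closed = 1.0 / (1.0 + np.exp(eps / (KB_KCAL * grid)))
        np.testing.assert_allclose(prof.values, closed, atol=1e-6)

    def test_length_mismatch_rejected(self, sampled_ensemble):
        table = solve_wham(sampled_ensemble)
        with pytest.raises(ValueError):
            ensemble_average(table, np.ones(3), temperature_grid())


class TestHeatCapacity:
    def test_schottky_peak_location(self):
        ens, eps = two_level_ensemble()
        table = solve_wham(ens, tol=1e-14)
        grid = temperature_grid(100.0, 500.0, 1.0)
        cv = heat_capacity(table, grid)
        # analytic two-level C_v maximum: maximize x^2 e^x/(1+e^x)^2
        res = minimize_scalar(
            lambda x: -x * x * np.exp(x) / (1 + np.exp(x)) ** 2,
            bounds=(0.1, 10.0), method="bounded")
        t_peak_exact = eps / (KB_KCAL * res.x)
        t_peak = grid[np.argmax(cv.values)]
        assert t_peak == pytest.approx(t_peak_exact, abs=1.0)

    def test_zero_variance_gives_zero(self):
        ens = _flat_frames([2.0] * 10, [0] * 5 + [1] * 5)
        table = solve_wham(ens)
        cv = heat_capacity(table, temperature_grid(260.0, 370.0, 10.0))
        np.testing.assert_allclose(cv.values, 0.0, atol=1e-12)

    def test_nonnegative_on_random_ensembles(self, rng):
        energies = rng.normal(scale=3.0, size=60)
        ens = _flat_frames(energies, rng.integers(0, 2, size=60))
        cv = heat_capacity(solve_wham(ens), temperature_grid(260.0, 370.0, 5.0))
        assert np.all(cv.values >= 0.0)
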