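"""Partition-model oracle, Markov-chain sampler, and rendered geometry."""

import collections
import math

import numpy as np
import pytest

from pepagg.constants import KB_KCAL
from pepagg.ensemble import BoxSpec
from pepagg.oligomers import identify_oligomers
from pepagg.synthetic import (ToyModelSpec, build_reference_geometries,
                              enumerate_partition_model, render_partition,
                              run_partition_chain, sample_ensemble,
                              sheet_coords)


class TestPartitionOracle:
    def test_two_chain_closed_form(self):
        spec = ToyModelSpec(n_chains=2, epsilon=0.6, nu=50.0)
        oracle = enumerate_partition_model(spec)
        for T in (200.0, 260.0, 300.0, 370.0, 800.0):
            be = spec.epsilon / (KB_KCAL * T)
            closed = math.exp(be) / (math.exp(be) + spec.nu)
            assert oracle.f_full(T) == pytest.approx(closed, rel=1e-12)

    def test_ground_state_dominates_at_low_temperature(self):
        oracle = enumerate_partition_model(ToyModelSpec())
        assert oracle.f_full(20.0) > 0.999

    def test_athermal_model_is_temperature_independent(self):
        spec = ToyModelSpec(n_chains=3, epsilon=0.0, nu=2.0)
        oracle = enumerate_partition_model(spec)
        # hand enumeration for n=3, nu=2: Z = 2 + 3*4 + 8 = 22
        np.testing.assert_allclose(oracle.fractions(100.0),
                                   [12 / 22, 8 / 22, 2 / 22])
        np.testing.assert_allclose(oracle.fractions(100.0),
                                   oracle.fractions(350.0))

    def test_fractions_normalized_and_monotone(self):
        oracle = enumerate_partition_model(ToyModelSpec())
        f_prev = None
        for T in np.linspace(200.0, 500.0, 16):
            f = oracle.fractions(T)
            assert f.sum() == pytest.approx(1.0)
            if f_prev is not None:
                assert f[-1] <= f_prev + 1e-12
            f_prev = f[-1]

    def test_midpoint_is_half_crossing(self):
        oracle = enumerate_partition_model(ToyModelSpec())
        tm = oracle.midpoint()
        assert oracle.f_full(tm) == pytest.approx(0.5, abs=1e-6)

    def test_enumeration_size(self):
        assert len(enumerate_partition_model(
            ToyModelSpec()).partitions) == 4140  # Bell(8)


class TestMarkovChain:
    def test_stationary_distribution_n3(self):
        """Detailed balance: empirical distribution over the 5 partitions
        of 3 chains matches the exact weights within 3 sigma."""
        spec = ToyModelSpec(n_chains=3, epsilon=0.6, nu=50.0)
        oracle = enumerate_partition_model(spec)
        T = 300.0
        n_moves = 100_000
        samples = run_partition_chain(spec, T, n_moves,
                                      np.random.default_rng(7))
        counts = collections.Counter(samples)
        p = oracle.stationary_distribution(T)
        for i, part in enumerate(oracle.partitions):
            obs = counts.get(part, 0) / n_moves
            # ~10-move autocorrelation allowance on the binomial SE
            se = math.sqrt(p[i] * (1 - p[i]) / n_moves) * math.sqrt(10.0)
            assert abs(obs - p[i]) < max(3 * se, 5e-3)

    def test_seed_determinism(self):
        spec = ToyModelSpec(n_sweeps=50, burn_in_sweeps=20, seed=11)
        a = sample_ensemble(spec)
        b = sample_ensemble(spec)
        assert len(a) == len(b)
        np.testing.assert_array_equal(a.energies, b.energies)
        np.testing.assert_array_equal(a.frames[10].coords,
                                      b.frames[10].coords)

    def test_sampled_f8_matches_oracle_per_rung(self, sampled_ensemble,
                                                oracle):
        from pepagg.oligomers import frame_oligomer_fractions

        fm = frame_oligomer_fractions(sampled_ensemble)
        ti = sampled_ensemble.temp_indices
        for k, T in enumerate(sampled_ensemble.ladder.temperatures):
            f8 = fm[ti == k, -1]
            blocks = np.array_split(f8, 20)
            bm = np.array([b.mean() for b in blocks])
            se = bm.std(ddof=1) / np.sqrt(len(bm))
            assert abs(f8.mean() - oracle.f_full(T)) < max(3 * se, 0.02)

    def test_wham_free_energies_match_oracle_partition_function(
            self, sampled_ensemble, oracle):
        from pepagg.wham import solve_wham

        table = solve_wham(sampled_ensemble)
        temps = sampled_ensemble.ladder.temperatures
        lz = np.array([oracle.log_partition(T) for T in temps])
        exact = -(lz - lz[0])
        np.testing.assert_allclose(table.free_energies, exact, atol=0.25)


class TestRendering:
    def test_rendered_partitions_are_recovered(self, rng):
        box = BoxSpec(100.0)
        from pepagg.ensemble import Frame

        for _ in range(30):
            # random partition of 8 chains
            labels = rng.integers(0, 4, size=8)
            blocks = [tuple(np.nonzero(labels == b)[0])
                      for b in np.unique(labels)]
            coords = render_partition(blocks, 6, box, rng)
            frame = Frame(coords=coords, energy=0.0, temp_index=0,
                          traj_id=0, step=0)
            found = identify_oligomers(frame, box)
            assert set(map(frozenset, found.blocks)) == set(
                map(frozenset, blocks))

    def test_sampled_ensemble_frames_recover_generating_partitions(
            self, sampled_ensemble):
        idx = np.linspace(0, len(sampled_ensemble) - 1, 50, dtype=int)
        parts = sampled_ensemble.generating_partitions
        for i in idx:
            found = identify_oligomers(sampled_ensemble.frames[i],
                                       sampled_ensemble.box)
            assert set(map(frozenset, found.blocks)) == set(
                map(frozenset, parts[i]))

    def test_box_too_small_raises(self, rng):
        with pytest.raises(RuntimeError, match="box"):
            render_partition([(i,) for i in range(8)], 6, BoxSpec(15.0), rng)


class TestReferenceGeometries:
    def test_helix_virtual_bond_length(self):
        h = build_reference_geometries("ideal-helix", 10)
        bonds = np.linalg.norm(np.diff(h, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 3.8, atol=0.1)

    def test_strand_extension_per_bond(self):
        s = build_reference_geometries("ideal-sheet", 12)
        ee = np.linalg.norm(s[-1] - s[0]) / 11
        assert 3.4 <= ee <= 3.6

    def test_coil_self_avoidance(self, rng):
        c = build_reference_geometries("random-coil", 12, rng=rng)
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        sep = np.abs(np.arange(12)[:, None] - np.arange(12)[None, :])
        assert d[sep >= 2].min() >= 4.0 - 1e-9

    def test_sheet_spacing(self):
        sh = sheet_coords(3, 8)
        gap = np.linalg.norm(sh[1] - sh[0], axis=1)
        np.testing.assert_allclose(gap, 4.8)
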