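"""Binless multi-temperature reweighting (WHAM) and derived profiles.

Given snapshots sampled at the rungs of a temperature ladder, the binless
WHAM self-consistency equations

    exp(-f_k) = sum_i exp(-beta_k E_i) / sum_l N_l exp(f_l - beta_l E_i)

are solved for one dimensionless free energy f_k per rung (gauge f_0 = 0).
Normalized per-snapshot weights at an arbitrary target temperature T are

    w_i(T) proportional to exp(-beta E_i) / sum_l N_l exp(f_l - beta_l E_i)

and turn per-snapshot observables into continuous temperature profiles
(oligomer-size fractions, secondary-structure fractions) and the heat
capacity C_v(T) = (<E^2> - <E>^2) / (k_B T^2). All exponentials are
evaluated in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB_KCAL
from .ensemble import EnsembleSet, TemperatureLadder
from .errors import ConvergenceError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemperatureProfile:
    """An observable evaluated on a strictly increasing temperature grid."""

    grid: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if len(values) != len(grid):
            raise ValueError("values and grid lengths differ")
        if not np.all(np.isfinite(values)):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.grid)


@dataclass(frozen=True)
class WeightTable:
    """Solved free energies plus the snapshot-weight function.

    ``free_energies[k]`` is the dimensionless f_k of ladder rung k with the
    gauge f_0 = 0. ``weights(T)`` returns normalized per-snapshot weights.
    """

    ladder: TemperatureLadder
    free_energies: np.ndarray
    energies: np.ndarray
    sample_counts: np.ndarray
    kB: float = KB_KCAL

    def log_weights(self, T: float) -> np.ndarray:
        beta = 1.0 / (self.kB * T)
        betas_k = 1.0 / (self.kB * self.ladder.as_array())
        counts = np.asarray(self.sample_counts, dtype=float)
        # rungs without samples contribute nothing to the denominator
        log_counts = np.where(counts > 0, np.log(np.maximum(counts, 1)),
                              -np.inf)
        # log denominator: logsumexp over rungs of log N_l + f_l - beta_l E_i
        log_denom = logsumexp(
            log_counts[:, None]
            + self.free_energies[:, None]
            - betas_k[:, None] * self.energies[None, :],
            axis=0,
        )
        logw = -beta * self.energies - log_denom
        return logw - logsumexp(logw)

    def weights(self, T: float) -> np.ndarray:
        return np.exp(self.log_weights(T))


def solve_wham(ensemble: EnsembleSet, tol: float = 1e-10,
               max_iter: int = 100000) -> WeightTable:
    """Solve the binless self-consistency equations by direct iteration.

    Converges on max |delta f_k| < tol; deterministic given input order.
    A single-temperature ensemble yields the degenerate uniform solution
    with a warning.
    """
    energies = ensemble.energies
    counts = ensemble.sample_counts
    ladder = ensemble.ladder
    occupied = counts > 0
    if occupied.sum() < 2:
        logger.warning("single-temperature ensemble: uniform weights")
        return WeightTable(ladder=ladder, free_energies=np.zeros(len(ladder)),
                           energies=energies, sample_counts=counts)
    if not np.all(occupied):
        raise ValueError("every ladder rung needs at least one snapshot")

    betas = 1.0 / (KB_KCAL * ladder.as_array())
    neg_be = -betas[:, None] * energies[None, :]  # (K, N)
    log_counts = np.log(counts)
    f = np.zeros(len(ladder))
    for _ in range(max_iter):
        log_denom = logsumexp(log_counts[:, None] + f[:, None] + neg_be, axis=0)
        f_new = -logsumexp(neg_be - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations", residual=delta
        )
    return WeightTable(ladder=ladder, free_energies=f, energies=energies,
                       sample_counts=counts)


def temperature_grid(start: float = 260.0, stop: float = 370.0,
                     step: float = 1.0) -> np.ndarray:
    return np.arange(start, stop + 0.5 * step, step)


def ensemble_average(table: WeightTable, per_frame_values: np.ndarray,
                     grid: np.ndarray, label: str = "") -> TemperatureProfile:
    """Reweighted average of a per-snapshot observable on a temperature grid.

    ``per_frame_values`` may be (N,) or (N, m); the profile then carries one
    column per observable component.
    """
    values = np.asarray(per_frame_values, dtype=float)
    if len(values) != len(table.energies):
        raise ValueError("need one value per snapshot")
    grid = np.asarray(grid, dtype=float)
    out = np.empty((len(grid),) + values.shape[1:])
    for g, T in enumerate(grid):
        out[g] = table.weights(T) @ values
    return TemperatureProfile(grid=grid, values=out, label=label)


def heat_capacity(table: WeightTable, grid: np.ndarray,
                  label: str = "Cv") -> TemperatureProfile:
    """C_v(T) from the reweighted energy fluctuations, per system, in the
    declared energy unit per kelvin."""
    grid = np.asarray(grid, dtype=float)
    E = table.energies
    cv = np.empty(len(grid))
    for g, T in enumerate(grid):
        w = table.weights(T)
        mean = w @ E
        var = w @ (E - mean) ** 2
        cv[g] = var / (table.kB * T * T)
    return TemperatureProfile(grid=grid, values=cv, label=label)
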