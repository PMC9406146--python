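"""End-to-end analysis: ensemble -> temperature profiles -> melting summary."""

from __future__ import annotations

import numpy as np

from .ensemble import EnsembleSet
from .melting import (MeltingSummary, cv_peaks, inflection_temperature,
                      midpoint_temperature)
from .oligomers import DEFAULT_CUTOFF, frame_oligomer_fractions
from .secstruct import DEFAULT_PARAMS, SecStructParams, frame_state_fractions
from .wham import (TemperatureProfile, WeightTable, ensemble_average,
                   heat_capacity, solve_wham, temperature_grid)


def oligomer_profiles(ensemble: EnsembleSet, grid: np.ndarray | None = None,
                      cutoff: float = DEFAULT_CUTOFF,
                      table: WeightTable | None = None) -> TemperatureProfile:
    """Reweighted f_m(T) for all oligomer sizes; columns m = 1..n_chains."""
    if grid is None:
        grid = temperature_grid(ensemble.ladder[0], ensemble.ladder[-1])
    table = table or solve_wham(ensemble)
    fm = frame_oligomer_fractions(ensemble, cutoff)
    return ensemble_average(table, fm, grid, label="f_m")


def full_aggregate_profile(ensemble: EnsembleSet,
                           grid: np.ndarray | None = None,
                           cutoff: float = DEFAULT_CUTOFF,
                           table: WeightTable | None = None) -> TemperatureProfile:
    """f_n(T): fraction of chains in the complete n-chain aggregate."""
    prof = oligomer_profiles(ensemble, grid, cutoff, table)
    return TemperatureProfile(grid=prof.grid, values=prof.values[:, -1],
                              label=f"f_{ensemble.n_chains}")


def secondary_structure_profiles(ensemble: EnsembleSet,
                                 grid: np.ndarray | None = None,
                                 params: SecStructParams = DEFAULT_PARAMS,
                                 table: WeightTable | None = None
                                 ) -> TemperatureProfile:
    """Reweighted (f_alpha, f_beta, f_c)(T); columns in that order."""
    if grid is None:
        grid = temperature_grid(ensemble.ladder[0], ensemble.ladder[-1])
    table = table or solve_wham(ensemble)
    fs = frame_state_fractions(ensemble, params)
    return ensemble_average(table, fs, grid, label="f_s")


def melting_summary(ensemble: EnsembleSet, grid: np.ndarray | None = None,
                    cutoff: float = DEFAULT_CUTOFF,
                    with_secondary_structure: bool = True) -> MeltingSummary:
    """T8m (aggregate-dissociation midpoint), beta inflection and Cv peaks."""
    if grid is None:
        grid = temperature_grid(ensemble.ladder[0], ensemble.ladder[-1])
    table = solve_wham(ensemble)
    f_full = full_aggregate_profile(ensemble, grid, cutoff, table)
    t8m = midpoint_temperature(f_full)
    ti_beta = None
    if with_secondary_structure:
        fs = secondary_structure_profiles(ensemble, grid, table=table)
        beta = TemperatureProfile(grid=fs.grid, values=fs.values[:, 1],
                                  label="f_beta")
        ti_beta = inflection_temperature(beta)
    cv = heat_capacity(table, grid)
    return MeltingSummary(T8m=t8m, Ti_beta=ti_beta,
                          cv_peaks=tuple(cv_peaks(cv)))
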