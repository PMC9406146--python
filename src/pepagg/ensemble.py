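"""Data model for multi-chain coarse-grained replica-exchange ensembles.

A :class:`Frame` holds the Cα coordinates of every chain in one snapshot
together with its potential energy and replica metadata (sampling-temperature
index, trajectory id, step). An :class:`EnsembleSet` is the ordered frame
collection plus the temperature ladder and periodic box it was sampled under.

Coordinates are stored unwrapped per chain (a stored chain never straddles
the periodic boundary); inter-chain distances must always be taken under the
minimum-image convention via :func:`min_image_distance`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EnsembleFormatError, ShortTrajectoryError

#: The 12-rung ladder used for all default simulations (kelvin).
DEFAULT_LADDER_K = (260.0, 272.0, 279.0, 284.0, 288.0, 291.0,
                    294.0, 298.0, 308.0, 322.0, 341.0, 370.0)


@dataclass(frozen=True)
class TemperatureLadder:
    """Strictly increasing list of replica temperatures in kelvin."""

    temperatures: tuple = DEFAULT_LADDER_K

    def __post_init__(self):
        temps = tuple(float(t) for t in self.temperatures)
        object.__setattr__(self, "temperatures", temps)
        if len(temps) < 2:
            raise ValueError("ladder needs at least 2 temperatures")
        if any(t <= 0 for t in temps):
            raise ValueError("temperatures must be positive")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperatures)

    def __getitem__(self, k: int) -> float:
        return self.temperatures[k]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.temperatures)


@dataclass(frozen=True)
class BoxSpec:
    """Cubic simulation box; side in angstrom."""

    side: float
    periodic: bool = True

    def __post_init__(self):
        if not self.side > 0:
            raise ValueError("box side must be positive")


@dataclass(frozen=True)
class Frame:
    """One snapshot: per-chain Cα coordinates plus energy and replica metadata."""

    coords: np.ndarray  # (n_chains, n_residues, 3), angstrom
    energy: float
    temp_index: int
    traj_id: int
    step: int

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3 or coords.shape[0] < 1:
            raise ValueError("coords must have shape (n_chains, n_residues, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_chains(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def chain(self, j: int) -> np.ndarray:
        return self.coords[j]


@dataclass
class EnsembleSet:
    """Ordered frames with their ladder and box.

    ``sample_counts[k]`` is the number of frames sampled at ladder rung ``k``
    (the N_k consumed by the multi-temperature reweighting).
    """

    frames: list = field(default_factory=list)
    ladder: TemperatureLadder = field(default_factory=TemperatureLadder)
    box: BoxSpec = field(default_factory=lambda: BoxSpec(100.0))
    energy_unit: str = "kcal/mol"

    def __post_init__(self):
        if self.frames:
            n_chains = self.frames[0].n_chains
            n_res = self.frames[0].n_residues
            for f in self.frames:
                if f.n_chains != n_chains or f.n_residues != n_res:
                    raise EnsembleFormatError("inconsistent frame dimensions")
                if not 0 <= f.temp_index < len(self.ladder):
                    raise EnsembleFormatError(
                        f"temp_index {f.temp_index} outside ladder of "
                        f"length {len(self.ladder)}"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_chains(self) -> int:
        return self.frames[0].n_chains

    @property
    def residues_per_chain(self) -> int:
        return self.frames[0].n_residues

    @property
    def energies(self) -> np.ndarray:
        return np.array([f.energy for f in self.frames])

    @property
    def temp_indices(self) -> np.ndarray:
        return np.array([f.temp_index for f in self.frames], dtype=int)

    @property
    def sample_counts(self) -> np.ndarray:
        return np.bincount(self.temp_indices, minlength=len(self.ladder))

    def traj_ids(self) -> np.ndarray:
        return np.array([f.traj_id for f in self.frames], dtype=int)


def analysis_window(ensemble: EnsembleSet, window_frames: int = 1000,
                    stride: int = 8) -> EnsembleSet:
    """Keep, per trajectory, the final ``window_frames`` frames sub-sampled
    at every ``stride``-th snapshot.

    With 48 trajectories, a 1000-frame window and stride 8 this yields the
    canonical 6000 analysis snapshots. Frames within a trajectory are taken
    in stored (step) order; the sub-sample keeps the last frame of every
    consecutive ``stride``-long group.
    """
    if window_frames < 1 or stride < 1:
        raise ValueError("window_frames and stride must be positive")
    by_traj: dict[int, list[Frame]] = {}
    for f in ensemble.frames:
        by_traj.setdefault(f.traj_id, []).append(f)
    kept: list[Frame] = []
    for traj_id in sorted(by_traj):
        frames = sorted(by_traj[traj_id], key=lambda f: f.step)
        if len(frames) < window_frames:
            raise ShortTrajectoryError(traj_id, len(frames), window_frames)
        tail = frames[-window_frames:]
        kept.extend(tail[stride - 1::stride])
    return replace(ensemble, frames=kept)


def min_image_displacement(a: np.ndarray, b: np.ndarray,
                           box: BoxSpec) -> np.ndarray:
    """Minimum-image displacement(s) b - a under the cubic periodic box.

    Broadcasts over leading dimensions; the last axis must be 3.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box.periodic:
        d = d - box.side * np.round(d / box.side)
    return d


def min_image_distance(a: np.ndarray, b: np.ndarray, box: BoxSpec) -> float:
    """Euclidean distance under the cubic minimum-image convention."""
    d = min_image_displacement(a, b, box)
    return float(np.linalg.norm(d, axis=-1)) if d.ndim == 1 else np.linalg.norm(d, axis=-1)
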