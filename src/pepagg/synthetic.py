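"""Synthetic replica-exchange ensembles with exactly known thermodynamics.

The generator emulates a multi-chain aggregation simulation with a chain
-partition Hamiltonian: a configuration is a set partition P of the n
chains into oligomer blocks, with energy

    E(P) = -epsilon * sum_blocks C(|b|, 2)

(every associated chain pair contributes -epsilon) and a temperature
-independent translational-entropy factor nu per block, giving the weight

    w(P, T) = nu^{|P|} * exp(-E(P) / (k_B T)).

For n <= 10 chains the partition function is enumerable (Bell(8) = 4140),
so oligomer-size fractions, mean energy, heat capacity and the exact
dissociation midpoint are available in closed form
(:class:`PartitionOracle`). The same model is sampled by a Metropolis
Markov chain (single-chain merge/split moves with exact proposal
correction) under replica exchange across a temperature ladder, and every
snapshot is rendered into Cα coordinates — blocks as parallel in-register
extended strands, free chains as random coils, placed in the periodic box
with all inter-block Cα distances beyond the association cutoff — so the
full geometric analysis pipeline can be exercised against the oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation
from scipy.special import logsumexp
from sympy.utilities.iterables import multiset_partitions

from .constants import KB_KCAL
from .ensemble import BoxSpec, EnsembleSet, Frame, TemperatureLadder

BOND_LENGTH = 3.8          # Cα virtual-bond length, angstrom
STRAND_SPACING = 4.8       # inter-strand spacing in a rendered block
HELIX_RISE, HELIX_RADIUS, HELIX_TWIST = 1.5, 2.3, 100.0
ASSOCIATION_CUTOFF = 7.0
PLACEMENT_MARGIN = 1.0


@dataclass(frozen=True)
class ToyModelSpec:
    """Study conditions of one synthetic aggregation system."""

    n_chains: int = 8
    residues_per_chain: int = 6
    epsilon: float = 0.6       # kcal/mol per associated chain pair
    nu: float = 50.0           # translational-entropy factor per block
    ladder: TemperatureLadder = field(default_factory=TemperatureLadder)
    box: BoxSpec = field(default_factory=lambda: BoxSpec(100.0))
    n_sweeps: int = 2500       # recorded sweeps after burn-in
    exchange_interval: int = 5  # sweeps between exchange/recording points
    burn_in_sweeps: int = 500
    multiplex: int = 1         # independent replica sets (trajectories per rung)
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_chains <= 10:
            raise ValueError("n_chains must be in 1..10 (exact enumeration)")
        # epsilon = 0 is the degenerate athermal (pure-entropy) model
        if self.epsilon < 0 or self.nu <= 0:
            raise ValueError("epsilon must be >= 0 and nu > 0")


def _canonical(blocks) -> tuple:
    return tuple(sorted((tuple(sorted(b)) for b in blocks), key=lambda b: b[0]))


class PartitionOracle:
    """Exact thermodynamics of the chain-partition model by enumeration."""

    def __init__(self, spec: ToyModelSpec):
        self.spec = spec
        n = spec.n_chains
        parts = [_canonical(p) for p in multiset_partitions(list(range(n)))]
        self.partitions = parts
        self.index = {p: i for i, p in enumerate(parts)}
        self.bonds = np.array(
            [sum(len(b) * (len(b) - 1) // 2 for b in p) for p in parts]
        )
        self.n_blocks = np.array([len(p) for p in parts])
        fm = np.zeros((len(parts), n))
        for i, p in enumerate(parts):
            for b in p:
                fm[i, len(b) - 1] += len(b) / n
        self.fm = fm

    def log_weights(self, T: float) -> np.ndarray:
        beta_eps = self.spec.epsilon / (KB_KCAL * T)
        return self.n_blocks * math.log(self.spec.nu) + self.bonds * beta_eps

    def stationary_distribution(self, T: float) -> np.ndarray:
        lw = self.log_weights(T)
        return np.exp(lw - logsumexp(lw))

    def log_partition(self, T: float) -> float:
        """log of the configurational partition sum at T."""
        return float(logsumexp(self.log_weights(T)))

    def fractions(self, T: float) -> np.ndarray:
        """Exact f_m(T), m = 1..n_chains; sums to 1."""
        return self.stationary_distribution(T) @ self.fm

    def f_full(self, T: float) -> float:
        """Fraction of chains in the complete n-chain aggregate."""
        return float(self.fractions(T)[-1])

    def mean_energy(self, T: float) -> float:
        p = self.stationary_distribution(T)
        return float(p @ (-self.spec.epsilon * self.bonds))

    def heat_capacity(self, T: float) -> float:
        p = self.stationary_distribution(T)
        e = -self.spec.epsilon * self.bonds
        mean = p @ e
        return float(p @ (e - mean) ** 2) / (KB_KCAL * T * T)

    def midpoint(self) -> float:
        """Exact temperature where f_n(T) crosses 1/2 (bisection)."""
        lo, hi = 10.0, 5000.0
        if self.f_full(lo) < 0.5:
            raise ValueError("aggregate never dominates; midpoint below range")
        if self.f_full(hi) > 0.5:
            raise ValueError("aggregate never dissociates; midpoint above range")
        return float(brentq(lambda T: self.f_full(T) - 0.5, lo, hi, xtol=1e-8))

    def sample_indices(self, T: float, size: int,
                       rng: np.random.Generator) -> np.ndarray:
        """I.i.d. partition indices from the exact distribution at T."""
        return rng.choice(len(self.partitions), size=size,
                          p=self.stationary_distribution(T))


def enumerate_partition_model(spec: ToyModelSpec) -> PartitionOracle:
    return PartitionOracle(spec)


# ---------------------------------------------------------------------------
# reference geometries


def strand_coords(n_res: int, bond: float = BOND_LENGTH,
                  bond_angle_deg: float = 135.0) -> np.ndarray:
    """Ideally extended (pleated zigzag) Cα strand along x, in the xz plane."""
    ang = math.radians(bond_angle_deg)
    step = bond * math.sin(ang / 2.0)
    h = bond * math.cos(ang / 2.0)
    return np.array([[i * step, 0.0, (h / 2.0 if i % 2 else -h / 2.0)]
                     for i in range(n_res)])


def helix_coords(n_res: int, rise: float = HELIX_RISE,
                 radius: float = HELIX_RADIUS,
                 twist_deg: float = HELIX_TWIST) -> np.ndarray:
    """Ideal right-handed α-helical Cα trace."""
    t = np.radians(twist_deg * np.arange(n_res))
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            rise * np.arange(n_res)])


def coil_coords(n_res: int, rng: np.random.Generator,
                bond: float = BOND_LENGTH, min_sep: float = 4.0,
                max_tries: int = 200) -> np.ndarray:
    """Self-avoiding random Cα walk with fixed bond length."""
    for _ in range(max_tries):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n_res - 1):
            for _ in range(50):
                v = rng.normal(size=3)
                cand = pts[-1] + bond * v / np.linalg.norm(v)
                if all(np.linalg.norm(cand - p) >= min_sep for p in pts[:-1]):
                    pts.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError("could not generate a self-avoiding coil")


def build_reference_geometries(kind: str, n_res: int,
                               rng: np.random.Generator | None = None,
                               **params) -> np.ndarray:
    """Analytic fixture chains: 'ideal-helix', 'ideal-sheet' (one ideally
    extended strand; stack copies at ``STRAND_SPACING`` for a sheet) or
    'random-coil'."""
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    if kind == "ideal-helix":
        return helix_coords(n_res, **params)
    if kind in ("ideal-sheet", "extended-strand"):
        return strand_coords(n_res, **params)
    if kind == "random-coil":
        if rng is None:
            rng = np.random.default_rng(0)
        return coil_coords(n_res, rng, **params)
    raise ValueError(f"unknown geometry kind {kind!r}")


def sheet_coords(n_strands: int, n_res: int,
                 spacing: float = STRAND_SPACING) -> np.ndarray:
    """Parallel in-register extended strands, shape (n_strands, n_res, 3)."""
    strand = strand_coords(n_res)
    return np.stack([strand + np.array([0.0, s * spacing, 0.0])
                     for s in range(n_strands)])


# ---------------------------------------------------------------------------
# Markov-chain sampler


class _PartitionState:
    """Mutable labeled partition with incremental bond bookkeeping."""

    def __init__(self, n_chains: int):
        self.blocks: list[list[int]] = [[c] for c in range(n_chains)]
        self.where = list(range(n_chains))
        self.bonds = 0
        self.n = n_chains

    def copy_from(self, other: "_PartitionState"):
        self.blocks = [list(b) for b in other.blocks]
        self.where = list(other.where)
        self.bonds = other.bonds

    def canonical(self) -> tuple:
        return _canonical(self.blocks)

    def n_targets(self, c: int) -> int:
        s = len(self.blocks[self.where[c]])
        return (len(self.blocks) - 1) + (1 if s > 1 else 0)


def _attempt_move(state: _PartitionState, beta_eps: float, log_nu: float,
                  rng: np.random.Generator) -> None:
    """One single-chain reassignment move (Metropolis–Hastings)."""
    n = state.n
    if n < 2:
        return
    c = int(rng.integers(n))
    src = state.where[c]
    s = len(state.blocks[src])
    others = [b for b in range(len(state.blocks)) if b != src]
    targets = list(others)
    if s > 1:
        targets.append(-1)  # split off into a new singleton block
    if not targets:
        return
    tgt = targets[int(rng.integers(len(targets)))]
    t = 0 if tgt == -1 else len(state.blocks[tgt])

    delta_bonds = t - (s - 1)
    delta_blocks = (1 if tgt == -1 else 0) - (1 if s == 1 else 0)
    # forward/reverse proposal counts
    n_fwd = state.n_targets(c)
    n_blocks_new = len(state.blocks) + delta_blocks
    n_rev = (n_blocks_new - 1) + (1 if t + 1 > 1 else 0)

    log_acc = (delta_blocks * log_nu + beta_eps * delta_bonds
               + math.log(n_fwd) - math.log(n_rev))
    if log_acc < 0 and rng.random() >= math.exp(log_acc):
        return

    # apply: remove c from src, insert into tgt (or new block)
    state.blocks[src].remove(c)
    if tgt == -1:
        state.blocks.append([c])
        state.where[c] = len(state.blocks) - 1
    else:
        state.blocks[tgt].append(c)
        state.where[c] = tgt
    if not state.blocks[src]:
        last = len(state.blocks) - 1
        state.blocks[src] = state.blocks[last]
        for ch in state.blocks[src]:
            state.where[ch] = src
        state.blocks.pop()
    state.bonds += delta_bonds


def run_partition_chain(spec: ToyModelSpec, T: float, n_moves: int,
                        rng: np.random.Generator,
                        record_every: int = 1) -> list[tuple]:
    """Plain (single-temperature) Metropolis chain; returns canonical
    partitions recorded every ``record_every`` moves. Used for detailed
    -balance validation."""
    state = _PartitionState(spec.n_chains)
    beta_eps = spec.epsilon / (KB_KCAL * T)
    log_nu = math.log(spec.nu)
    out = []
    for m in range(n_moves):
        _attempt_move(state, beta_eps, log_nu, rng)
        if (m + 1) % record_every == 0:
            out.append(state.canonical())
    return out


# ---------------------------------------------------------------------------
# coordinate rendering


def _block_geometry(size: int, n_res: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Centered coordinates of one oligomer block or free chain."""
    if size == 1:
        geom = coil_coords(n_res, rng)[None]
    else:
        geom = sheet_coords(size, n_res)
    geom = geom - geom.reshape(-1, 3).mean(axis=0)
    rot = Rotation.from_quat(rng.normal(size=4))  # uniform random rotation
    return rot.apply(geom.reshape(-1, 3)).reshape(geom.shape)


def render_partition(blocks, n_res: int, box: BoxSpec,
                     rng: np.random.Generator,
                     max_tries: int = 2000) -> np.ndarray:
    """Lay a chain partition out in the periodic box.

    Oligomer blocks become parallel in-register extended strands (so every
    member chain satisfies the association criterion transitively and
    interior residues satisfy the β criteria); free chains become random
    coils. Block placements keep every inter-block Cα pair farther than the
    association cutoff plus a margin, under the minimum image.
    """
    n_chains = sum(len(b) for b in blocks)
    coords = np.empty((n_chains, n_res, 3))
    placed: list[tuple[np.ndarray, float]] = []
    for block in blocks:
        geom = _block_geometry(len(block), n_res, rng)
        radius = float(np.max(np.linalg.norm(geom.reshape(-1, 3), axis=1)))
        for attempt in range(max_tries):
            center = rng.uniform(0.0, box.side, size=3)
            ok = True
            for other_center, other_radius in placed:
                d = center - other_center
                d -= box.side * np.round(d / box.side)
                if np.linalg.norm(d) < (radius + other_radius
                                        + ASSOCIATION_CUTOFF + PLACEMENT_MARGIN):
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not place a block of radius {radius:.1f} in a box of "
                f"side {box.side:.1f}; increase the box side"
            )
        placed.append((center, radius))
        for chain_pos, chain_idx in enumerate(block):
            coords[chain_idx] = geom[chain_pos] + center
    return coords


# ---------------------------------------------------------------------------
# replica-exchange sampling


def sample_ensemble(spec: ToyModelSpec) -> EnsembleSet:
    """Replica-exchange Monte Carlo over chain partitions, rendered to
    coordinates.

    One Markov chain runs per ladder rung (times ``multiplex``); snapshots
    are recorded at every exchange point after burn-in. ``traj_id`` is the
    temperature-ordered trajectory index, ``step`` the sweep count.
    Deterministic for a fixed ``seed``. The returned ensemble carries the
    generating partitions (one canonical block tuple per frame, in frame
    order) as the attribute ``generating_partitions``.
    """
    rng = np.random.default_rng(spec.seed)
    temps = spec.ladder.as_array()
    n_rungs = len(temps)
    log_nu = math.log(spec.nu)
    betas_eps = spec.epsilon / (KB_KCAL * temps)
    frames: list[Frame] = []
    partitions: list[tuple] = []

    for rep in range(spec.multiplex):
        states = [_PartitionState(spec.n_chains) for _ in range(n_rungs)]
        total_sweeps = spec.burn_in_sweeps + spec.n_sweeps
        for sweep in range(1, total_sweeps + 1):
            for k in range(n_rungs):
                for _ in range(spec.n_chains):
                    _attempt_move(states[k], betas_eps[k], log_nu, rng)
            if sweep % spec.exchange_interval == 0:
                # alternate even/odd neighbor pairs
                start = (sweep // spec.exchange_interval) % 2
                for k in range(start, n_rungs - 1, 2):
                    e_k = -spec.epsilon * states[k].bonds
                    e_k1 = -spec.epsilon * states[k + 1].bonds
                    d_beta = (1.0 / (KB_KCAL * temps[k])
                              - 1.0 / (KB_KCAL * temps[k + 1]))
                    log_acc = d_beta * (e_k - e_k1)
                    if log_acc >= 0 or rng.random() < math.exp(log_acc):
                        states[k], states[k + 1] = states[k + 1], states[k]
                if sweep > spec.burn_in_sweeps:
                    for k in range(n_rungs):
                        coords = render_partition(states[k].blocks,
                                                  spec.residues_per_chain,
                                                  spec.box, rng)
                        frames.append(Frame(
                            coords=coords,
                            energy=-spec.epsilon * states[k].bonds,
                            temp_index=k,
                            traj_id=rep * n_rungs + k,
                            step=sweep,
                        ))
                        partitions.append(states[k].canonical())
    ens = EnsembleSet(frames=frames, ladder=spec.ladder, box=spec.box)
    ens.generating_partitions = partitions
    return ens
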