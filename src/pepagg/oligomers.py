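"""Oligomer identification from the inter-chain Cα contact criterion.

Two chains are associated when any Cα of one lies strictly closer than the
cutoff (default 7 Å) to any Cα of the other, distances taken under the
minimum-image convention of the periodic box. Oligomers are grown
iteratively: starting from the lowest unassigned chain index, the remaining
chains are repeatedly scanned in index order for one associated with any
current member; when none is found the oligomer is closed and the search
restarts at the next unassigned chain. The result coincides with the
connected components of the pairwise association graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import BoxSpec, EnsembleSet, Frame, min_image_displacement

DEFAULT_CUTOFF = 7.0  # angstrom, strict inequality


@dataclass(frozen=True)
class OligomerPartition:
    """Disjoint blocks of chain indices covering all chains of one frame."""

    blocks: tuple  # tuple of sorted tuples of chain indices
    n_chains: int

    def __post_init__(self):
        blocks = tuple(tuple(sorted(b)) for b in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        members = sorted(i for b in blocks for i in b)
        if members != list(range(self.n_chains)):
            raise ValueError("blocks must partition the chain indices")

    @property
    def size_counts(self) -> np.ndarray:
        """``size_counts[m-1]`` = number of m-chain oligomers."""
        counts = np.zeros(self.n_chains, dtype=int)
        for b in self.blocks:
            counts[len(b) - 1] += 1
        return counts

    def sizes(self) -> tuple:
        return tuple(sorted((len(b) for b in self.blocks), reverse=True))


def chains_associated(chain_a: np.ndarray, chain_b: np.ndarray, box: BoxSpec,
                      cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True iff the minimum Cα–Cα minimum-image distance is < cutoff."""
    d = min_image_displacement(chain_a[:, None, :], chain_b[None, :, :], box)
    return bool(np.min(np.einsum("ijk,ijk->ij", d, d)) < cutoff * cutoff)


def _association_matrix(frame: Frame, box: BoxSpec, cutoff: float) -> np.ndarray:
    n = frame.n_chains
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if chains_associated(frame.coords[i], frame.coords[j], box, cutoff):
                adj[i, j] = adj[j, i] = True
    return adj


def identify_oligomers(frame: Frame, box: BoxSpec,
                       cutoff: float = DEFAULT_CUTOFF) -> OligomerPartition:
    """Assign every chain of the frame to an oligomer (or leave it isolated)."""
    adj = _association_matrix(frame, box, cutoff)
    n = frame.n_chains
    unassigned = list(range(n))
    blocks = []
    while unassigned:
        seed = unassigned.pop(0)
        oligomer = [seed]
        grown = True
        while grown:
            grown = False
            for c in list(unassigned):  # scan remaining chains in index order
                if any(adj[c, member] for member in oligomer):
                    oligomer.append(c)
                    unassigned.remove(c)
                    grown = True
                    break
        blocks.append(tuple(oligomer))
    return OligomerPartition(blocks=tuple(blocks), n_chains=n)


def oligomer_fractions(partition: OligomerPartition) -> np.ndarray:
    """Fraction of chains residing in m-chain oligomers.

    Returns ``f`` with ``f[m-1] = m * count(m) / n_chains``; sums to 1.
    """
    m = np.arange(1, partition.n_chains + 1)
    return m * partition.size_counts / partition.n_chains


def frame_oligomer_fractions(ensemble: EnsembleSet,
                             cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Per-frame oligomer-size fractions, shape (n_frames, n_chains)."""
    return np.array(
        [oligomer_fractions(identify_oligomers(f, ensemble.box, cutoff))
         for f in ensemble.frames]
    )
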