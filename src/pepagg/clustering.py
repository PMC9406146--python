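"""Conformational clustering of snapshots and per-residue fluctuations.

Frames are compared by all-chain Cα RMSD after optimal rigid superposition;
because the chains share one sequence they are interchangeable, so the
default metric additionally minimizes over chain relabelings (assignment on
chain-centroid distances, refined by re-superposition). Ward
minimum-variance linkage on that distance matrix, cut at k clusters, yields
conformational families which are ranked by the cumulative reweighting
probability of their members; each family is represented by its medoid.
RMSF profiles are the per-residue standard deviations of Cα positions of
all chains of a frame set about the iteratively superposed mean chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .ensemble import Frame


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of point sets (n,3) after centering and optimal rotation."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


def _superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigidly superpose mobile (n,3) onto target; returns moved copy."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def frame_distance(a: Frame, b: Frame, mode: str = "best-permutation") -> float:
    """All-chain Cα RMSD between two frames.

    ``fixed-labels`` keeps chain identities; ``best-permutation`` minimizes
    over chain relabelings of ``b`` (iterated centroid assignment +
    re-superposition), appropriate for identical-sequence chains.
    """
    if a.coords.shape != b.coords.shape:
        raise ValueError("frames have different dimensions")
    n_chains = a.n_chains
    flat_a = a.coords.reshape(-1, 3)
    if mode == "fixed-labels":
        return _kabsch_rmsd(flat_a, b.coords.reshape(-1, 3))
    if mode != "best-permutation":
        raise ValueError(f"unknown mode {mode!r}")

    perm = np.arange(n_chains)
    best = np.inf
    for _ in range(10):
        moved = _superpose(b.coords[perm].reshape(-1, 3), flat_a)
        cents_b = moved.reshape(n_chains, -1, 3).mean(axis=1)
        cents_a = a.coords.mean(axis=1)
        cost = np.linalg.norm(cents_a[:, None] - cents_b[None, :], axis=-1)
        _, cols = linear_sum_assignment(cost)
        new_perm = perm[cols]
        rmsd = _kabsch_rmsd(flat_a, b.coords[new_perm].reshape(-1, 3))
        if rmsd >= best - 1e-12:
            best = min(best, rmsd)
            break
        best, perm = rmsd, new_perm
    return best


@dataclass(frozen=True)
class ClusterSet:
    """k conformational families ranked by cumulative snapshot probability."""

    frame_indices: np.ndarray   # indices (into the source frame list) used
    assignments: np.ndarray     # cluster rank per used frame, 0 = most probable
    probabilities: np.ndarray   # cumulative weight per cluster, sums to 1
    representatives: np.ndarray  # one source frame index per cluster
    k: int


def ward_cluster(frames: list[Frame], weights: np.ndarray, k: int = 5,
                 mode: str = "best-permutation", subsample: int = 600,
                 seed: int = 0) -> ClusterSet:
    """Ward minimum-variance clustering of frames under the RMSD metric.

    ``weights`` are the per-frame reweighting probabilities at the analysis
    temperature; when there are more frames than ``subsample``, a
    probability-weighted subsample (fixed ``seed``) bounds the O(n^2)
    distance matrix. Clusters are ordered by descending cumulative weight;
    ties in the merge sequence follow the lowest-index convention of the
    linkage implementation.
    """
    weights = np.asarray(weights, dtype=float)
    if len(frames) != len(weights):
        raise ValueError("one weight per frame required")
    if len(frames) < k:
        raise ValueError(f"need at least k={k} frames")
    idx = np.arange(len(frames))
    if len(frames) > subsample:
        rng = np.random.default_rng(seed)
        p = weights / weights.sum()
        n_pos = int(np.count_nonzero(p))
        idx = np.sort(rng.choice(idx, size=min(subsample, n_pos),
                                 replace=False, p=p))
    used = [frames[i] for i in idx]
    w = weights[idx]
    w = w / w.sum() if w.sum() > 0 else np.full(len(idx), 1.0 / len(idx))

    n = len(used)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = frame_distance(used[i], used[j], mode)
    labels = fcluster(linkage(squareform(dmat, checks=False), method="ward"),
                      t=k, criterion="maxclust")

    cum = np.array([w[labels == c].sum() for c in range(1, k + 1)])
    order = np.argsort(-cum, kind="stable")
    rank_of = {c + 1: r for r, c in enumerate(order)}
    assignments = np.array([rank_of[c] for c in labels])

    reps = np.empty(k, dtype=int)
    for r in range(k):
        members = np.nonzero(assignments == r)[0]
        sub = dmat[np.ix_(members, members)]
        # medoid: min mean squared distance, ties to lowest frame index
        reps[r] = idx[members[int(np.argmin(np.mean(sub ** 2, axis=1)))]]
    return ClusterSet(frame_indices=idx, assignments=assignments,
                      probabilities=cum[order], representatives=reps, k=k)


def rmsf_per_residue(frames: list[Frame], tol: float = 1e-8,
                     max_iter: int = 100) -> np.ndarray:
    """Per-residue Cα RMSF over all chains of all given frames (angstrom).

    Every chain is superposed onto the evolving mean chain; the mean is
    iterated to convergence, then RMSF_j is the root-mean-square deviation
    of residue j over all superposed chains.
    """
    chains = np.concatenate([f.coords for f in frames])  # (M, n_res, 3)
    mean = chains[0].copy()
    for _ in range(max_iter):
        moved = np.stack([_superpose(c, mean) for c in chains])
        new_mean = moved.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    moved = np.stack([_superpose(c, mean) for c in chains])
    dev2 = np.sum((moved - mean) ** 2, axis=2)  # (M, n_res)
    return np.sqrt(dev2.mean(axis=0))
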