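"""Independent reference implementations used as test oracles.

Everything here deliberately re-derives results through a different
algorithmic route than the package (graph library components instead of the
iterative growth procedure, convex optimization instead of self-consistent
iteration, explicit image enumeration instead of nearest-image rounding) so
that agreement is a genuine cross-check.
"""

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from pepagg.constants import KB_KCAL


def brute_force_components(coords: np.ndarray, side: float,
                           cutoff: float = 7.0) -> set[frozenset]:
    """Connected components of the chain-association graph.

    Pair distances minimize explicitly over the 27 periodic images; the
    graph is handed to networkx.
    """
    n_chains = coords.shape[0]
    shifts = side * np.array(list(itertools.product((-1, 0, 1), repeat=3)))
    g = nx.Graph()
    g.add_nodes_from(range(n_chains))
    for i in range(n_chains):
        for j in range(i + 1, n_chains):
            diff = coords[i][:, None, :] - coords[j][None, :, :]
            d = np.linalg.norm(diff[None, :, :, :] + shifts[:, None, None, :],
                               axis=-1)
            if d.min() < cutoff:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def mbar_free_energies(energies: np.ndarray, temp_indices: np.ndarray,
                       temperatures: np.ndarray,
                       kB: float = KB_KCAL) -> np.ndarray:
    """Multistate-reweighting free energies by direct minimization of the
    convex objective  sum_i log sum_k N_k exp(f_k - b_k E_i) - sum_k N_k f_k
    (gauge f_0 = 0), an independent route to the same estimator as the
    self-consistent iteration."""
    betas = 1.0 / (kB * np.asarray(temperatures))
    counts = np.bincount(temp_indices, minlength=len(betas))
    neg_u = -betas[:, None] * energies[None, :]  # (K, N)
    log_counts = np.log(counts)

    def objective(f_tail):
        f = np.concatenate([[0.0], f_tail])
        log_denom = logsumexp(log_counts[:, None] + f[:, None] + neg_u,
                              axis=0)
        value = log_denom.sum() - counts @ f
        resp = np.exp(log_counts[:, None] + f[:, None] + neg_u
                      - log_denom[None, :])
        grad = resp.sum(axis=1) - counts
        return value, grad[1:]

    res = minimize(objective, np.zeros(len(betas) - 1), jac=True,
                   method="BFGS", options={"gtol": 1e-11, "maxiter": 5000})
    return np.concatenate([[0.0], res.x])


def two_level_ensemble(T1: float = 300.0, n_per_temp: int = 100):
    """Two-level system sampled exactly at its Boltzmann proportions.

    The gap eps and the second temperature are chosen so that the level
    occupancies are exactly 3:1 and 4:1, making the empirical counts an
    exact fixed point of the reweighting equations. Returns
    (ensemble, eps).
    """
    from pepagg.ensemble import EnsembleSet, Frame, TemperatureLadder

    eps = KB_KCAL * T1 * np.log(3.0)
    T2 = eps / (KB_KCAL * np.log(4.0))  # below T1
    ladder = TemperatureLadder((T2, T1))
    coords = np.zeros((1, 3, 3))
    frames = []
    step = 0
    for temp_index, upper_frac in ((0, 1 / 5), (1, 1 / 4)):
        n_upper = round(n_per_temp * upper_frac)
        for energy in [0.0] * (n_per_temp - n_upper) + [eps] * n_upper:
            frames.append(Frame(coords=coords, energy=energy,
                                temp_index=temp_index, traj_id=0, step=step))
            step += 1
    return EnsembleSet(frames=frames, ladder=ladder), eps


def two_level_mean_energy(eps: float, T: float) -> float:
    return eps / (1.0 + np.exp(eps / (KB_KCAL * T)))


def reference_rmsf(chains: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Per-residue RMSF by explicit SVD Kabsch superposition onto an
    iterated mean chain (no shared code with the package implementation)."""

    def kabsch(mobile, target):
        mc, tc = mobile.mean(0), target.mean(0)
        h = (mobile - mc).T @ (target - tc)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        return (mobile - mc) @ r.T + tc

    mean = chains[0].copy()
    for _ in range(n_iter):
        moved = np.stack([kabsch(c, mean) for c in chains])
        mean = moved.mean(axis=0)
    moved = np.stack([kabsch(c, mean) for c in chains])
    return np.sqrt(((moved - mean) ** 2).sum(axis=2).mean(axis=0))
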