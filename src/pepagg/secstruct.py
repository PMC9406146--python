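"""Secondary-structure assignment from Cα-trace geometry.

Each residue of each chain is labelled α, β or statistical coil (c) using
local virtual-bond geometry plus a backbone-interaction pattern built from
pseudo-peptide centers (midpoints of consecutive Cα atoms, standing in for
the peptide-group positions of a two-site-per-residue chain model):

* α — the virtual dihedral over Cα(i-1..i+2) lies in the helical band,
  the Cα(i)–Cα(i+3) distance is short, and the flanking pseudo-peptide
  center contacts its i+3 counterpart (the helical hydrogen-bond pattern).
* β — the virtual dihedral is extended AND a flanking pseudo-peptide
  center pairs with a center of another strand segment (inter-chain under
  the minimum image, or intra-chain at sequence separation >= 4) in a
  ladder of at least ``min_ladder`` consecutive rungs. Extended local
  geometry alone is never β.
* c — everything else; residues with undefined dihedrals default to c.

All thresholds are named parameters of :class:`SecStructParams`; the
defaults classify ideal helix/sheet reference geometries correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .ensemble import BoxSpec, EnsembleSet, Frame, min_image_displacement

COIL, ALPHA, BETA = 0, 1, 2
STATE_LETTERS = np.array(["c", "a", "b"])


@dataclass(frozen=True)
class SecStructParams:
    """Thresholds of the geometric assignment (angstrom, degrees)."""

    helix_dihedral_band: tuple = (30.0, 70.0)
    helix_d13_max: float = 6.0          # Cα(i)–Cα(i+3) distance
    helix_contact_max: float = 6.0      # pseudo-peptide center i..i+3 contact
    extended_dihedral_min: float = 120.0  # |dihedral| above this is extended
    hbond_center_max: float = 5.5       # pseudo-peptide H-bond proxy
    min_ladder: int = 2                 # consecutive rungs required for β
    min_chain_length: int = 5           # shorter chains are all coil


DEFAULT_PARAMS = SecStructParams()


@dataclass(frozen=True)
class StateAssignment:
    """Per-chain, per-residue states (codes 0=c, 1=α, 2=β)."""

    states: np.ndarray  # (n_chains, n_residues) int

    @property
    def letters(self) -> np.ndarray:
        return STATE_LETTERS[self.states]

    def fractions(self) -> np.ndarray:
        """Per-chain (f_α, f_β, f_c); rows sum to 1."""
        n_res = self.states.shape[1]
        f_a = (self.states == ALPHA).sum(axis=1) / n_res
        f_b = (self.states == BETA).sum(axis=1) / n_res
        return np.column_stack([f_a, f_b, 1.0 - f_a - f_b])


def _virtual_dihedrals(chain: np.ndarray) -> np.ndarray:
    """Dihedral assigned to residue i from Cα(i-1, i, i+1, i+2); NaN at ends."""
    n = len(chain)
    out = np.full(n, np.nan)
    if n >= 4:
        out[1:n - 2] = np.degrees(
            struc.dihedral(chain[:-3], chain[1:-2], chain[2:-1], chain[3:])
        )
    return out


def assign_states(frame: Frame, box: BoxSpec,
                  params: SecStructParams = DEFAULT_PARAMS) -> StateAssignment:
    n_chains, n_res = frame.n_chains, frame.n_residues
    states = np.zeros((n_chains, n_res), dtype=int)
    if n_res < params.min_chain_length:
        return StateAssignment(states)

    dihedrals = np.array([_virtual_dihedrals(frame.coords[j])
                          for j in range(n_chains)])
    # pseudo-peptide centers, one per virtual bond
    centers = 0.5 * (frame.coords[:, :-1] + frame.coords[:, 1:])
    n_cent = n_res - 1
    flat = centers.reshape(n_chains * n_cent, 3)
    disp = min_image_displacement(flat[:, None, :], flat[None, :, :], box)
    dist = np.linalg.norm(disp, axis=-1).reshape(n_chains, n_cent,
                                                 n_chains, n_cent)

    # rung[j, i, j2, k]: H-bond proxy contact between center i of chain j
    # and center k of chain j2, restricted to genuine strand partners
    rung = dist < params.hbond_center_max
    same = np.eye(n_chains, dtype=bool)
    sep = np.abs(np.arange(n_cent)[:, None] - np.arange(n_cent)[None, :])
    rung[same[:, None, :, None] & (sep < 4)[None, :, None, :]] = False

    # ladder: rung (i,k) supported by a diagonal neighbor rung
    ladder = np.zeros_like(rung)
    r = rung
    support = np.zeros_like(rung)
    support[:, :-1, :, :-1] |= r[:, 1:, :, 1:]   # (i+1, k+1)
    support[:, :-1, :, 1:] |= r[:, 1:, :, :-1]   # (i+1, k-1)
    support[:, 1:, :, :-1] |= r[:, :-1, :, 1:]   # (i-1, k+1)
    support[:, 1:, :, 1:] |= r[:, :-1, :, :-1]   # (i-1, k-1)
    ladder = rung & support
    center_in_ladder = ladder.any(axis=(2, 3))   # (n_chains, n_cent)

    lo, hi = params.helix_dihedral_band
    for j in range(n_chains):
        chain = frame.coords[j]
        for i in range(n_res):
            g = dihedrals[j, i]
            if not np.isfinite(g):
                continue
            if lo <= g <= hi:
                # helical local geometry; check i,i+3 compactness + contact
                if i + 3 < n_res and np.linalg.norm(
                        chain[i + 3] - chain[i]) < params.helix_d13_max:
                    if i + 3 < n_cent and np.linalg.norm(
                            centers[j, i + 3] - centers[j, i]
                    ) < params.helix_contact_max:
                        states[j, i] = ALPHA
            elif abs(g) >= params.extended_dihedral_min:
                # extended; β only with a laddered H-bond-proxy partner
                flanks = [c for c in (i - 1, i) if 0 <= c < n_cent]
                if any(center_in_ladder[j, c] for c in flanks):
                    states[j, i] = BETA
    return StateAssignment(states)


def state_fractions(assignment: StateAssignment) -> np.ndarray:
    """Per-chain (f_α, f_β, f_c) fractions."""
    return assignment.fractions()


def frame_state_fractions(ensemble: EnsembleSet,
                          params: SecStructParams = DEFAULT_PARAMS) -> np.ndarray:
    """Chain-averaged (f_α, f_β, f_c) per frame, shape (n_frames, 3).

    These per-snapshot values are what the multi-temperature reweighting
    averages into secondary-structure melting profiles.
    """
    out = np.empty((len(ensemble), 3))
    for i, frame in enumerate(ensemble.frames):
        out[i] = assign_states(frame, ensemble.box, params).fractions().mean(axis=0)
    return out
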