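"""File I/O for ensembles.

Coordinates travel as multi-model PDB (one MODEL per frame, Cα records only,
chains labelled A, B, C, ...), metadata as a TSV with columns
``frame_index traj_id step temp_index energy`` (frame_index is 0-based), and
the ladder/box/system description as a small YAML config. A call to
:func:`write_ensemble` with prefix ``p`` produces ``p.pdb``, ``p.meta.tsv``
and ``p.config.yaml``; :func:`read_ensemble` reverses it.
"""

from __future__ import annotations

import string
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .ensemble import BoxSpec, EnsembleSet, Frame, TemperatureLadder
from .errors import EnsembleFormatError

_META_COLUMNS = ["frame_index", "traj_id", "step", "temp_index", "energy"]
_CHAIN_IDS = string.ascii_uppercase


def _stack_from_frames(frames: list[Frame]) -> struc.AtomArrayStack:
    n_chains = frames[0].n_chains
    n_res = frames[0].n_residues
    n_atoms = n_chains * n_res
    template = struc.AtomArray(n_atoms)
    template.chain_id = np.repeat(list(_CHAIN_IDS[:n_chains]), n_res)
    template.res_id = np.tile(np.arange(1, n_res + 1), n_chains)
    template.res_name = np.full(n_atoms, "ALA")
    template.atom_name = np.full(n_atoms, "CA")
    template.element = np.full(n_atoms, "C")
    coords = np.stack([f.coords.reshape(n_atoms, 3) for f in frames])
    return struc.from_template(template, coords)


def write_ensemble(ensemble: EnsembleSet, prefix: str | Path) -> dict[str, Path]:
    """Write coordinates, metadata and config; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "coords": prefix.with_suffix(".pdb"),
        "meta": prefix.parent / (prefix.name + ".meta.tsv"),
        "config": prefix.parent / (prefix.name + ".config.yaml"),
    }
    pdb = PDBFile()
    pdb.set_structure(_stack_from_frames(ensemble.frames))
    pdb.write(str(paths["coords"]))

    meta = pd.DataFrame(
        {
            "frame_index": np.arange(len(ensemble)),
            "traj_id": ensemble.traj_ids(),
            "step": [f.step for f in ensemble.frames],
            "temp_index": ensemble.temp_indices,
            "energy": ensemble.energies,
        }
    )
    with open(paths["meta"], "w") as fh:
        fh.write("# frame_index is 0-based; energy unit: %s\n" % ensemble.energy_unit)
        meta.to_csv(fh, sep="\t", index=False)

    config = {
        "temperatures_K": list(ensemble.ladder.temperatures),
        "box_side_A": ensemble.box.side,
        "periodic": ensemble.box.periodic,
        "energy_unit": ensemble.energy_unit,
        "n_chains": ensemble.n_chains,
        "residues_per_chain": ensemble.residues_per_chain,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh)
    return paths


def read_ensemble(coord_path: str | Path, meta_path: str | Path | None = None,
                  config_path: str | Path | None = None) -> EnsembleSet:
    """Read an ensemble written by :func:`write_ensemble`.

    ``meta_path``/``config_path`` default to the sibling files implied by
    the coordinate path.
    """
    coord_path = Path(coord_path)
    stem = coord_path.parent / coord_path.stem
    meta_path = Path(meta_path) if meta_path else Path(str(stem) + ".meta.tsv")
    config_path = (Path(config_path) if config_path
                   else Path(str(stem) + ".config.yaml"))

    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    ladder = TemperatureLadder(tuple(config["temperatures_K"]))
    box = BoxSpec(float(config["box_side_A"]), bool(config.get("periodic", True)))
    n_chains = int(config["n_chains"])
    n_res = int(config["residues_per_chain"])

    stack = PDBFile.read(str(coord_path)).get_structure()
    ca = stack[:, stack.atom_name == "CA"]
    n_models, n_atoms = ca.coord.shape[:2]
    if n_atoms != n_chains * n_res:
        raise EnsembleFormatError(
            f"expected {n_chains * n_res} CA atoms per model, found {n_atoms}"
        )

    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    missing = set(_META_COLUMNS) - set(meta.columns)
    if missing:
        raise EnsembleFormatError(f"metadata missing column(s) {sorted(missing)}")
    if len(meta) != n_models:
        raise EnsembleFormatError(
            f"{n_models} models but {len(meta)} metadata rows"
        )
    meta = meta.sort_values("frame_index")
    if not np.array_equal(meta["frame_index"].to_numpy(), np.arange(n_models)):
        raise EnsembleFormatError("frame_index must enumerate 0..n_frames-1")
    if not np.all(np.isfinite(meta["energy"].to_numpy(dtype=float))):
        raise EnsembleFormatError("non-finite energy in metadata")
    temp_idx = meta["temp_index"].to_numpy(dtype=int)
    if temp_idx.min() < 0 or temp_idx.max() >= len(ladder):
        raise EnsembleFormatError(
            f"temp_index outside valid range 0..{len(ladder) - 1}"
        )

    frames = [
        Frame(
            coords=ca.coord[i].reshape(n_chains, n_res, 3),
            energy=float(meta["energy"].iloc[i]),
            temp_index=int(temp_idx[i]),
            traj_id=int(meta["traj_id"].iloc[i]),
            step=int(meta["step"].iloc[i]),
        )
        for i in range(n_models)
    ]
    return EnsembleSet(frames=frames, ladder=ladder, box=box,
                       energy_unit=str(config.get("energy_unit", "kcal/mol")))
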