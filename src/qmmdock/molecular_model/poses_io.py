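"""Pose ensemble output: multi-record SDF (ligand) and multi-model PDB
(complex), with scores embedded as SDF tags / PDB REMARKs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from rdkit import Chem

from qmmdock.errors import QmmdockError
from qmmdock.molecular_model import ligand_io, pdb
from qmmdock.molecular_model.types import MolecularSystem

PathLike = Union[str, Path]


def _pose_tags(pose) -> dict:
    tags = {}
    for key in ("score_class", "score_qmmm", "rmsd_to_native"):
        value = getattr(pose, key, None)
        if value is not None:
            tags[key] = f"{value:.6f}"
    prov = getattr(pose, "provenance", None)
    if prov is not None:
        tags["provenance"] = prov
    conv = getattr(pose, "converged", None)
    if conv is not None:
        tags["converged"] = str(bool(conv))
    return tags


def write_poses(
    poses: Sequence,
    system: MolecularSystem,
    sdf_path: Optional[PathLike] = None,
    pdb_path: Optional[PathLike] = None,
) -> None:
    """Write a pose ensemble sharing one ligand topology.

    Each pose must expose ``coords`` (coordinates of its movable atoms)
    and ``movable`` (their indices in ``system``). SDF records contain
    the ligand only; the PDB contains the whole complex, one MODEL per
    pose.
    """
    if sdf_path is None and pdb_path is None:
        raise QmmdockError("write_poses: no output path given")
    movables = {tuple(getattr(p, "movable")) for p in poses}
    if len(movables) > 1:
        raise QmmdockError("write_poses: poses have heterogeneous topologies")

    lig_idx = system.ligand_idx
    posed_systems: list[MolecularSystem] = []
    for pose in poses:
        s = system.copy()
        coords = s.coords
        coords[list(pose.movable)] = np.asarray(pose.coords, dtype=float)
        s.set_coords(coords)
        posed_systems.append(s)

    if sdf_path is not None:
        tags = [_pose_tags(p) for p in poses]
        if posed_systems:
            ligand_io.write_sdf(posed_systems, sdf_path, subset=lig_idx, tags=tags)
        else:
            Path(sdf_path).write_text("")
    if pdb_path is not None:
        if posed_systems:
            remarks = [
                [f"{k} = {v}" for k, v in _pose_tags(p).items()] for p in poses
            ]
            pdb.write_pdb(posed_systems, pdb_path, remarks=remarks)
        else:
            Path(pdb_path).write_text("END\n")


def read_pose_coords(sdf_path: PathLike) -> list[tuple[np.ndarray, dict]]:
    """Read back pose ligand coordinates and tags from a multi-record SDF."""
    out = []
    supplier = Chem.SDMolSupplier(str(sdf_path), removeHs=False, sanitize=False)
    for mol in supplier:
        if mol is None:
            raise QmmdockError(f"{sdf_path}: unparsable pose record")
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        tags = {name: mol.GetProp(name) for name in mol.GetPropNames()}
        out.append((coords, tags))
    return out
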