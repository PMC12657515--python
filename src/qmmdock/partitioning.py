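"""Primary/secondary system selection, link atoms, embedding charges.

The primary system (PS) is treated quantum-mechanically in the field of
scaled secondary-system (SS) point charges (electrostatic embedding).
A bond crossing the boundary is capped with a hydrogen link atom placed
along the cut bond; the first classical neighbor's embedding charge is
zeroed. Selection modes:

``lig``
    The ligand; for covalent complexes the bound protein residue is
    added automatically (side chain only when ``sidechain_only``).
``lig+MB``
    Additionally every metal within ``metal_cutoff`` of a ligand heavy
    atom, plus its coordinating residues.
``lig+BoxN+MB``
    Additionally every residue/cofactor with at least one atom inside a
    cubic box of edge ``box_edge`` centered on the sampling-box center
    (ligand centroid by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from qmmdock import constants
from qmmdock.errors import ConfigError, TopologyError
from qmmdock.molecular_model.types import Atom, MolecularSystem, pairwise_distances

logger = logging.getLogger(__name__)

MODES = ("lig", "lig+SC", "lig+MB", "lig+BoxN+MB")

_BACKBONE_NAMES = {"N", "CA", "C", "O", "HN", "HA", "H"}


@dataclass
class LinkAtom:
    """Hydrogen cap on a cut bond: no classical charge, no LJ."""

    qm_host: int
    mm_neighbor: int
    position: np.ndarray
    length: float = constants.LINK_LENGTH

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class Partition:
    ps_atoms: set[int] = field(default_factory=set)
    ss_atoms: set[int] = field(default_factory=set)
    cut_bonds: list[tuple[int, int]] = field(default_factory=list)  # (ps, ss)
    link_atoms: list[LinkAtom] = field(default_factory=list)
    embedding_charges: list[tuple[np.ndarray, float]] = field(default_factory=list)
    embedding_scale: float = 1.0
    ps_net_charge: int = 0
    ps_multiplicity: int = 1
    zeroed_neighbors: set[int] = field(default_factory=set)

    def validate(self, n_atoms: int) -> None:
        if self.ps_atoms & self.ss_atoms:
            raise TopologyError("PS and SS atom sets overlap")
        if self.ps_atoms | self.ss_atoms != set(range(n_atoms)):
            raise TopologyError("PS and SS do not cover all atoms")
        if self.link_atoms and len(self.link_atoms) != len(self.cut_bonds):
            raise TopologyError("one link atom required per cut bond")

    def embedding_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.embedding_charges:
            return np.zeros((0, 3)), np.zeros(0)
        pos = np.array([p for p, _ in self.embedding_charges])
        q = np.array([c for _, c in self.embedding_charges])
        return pos, q


# ----------------------------------------------------------------------
# selection


def select_primary_system(
    system: MolecularSystem,
    mode: str = "lig",
    box_edge: Optional[float] = None,
    sidechain_only: bool = True,
    metal_cutoff: float = constants.METAL_CUTOFF,
    coordination_cutoff: float = constants.COORDINATION_CUTOFF,
    box_center: Optional[np.ndarray] = None,
) -> Partition:
    """Choose the PS atom set and record the boundary (cut) bonds.

    ``lig+SC`` is an alias of ``lig`` (the covalently bound side chain
    is always added automatically for covalent systems).
    """
    if mode not in MODES:
        raise ConfigError(f"unknown PS mode {mode!r}; expected one of {MODES}")
    if mode == "lig+BoxN+MB" and box_edge is None:
        raise ConfigError("PS mode lig+BoxN+MB requires box_edge")

    ps: set[int] = set(system.ligand_idx)
    include_backbone = mode == "lig+BoxN+MB" and not sidechain_only

    # covalent: the protein binding residue joins the PS automatically
    if system.covalent_link is not None:
        lig_at, rec_at = system.covalent_link
        ps |= _residue_selection(
            system, system.atoms[rec_at].residue_id, sidechain_only=sidechain_only
        )

    if mode in ("lig+MB", "lig+BoxN+MB"):
        lig_heavy = system.heavy_idx(system.ligand_idx)
        coords = system.coords
        for m in sorted(system.metals):
            if not lig_heavy:
                break
            dmin = float(
                np.min(np.linalg.norm(coords[lig_heavy] - coords[m], axis=1))
            )
            if dmin <= metal_cutoff:
                ps.add(m)
                for rid in _coordinating_residues(system, m, coordination_cutoff):
                    ps |= _residue_selection(system, rid, sidechain_only=sidechain_only)

    if mode == "lig+BoxN+MB":
        center = (
            np.mean(system.coords[system.heavy_idx(system.ligand_idx)], axis=0)
            if box_center is None
            else np.asarray(box_center, dtype=float)
        )
        half = box_edge / 2.0
        coords = system.coords
        for rid in system.residues():
            idxs = system.residue_atoms(rid)
            if all(system.atoms[i].is_ligand for i in idxs):
                continue
            inside = np.all(np.abs(coords[idxs] - center) <= half, axis=1)
            if np.any(inside):
                ps |= _residue_selection(
                    system, rid, sidechain_only=not include_backbone
                )

    part = Partition(
        ps_atoms=ps,
        ss_atoms=set(range(system.n_atoms)) - ps,
        ps_multiplicity=system.multiplicity,
    )
    part.cut_bonds = _find_cut_bonds(system, ps)
    part.ps_net_charge = int(round(sum(system.atoms[i].charge for i in ps)))
    part.validate(system.n_atoms)
    return part


def _residue_selection(
    system: MolecularSystem, residue_id: str, sidechain_only: bool
) -> set[int]:
    idxs = system.residue_atoms(residue_id)
    if not sidechain_only:
        return set(idxs)
    side = {
        i
        for i in idxs
        if system.atoms[i].atom_name.upper() not in _BACKBONE_NAMES
    }
    if not side:
        logger.warning(
            "residue %s has no side chain atoms (Gly?); skipped in "
            "sidechain-only PS selection",
            residue_id,
        )
    return side


def _coordinating_residues(
    system: MolecularSystem, metal: int, cutoff: float
) -> list[str]:
    coords = system.coords
    out: list[str] = []
    for rid in system.residues():
        idxs = [
            i
            for i in system.residue_atoms(rid)
            if not system.atoms[i].is_ligand
            and i != metal
            and system.atoms[i].element.upper() != "H"
        ]
        if not idxs:
            continue
        dmin = float(np.min(np.linalg.norm(coords[idxs] - coords[metal], axis=1)))
        if dmin <= cutoff:
            out.append(rid)
    return out


def _find_cut_bonds(system: MolecularSystem, ps: set[int]) -> list[tuple[int, int]]:
    cut = []
    for b in system.bonds:
        if (b.i in ps) != (b.j in ps):
            qm, mm = (b.i, b.j) if b.i in ps else (b.j, b.i)
            cut.append((qm, mm))
    return cut


# ----------------------------------------------------------------------
# link atoms and embedding


def build_link_atoms(
    partition: Partition,
    system: MolecularSystem,
    link_length: float = constants.LINK_LENGTH,
) -> Partition:
    """Place one hydrogen link atom per cut bond, collinear with it."""
    # a ring cut leaves two boundary bonds within one cycle: unsupported
    cut_pairs = {frozenset(c) for c in partition.cut_bonds}
    if len(cut_pairs) >= 2:
        g = system.bond_graph()
        for cycle in nx.cycle_basis(g):
            edges = {
                frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))
                for k in range(len(cycle))
            }
            if len(edges & cut_pairs) >= 2:
                raise TopologyError(
                    "PS/SS boundary cuts a ring twice; choose a different PS"
                )
    coords = system.coords
    partition.link_atoms = []
    for qm, mm in partition.cut_bonds:
        direction = coords[mm] - coords[qm]
        norm = float(np.linalg.norm(direction))
        if norm < 1e-9:
            raise TopologyError(f"cut bond {qm}-{mm} has zero length")
        pos = coords[qm] + link_length * direction / norm
        partition.link_atoms.append(
            LinkAtom(qm_host=qm, mm_neighbor=mm, position=pos, length=link_length)
        )
    partition.zeroed_neighbors = {mm for _, mm in partition.cut_bonds}
    return partition


def embedding_charges(
    partition: Partition,
    system: MolecularSystem,
    scale: float = constants.EMBEDDING_SCALE,
) -> Partition:
    """SS point charges scaled by ``scale``; boundary neighbors zeroed.

    Zeroed charge is not redistributed, so the embedding set may carry a
    non-integer total charge.
    """
    if not 0.0 < scale <= 1.0:
        raise ConfigError("embedding scale must be in (0, 1]")
    coords = system.coords
    charges = []
    for i in sorted(partition.ss_atoms):
        q = 0.0 if i in partition.zeroed_neighbors else scale * system.atoms[i].charge
        charges.append((coords[i].copy(), q))
    partition.embedding_charges = charges
    partition.embedding_scale = scale
    return partition


def make_partition(
    system: MolecularSystem,
    mode: str = "lig",
    box_edge: Optional[float] = None,
    sidechain_only: bool = True,
    link_length: float = constants.LINK_LENGTH,
    scale: float = constants.EMBEDDING_SCALE,
    metal_cutoff: float = constants.METAL_CUTOFF,
    coordination_cutoff: float = constants.COORDINATION_CUTOFF,
    box_center: Optional[np.ndarray] = None,
) -> Partition:
    """Select, cap and charge a partition in one call."""
    part = select_primary_system(
        system,
        mode=mode,
        box_edge=box_edge,
        sidechain_only=sidechain_only,
        metal_cutoff=metal_cutoff,
        coordination_cutoff=coordination_cutoff,
        box_center=box_center,
    )
    build_link_atoms(part, system, link_length=link_length)
    embedding_charges(part, system, scale=scale)
    return part


def refresh_geometry(partition: Partition, system: MolecularSystem) -> Partition:
    """Re-place link atoms and embedding positions after coordinates moved."""
    coords = system.coords
    for link in partition.link_atoms:
        direction = coords[link.mm_neighbor] - coords[link.qm_host]
        norm = float(np.linalg.norm(direction))
        link.position = coords[link.qm_host] + link.length * direction / norm
    new_charges = []
    ss_sorted = sorted(partition.ss_atoms)
    for i, (_, q) in zip(ss_sorted, partition.embedding_charges):
        new_charges.append((coords[i].copy(), q))
    partition.embedding_charges = new_charges
    return partition


# ----------------------------------------------------------------------
# PS geometry handed to QM engines


@dataclass
class PSGeometry:
    """The capped primary system as a standalone sub-system.

    ``subsystem`` holds PS atoms (original parameters) followed by link
    atoms (element H, no charge, no LJ); ``n_real`` counts the PS atoms,
    ``index_map`` maps local to parent-system indices.
    """

    subsystem: MolecularSystem
    n_real: int
    index_map: list[int]

    @property
    def coords(self) -> np.ndarray:
        return self.subsystem.coords


def extract_ps_geometry(system: MolecularSystem, partition: Partition) -> PSGeometry:
    idxs = sorted(partition.ps_atoms)
    remap = {old: new for new, old in enumerate(idxs)}
    sub = MolecularSystem(multiplicity=partition.ps_multiplicity)
    for old in idxs:
        a = system.atoms[old].copy()
        a.index = remap[old]
        sub.atoms.append(a)
    for b in system.bonds:
        if b.i in remap and b.j in remap:
            sub.bonds.append(replace(b, i=remap[b.i], j=remap[b.j]))
    for a in system.angles:
        if {a.i, a.j, a.k} <= set(remap):
            sub.angles.append(replace(a, i=remap[a.i], j=remap[a.j], k=remap[a.k]))
    for t in system.torsions:
        if {t.i, t.j, t.k, t.l} <= set(remap):
            sub.torsions.append(
                replace(t, i=remap[t.i], j=remap[t.j], k=remap[t.k], l=remap[t.l])
            )
    sub.metals = {remap[m] for m in system.metals if m in remap}
    n_real = len(sub.atoms)
    for k, link in enumerate(partition.link_atoms):
        sub.atoms.append(
            Atom(
                index=n_real + k,
                element="H",
                coords=link.position.copy(),
                atom_name=f"HL{k + 1}",
                residue_name="LNK",
                residue_id="X:999",
                charge=0.0,
                lj_epsilon=0.0,
                lj_rmin_half=0.0,
            )
        )
    sub.net_charge = partition.ps_net_charge
    return PSGeometry(subsystem=sub, n_real=n_real, index_map=idxs)
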