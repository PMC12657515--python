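"""Core molecular data model.

All coordinates are Angstrom, charges elementary charges, energies
kcal/mol. Atom indices are 0-based; residue numbering is 1-based as in
PDB, with residue ids spelled ``"<chain>:<number>"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from qmmdock.errors import QmmdockError


@dataclass
class Atom:
    """One atom with its classical parameters.

    ``lj_epsilon``/``lj_rmin_half`` use the CHARMM Rmin convention:
    the pair minimum sits at ``rmin_half_i + rmin_half_j``.
    """

    index: int
    element: str
    coords: np.ndarray
    atom_name: str
    residue_name: str
    residue_id: str
    charge: float = 0.0
    lj_epsilon: Optional[float] = None
    lj_rmin_half: Optional[float] = None
    is_ligand: bool = False
    b_factor: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise QmmdockError(f"atom {self.index} has non-finite coordinates")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise QmmdockError(f"atom {self.index}: lj_epsilon must be >= 0")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class BondTerm:
    i: int
    j: int
    force_k: Optional[float] = None  # kcal/mol/A^2
    r0: Optional[float] = None  # A
    order: float = 1.0


@dataclass
class AngleTerm:
    i: int
    j: int
    k: int  # j is the apex
    force_k: Optional[float] = None  # kcal/mol/rad^2
    theta0: Optional[float] = None  # degrees


@dataclass
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    force_k: Optional[float] = None  # kcal/mol
    periodicity: int = 3
    phase: float = 0.0  # degrees


@dataclass
class MolecularSystem:
    """A receptor, a ligand, or a full complex."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsions: list[TorsionTerm] = field(default_factory=list)
    metals: set[int] = field(default_factory=set)
    covalent_link: Optional[tuple[int, int]] = None  # (ligand atom, receptor atom)
    net_charge: Optional[int] = None
    multiplicity: int = 1

    # ------------------------------------------------------------------
    # coordinates
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise QmmdockError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz.copy()

    # ------------------------------------------------------------------
    # selections
    @property
    def ligand_idx(self) -> list[int]:
        return [a.index for a in self.atoms if a.is_ligand]

    @property
    def receptor_idx(self) -> list[int]:
        return [a.index for a in self.atoms if not a.is_ligand]

    def heavy_idx(self, subset: Optional[Iterable[int]] = None) -> list[int]:
        pool = range(self.n_atoms) if subset is None else subset
        return [i for i in pool if self.atoms[i].element.upper() != "H"]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def residue_atoms(self, residue_id: str) -> list[int]:
        return [a.index for a in self.atoms if a.residue_id == residue_id]

    def residues(self) -> list[str]:
        """Residue ids in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    # ------------------------------------------------------------------
    # topology
    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order)
        return g

    def validate(self, check_charges: bool = False) -> None:
        """Enforce the structural invariants of the data model."""
        n = self.n_atoms
        for b in self.bonds:
            if b.i == b.j:
                raise QmmdockError(f"bond ({b.i}, {b.j}) joins an atom to itself")
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise QmmdockError(f"bond ({b.i}, {b.j}) out of range")
        lig = set(self.ligand_idx)
        if lig:
            g = self.bond_graph().subgraph(lig)
            if nx.number_connected_components(g) != 1:
                raise QmmdockError("ligand atoms do not form one bonded component")
        if check_charges and self.net_charge is not None:
            total = float(np.sum(self.charges))
            if abs(total - self.net_charge) > 0.01:
                raise QmmdockError(
                    f"sum of partial charges {total:.4f} deviates from declared "
                    f"net charge {self.net_charge} by more than 0.01 e"
                )

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            atoms=[a.copy() for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            angles=[replace(a) for a in self.angles],
            torsions=[replace(t) for t in self.torsions],
            metals=set(self.metals),
            covalent_link=self.covalent_link,
            net_charge=self.net_charge,
            multiplicity=self.multiplicity,
        )

    def merged_with(self, other: "MolecularSystem") -> "MolecularSystem":
        """Concatenate two systems (receptor + ligand -> complex)."""
        out = self.copy()
        off = out.n_atoms
        for a in other.atoms:
            b = a.copy()
            b.index = a.index + off
            out.atoms.append(b)
        for b in other.bonds:
            out.bonds.append(replace(b, i=b.i + off, j=b.j + off))
        for a in other.angles:
            out.angles.append(replace(a, i=a.i + off, j=a.j + off, k=a.k + off))
        for t in other.torsions:
            out.torsions.append(
                replace(t, i=t.i + off, j=t.j + off, k=t.k + off, l=t.l + off)
            )
        out.metals |= {m + off for m in other.metals}
        if other.covalent_link is not None:
            out.covalent_link = tuple(x + off for x in other.covalent_link)
        if self.net_charge is not None and other.net_charge is not None:
            out.net_charge = self.net_charge + other.net_charge
        return out


@dataclass
class BenchmarkRecord:
    """Per-complex structure-quality metadata, consumed by the curation stack."""

    complex_id: str
    resolution: float  # A
    dpi: float  # A
    ligand_b_factor_avg: float  # A^2
    ediam: float
    mw: float  # Da
    n_rotatable_bonds: int
    ghose_pass_count: int
    lipinski_pass_count: int
    has_missing_atoms: bool
    has_altlocs: bool
    min_crystal_contact: float  # A

    NUMERIC_FIELDS = (
        "resolution",
        "dpi",
        "ligand_b_factor_avg",
        "ediam",
        "mw",
        "n_rotatable_bonds",
        "ghose_pass_count",
        "lipinski_pass_count",
        "min_crystal_contact",
    )

    def __post_init__(self) -> None:
        for name in self.NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise QmmdockError(f"{self.complex_id}: field {name} is negative")


def pairwise_distances(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between two coordinate sets."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def plain_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD without superposition (receptor-frame convention)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise QmmdockError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def guess_element(atom_name: str, residue_name: str = "") -> str:
    """Element from a PDB atom name when columns 77-78 are blank."""
    name = atom_name.strip()
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise QmmdockError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    from qmmdock.constants import METAL_ELEMENTS

    res = residue_name.strip().upper()
    # only trust a two-letter metal when the residue is the ion itself
    # (ZN/ZN) or a known metal-bearing cofactor (HEM/FE)
    if two in METAL_ELEMENTS and (res == two or res in ("ZNM",) or (res == "HEM" and two == "FE")):
        return two.capitalize()
    return stripped[0].upper()


_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
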