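"""Ligand I/O: SDF (V2000, via RDKit) and MOL2 (SYBYL, minimal native parser).

RDKit has no MOL2 writer, so both MOL2 directions are implemented here
against the plain SYBYL dialect we emit; bond orders are preserved for
automorphism detection downstream.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from qmmdock.errors import EmptyInputError, FormatError
from qmmdock.molecular_model.types import Atom, BondTerm, MolecularSystem

RDLogger.DisableLog("rdApp.*")

PathLike = Union[str, Path]

_SYBYL_ORDER = {"1": 1.0, "2": 2.0, "3": 3.0, "ar": 1.5, "am": 1.0, "du": 1.0}
_ORDER_SYBYL = {1.0: "1", 2.0: "2", 3.0: "3", 1.5: "ar"}


def read_ligand(path: PathLike) -> MolecularSystem:
    """Read a ligand from SDF or MOL2 (chosen by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".mol", ".sd"):
        mols = list(read_sdf_multi(path))
        if not mols:
            raise EmptyInputError(f"{path}: no molecule records")
        return mols[0]
    if suffix == ".mol2":
        return _read_mol2(path)
    raise FormatError(f"{path}: unsupported ligand format {suffix!r}")


def read_sdf_multi(path: PathLike) -> list[MolecularSystem]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    systems = []
    for mol in supplier:
        if mol is None:
            raise FormatError(f"{path}: unparsable SDF record")
        systems.append(mol_to_system(mol, source=str(path)))
    return systems


def mol_to_system(mol: Chem.Mol, source: str = "<mol>") -> MolecularSystem:
    if mol.GetNumAtoms() == 0:
        raise EmptyInputError(f"{source}: molecule with zero atoms")
    if mol.GetNumBonds() == 0 and mol.GetNumAtoms() > 1:
        raise FormatError(f"{source}: connection table has no bonds")
    conf = mol.GetConformer()
    sys_ = MolecularSystem()
    for i, rd_atom in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        sys_.atoms.append(
            Atom(
                index=i,
                element=rd_atom.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                atom_name=f"{rd_atom.GetSymbol().upper()}{i + 1}",
                residue_name="LIG",
                residue_id="L:1",
                is_ligand=True,
            )
        )
    for bond in mol.GetBonds():
        sys_.bonds.append(
            BondTerm(
                i=bond.GetBeginAtomIdx(),
                j=bond.GetEndAtomIdx(),
                order=float(bond.GetBondTypeAsDouble()),
            )
        )
    sys_.net_charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    return sys_


def system_to_mol(system: MolecularSystem, subset: Optional[list[int]] = None) -> Chem.Mol:
    """Build an RDKit molecule (no sanitization) from a system subset."""
    idxs = list(range(system.n_atoms)) if subset is None else list(subset)
    remap = {old: new for new, old in enumerate(idxs)}
    mol = Chem.RWMol()
    for old in idxs:
        a = system.atoms[old]
        rd_atom = Chem.Atom(a.element.capitalize())
        rd_atom.SetNoImplicit(True)
        mol.AddAtom(rd_atom)
    order_map = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for b in system.bonds:
        if b.i in remap and b.j in remap:
            mol.AddBond(remap[b.i], remap[b.j], order_map.get(b.order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(idxs))
    for old in idxs:
        xyz = system.atoms[old].coords
        conf.SetAtomPosition(remap[old], Point3D(*[float(v) for v in xyz]))
    out = mol.GetMol()
    out.AddConformer(conf)
    if system.net_charge:
        # park the net formal charge on the first atom: the data model
        # tracks per-molecule, not per-atom, formal charge
        out.GetAtomWithIdx(0).SetFormalCharge(int(system.net_charge))
    return out


def write_sdf(
    systems: Union[MolecularSystem, list[MolecularSystem]],
    path: PathLike,
    subset: Optional[list[int]] = None,
    tags: Optional[list[dict]] = None,
) -> None:
    """Write one or more ligands as a multi-record SDF with optional tags."""
    if isinstance(systems, MolecularSystem):
        systems = [systems]
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for k, sys_ in enumerate(systems):
            mol = system_to_mol(sys_, subset=subset)
            mol.SetProp("_Name", f"record_{k}")
            if tags is not None and k < len(tags):
                for key, value in tags[k].items():
                    mol.SetProp(str(key), str(value))
            writer.write(mol)
    finally:
        writer.close()


# ----------------------------------------------------------------------
# MOL2


def _read_mol2(path: Path) -> MolecularSystem:
    lines = Path(path).read_text().splitlines()
    section = None
    atoms: list[tuple] = []
    bonds: list[tuple] = []
    net_charge = 0.0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:].upper()
            continue
        if not line or line.startswith("#"):
            continue
        if section == "ATOM":
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: short ATOM line")
            atoms.append(
                (
                    parts[1],
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    parts[5],
                    float(parts[8]) if len(parts) > 8 else 0.0,
                )
            )
        elif section == "BOND":
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: short BOND line")
            bonds.append((int(parts[1]) - 1, int(parts[2]) - 1, parts[3].lower()))
    if not atoms:
        raise EmptyInputError(f"{path}: no ATOM section")
    if not bonds and len(atoms) > 1:
        raise FormatError(f"{path}: missing BOND section")
    sys_ = MolecularSystem()
    for i, (name, x, y, z, sybyl, charge) in enumerate(atoms):
        element = sybyl.split(".")[0].capitalize()
        sys_.atoms.append(
            Atom(
                index=i,
                element=element,
                coords=np.array([x, y, z]),
                atom_name=name,
                residue_name="LIG",
                residue_id="L:1",
                charge=charge,
                is_ligand=True,
            )
        )
        net_charge += charge
    for i, j, kind in bonds:
        if kind not in _SYBYL_ORDER:
            raise FormatError(f"{path}: unknown bond type {kind!r}")
        sys_.bonds.append(BondTerm(i=i, j=j, order=_SYBYL_ORDER[kind]))
    sys_.net_charge = int(round(net_charge))
    return sys_


def write_mol2(system: MolecularSystem, path: PathLike, name: str = "LIG") -> None:
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{system.n_atoms:5d} {len(system.bonds):5d}     1",
        "SMALL",
        "USER_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for a in system.atoms:
        lines.append(
            f"{a.index + 1:>7} {a.atom_name:<8} "
            f"{a.coords[0]:>9.4f} {a.coords[1]:>9.4f} {a.coords[2]:>9.4f} "
            f"{a.element.capitalize():<5} 1 {a.residue_name:<4} {a.charge:>9.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for k, b in enumerate(system.bonds, start=1):
        kind = _ORDER_SYBYL.get(b.order, "1")
        lines.append(f"{k:>6} {b.i + 1:>5} {b.j + 1:>5} {kind:>4}")
    Path(path).write_text("\n".join(lines) + "\n")
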