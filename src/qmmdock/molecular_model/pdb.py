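"""PDB v3.3 reading and writing.

Only ATOM/HETATM/MODEL/ENDMDL/CONECT/TER/END records are interpreted.
Bond perception is deterministic: residue templates for amino acids,
water and the heme core, peptide bonds between consecutive residues of
one chain, and CONECT records for everything else. Insertion codes are
rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from qmmdock.constants import METAL_ELEMENTS
from qmmdock.errors import EmptyInputError, FormatError
from qmmdock.molecular_model import templates
from qmmdock.molecular_model.types import (
    Atom,
    BondTerm,
    MolecularSystem,
    guess_element,
)

PathLike = Union[str, Path]


def read_receptor(
    path: PathLike, model: Optional[int] = None
) -> Union[MolecularSystem, list[MolecularSystem]]:
    """Read a receptor (or complex) PDB file.

    Single-model files return one :class:`MolecularSystem`. Files with
    several MODEL blocks return a list, one system per model, unless
    ``model`` selects a specific 1-based model number.
    """
    blocks = _parse_models(Path(path))
    systems = [_build_system(atoms, conect) for atoms, conect in blocks]
    if not systems or all(s.n_atoms == 0 for s in systems):
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    if model is not None:
        if not (1 <= model <= len(systems)):
            raise FormatError(f"{path}: model {model} not present")
        return systems[model - 1]
    if len(systems) == 1:
        return systems[0]
    return systems


# ----------------------------------------------------------------------
# parsing


def _parse_models(path: Path):
    lines = path.read_text().splitlines()
    models: list[tuple[list[dict], list[tuple[int, int]]]] = []
    current_atoms: list[dict] = []
    conect: list[tuple[int, int]] = []
    in_model = False
    seen_model_kw = False

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            seen_model_kw = True
            in_model = True
            current_atoms = []
        elif rec == "ENDMDL":
            in_model = False
            models.append((current_atoms, conect))
            current_atoms = []
        elif rec in ("ATOM", "HETATM"):
            current_atoms.append(_parse_atom_line(line, lineno, path))
        elif rec == "CONECT":
            try:
                serials = [int(line[6:11])] + [
                    int(line[s : s + 5])
                    for s in (11, 16, 21, 26)
                    if line[s : s + 5].strip()
                ]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad CONECT record") from exc
            for other in serials[1:]:
                conect.append((serials[0], other))
        elif rec in ("TER", "END", "REMARK", "HEADER", "TITLE", "CRYST1", "SEQRES",
                     "COMPND", "SOURCE", "EXPDTA", "AUTHOR", "SCALE1", "SCALE2",
                     "SCALE3", "ORIGX1", "ORIGX2", "ORIGX3", "ANISOU", "MASTER",
                     "HETNAM", "HET", "FORMUL", "LINK", "SSBOND", ""):
            continue
        else:
            raise FormatError(f"{path}:{lineno}: unrecognized record {rec!r}")

    if current_atoms or not models:
        models.append((current_atoms, conect))
    if seen_model_kw:
        # drop a trailing empty pseudo-model created by atoms-after-ENDMDL logic
        models = [m for m in models if m[0]] or models[:1]
    return models


def _parse_atom_line(line: str, lineno: int, path: Path) -> dict:
    if len(line) < 54:
        raise FormatError(f"{path}:{lineno}: truncated ATOM/HETATM record")
    icode = line[26:27]
    if icode.strip():
        raise FormatError(
            f"{path}:{lineno}: insertion codes are not supported "
            f"(found {icode!r}); renumber the file first"
        )
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        res_name = line[17:20].strip() or line[17:21].strip()
        chain = line[21:22].strip() or "A"
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: unparsable ATOM/HETATM fields") from exc
    b_factor = None
    if len(line) >= 66 and line[60:66].strip():
        try:
            b_factor = float(line[60:66])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad B-factor field") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = guess_element(name, res_name)
    element = element.capitalize()
    return {
        "serial": serial,
        "name": name,
        "altloc": altloc,
        "res_name": res_name,
        "chain": chain,
        "res_seq": res_seq,
        "coords": np.array([x, y, z]),
        "b_factor": b_factor,
        "element": element,
        "het": line[:6].strip() == "HETATM",
        "lineno": lineno,
    }


# ----------------------------------------------------------------------
# system construction


def _build_system(records: list[dict], conect: list[tuple[int, int]]) -> MolecularSystem:
    sys_ = MolecularSystem()
    serial_to_index: dict[int, int] = {}
    for rec in records:
        if rec["altloc"] and rec["altloc"] != "A":
            raise FormatError(
                f"line {rec['lineno']}: alternate locations are not supported"
            )
        idx = len(sys_.atoms)
        serial_to_index[rec["serial"]] = idx
        sys_.atoms.append(
            Atom(
                index=idx,
                element=rec["element"],
                coords=rec["coords"],
                atom_name=rec["name"],
                residue_name=rec["res_name"],
                residue_id=f"{rec['chain']}:{rec['res_seq']}",
                b_factor=rec["b_factor"],
            )
        )
        if rec["element"].upper() in METAL_ELEMENTS and rec["het"]:
            sys_.metals.add(idx)

    _infer_bonds(sys_)

    seen = {(b.i, b.j) for b in sys_.bonds} | {(b.j, b.i) for b in sys_.bonds}
    for sa, sb in conect:
        if sa in serial_to_index and sb in serial_to_index:
            i, j = serial_to_index[sa], serial_to_index[sb]
            if i != j and (i, j) not in seen:
                sys_.bonds.append(BondTerm(i=min(i, j), j=max(i, j)))
                seen.add((i, j))
                seen.add((j, i))
    return sys_


def _infer_bonds(sys_: MolecularSystem) -> None:
    by_residue: dict[str, list[int]] = {}
    for a in sys_.atoms:
        by_residue.setdefault(a.residue_id, []).append(a.index)

    residue_order = sys_.residues()
    for rid in residue_order:
        idxs = by_residue[rid]
        res_name = sys_.atoms[idxs[0]].residue_name.upper()
        if not templates.is_templated(res_name):
            continue
        name_to_idx = {sys_.atoms[i].atom_name.upper(): i for i in idxs}
        for a_name, b_name in templates.template_bonds(res_name):
            if a_name in name_to_idx and b_name in name_to_idx:
                sys_.bonds.append(
                    BondTerm(i=name_to_idx[a_name], j=name_to_idx[b_name])
                )
        # waters: both hydrogens bond to O
        heavy_names = [
            sys_.atoms[i].atom_name.upper()
            for i in idxs
            if sys_.atoms[i].element.upper() != "H"
        ]
        for i in idxs:
            atom = sys_.atoms[i]
            if atom.element.upper() != "H":
                continue
            parent = templates.hydrogen_parent(atom.atom_name, heavy_names)
            if parent is not None and parent in name_to_idx:
                sys_.bonds.append(BondTerm(i=name_to_idx[parent], j=i))

    # peptide bonds between consecutive residues of one chain
    for prev_rid, next_rid in zip(residue_order, residue_order[1:]):
        p_chain, p_num = prev_rid.split(":")
        n_chain, n_num = next_rid.split(":")
        if p_chain != n_chain or int(n_num) != int(p_num) + 1:
            continue
        prev_name = sys_.atoms[by_residue[prev_rid][0]].residue_name.upper()
        next_name = sys_.atoms[by_residue[next_rid][0]].residue_name.upper()
        if prev_name not in templates.AMINO_ACIDS or next_name not in templates.AMINO_ACIDS:
            continue
        c_idx = next(
            (i for i in by_residue[prev_rid] if sys_.atoms[i].atom_name.upper() == "C"),
            None,
        )
        n_idx = next(
            (i for i in by_residue[next_rid] if sys_.atoms[i].atom_name.upper() == "N"),
            None,
        )
        if c_idx is not None and n_idx is not None:
            sys_.bonds.append(BondTerm(i=c_idx, j=n_idx))


# ----------------------------------------------------------------------
# writing


def write_pdb(
    systems: Union[MolecularSystem, Sequence[MolecularSystem]],
    path: PathLike,
    remarks: Optional[Sequence[Sequence[str]]] = None,
    write_conect: bool = True,
) -> None:
    """Write one system, or several as MODEL blocks, to a PDB file.

    ``remarks`` is an optional per-model list of REMARK payload strings
    (used to embed scores into multi-model pose output).
    """
    if isinstance(systems, MolecularSystem):
        systems = [systems]
    multi = len(systems) > 1
    lines: list[str] = []
    for imodel, sys_ in enumerate(systems, start=1):
        if remarks is not None and imodel - 1 < len(remarks):
            for text in remarks[imodel - 1]:
                lines.append(f"REMARK 250 {text}"[:80])
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        for a in sys_.atoms:
            chain, res_seq = a.residue_id.split(":")
            record = "HETATM" if (a.is_ligand or a.index in sys_.metals) else "ATOM"
            name = a.atom_name
            if len(name) < 4 and len(a.element) == 1:
                name = f" {name}"
            b = 0.0 if a.b_factor is None else a.b_factor
            lines.append(
                f"{record:<6}{a.index + 1:>5} {name:<4}{'':1}{a.residue_name:<3} "
                f"{chain[:1]}{int(res_seq):>4}{'':4}"
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.00:6.2f}{b:6.2f}{'':10}{a.element.upper():>2}"
            )
        if multi:
            lines.append("ENDMDL")
    if write_conect and systems:
        # CONECT from the first model's bond list (topology is shared)
        for bond in systems[0].bonds:
            lines.append(f"CONECT{bond.i + 1:>5}{bond.j + 1:>5}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
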