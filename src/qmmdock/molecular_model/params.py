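"""Parameter tables and assignment.

A parameter table is a nested mapping (usually loaded from YAML):

.. code-block:: yaml

    atoms:
      LIG:
        C1: {charge: -0.10, epsilon: 0.08, rmin_half: 2.0}
    bonds:
      C-C: {k: 300.0, r0: 1.53}
    angles:
      C-C-C: {k: 50.0, theta0: 111.0}
    torsions:
      C-C-C-C: {k: 0.20, n: 3, delta: 0.0}

Per-atom entries are keyed by residue name then atom name; bonded terms
are keyed by element sequences (canonicalized so ``C-H`` == ``H-C``).
Angle and torsion records are generated from the bond graph during
assignment; element combinations absent from the table contribute no
term.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import yaml

from qmmdock.errors import ParameterError
from qmmdock.molecular_model.types import AngleTerm, MolecularSystem, TorsionTerm

PathLike = Union[str, Path]


def load_parameter_table(path: PathLike) -> dict:
    with open(path) as fh:
        table = yaml.safe_load(fh)
    if not isinstance(table, dict) or "atoms" not in table:
        raise ParameterError(f"{path}: parameter table must contain an 'atoms' block")
    return table


def save_parameter_table(table: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(table, sort_keys=True))


def _canon(elements: list[str]) -> str:
    elems = [e.upper() for e in elements]
    rev = list(reversed(elems))
    return "-".join(min(elems, rev))


def assign_parameters(system: MolecularSystem, table: dict) -> MolecularSystem:
    """Populate charges, LJ and bonded parameters in place (idempotent).

    Every atom must resolve in ``table['atoms'][residue_name][atom_name]``;
    an unresolvable atom raises :class:`ParameterError` naming it.
    """
    atom_table = table.get("atoms", {})
    for atom in system.atoms:
        res_block = atom_table.get(atom.residue_name)
        entry = None if res_block is None else res_block.get(atom.atom_name)
        if entry is None:
            raise ParameterError(
                f"no parameters for atom {atom.atom_name!r} in residue "
                f"{atom.residue_name!r} ({atom.residue_id})"
            )
        atom.charge = float(entry["charge"])
        atom.lj_epsilon = float(entry["epsilon"])
        atom.lj_rmin_half = float(entry["rmin_half"])

    bond_table = table.get("bonds", {})
    for bond in system.bonds:
        key = _canon([system.atoms[bond.i].element, system.atoms[bond.j].element])
        entry = bond_table.get(key)
        if entry is not None:
            bond.force_k = float(entry["k"])
            bond.r0 = float(entry["r0"])

    _generate_angles_torsions(system, table)

    total = sum(a.charge for a in system.atoms)
    if system.net_charge is None:
        system.net_charge = int(round(total))
    elif abs(total - system.net_charge) > 0.01:
        raise ParameterError(
            f"assigned charges sum to {total:.4f} but the system declares "
            f"net charge {system.net_charge}"
        )
    return system


def _generate_angles_torsions(system: MolecularSystem, table: dict) -> None:
    graph = system.bond_graph()
    elem = [a.element for a in system.atoms]
    angle_table = table.get("angles", {})
    torsion_table = table.get("torsions", {})

    angles: list[AngleTerm] = []
    seen_ang = set()
    for j in graph.nodes:
        nbrs = sorted(graph.neighbors(j))
        for ai in range(len(nbrs)):
            for ak in range(ai + 1, len(nbrs)):
                i, k = nbrs[ai], nbrs[ak]
                key = _canon([elem[i], elem[j], elem[k]])
                entry = angle_table.get(key)
                if entry is None:
                    continue
                sig = (min(i, k), j, max(i, k))
                if sig in seen_ang:
                    continue
                seen_ang.add(sig)
                angles.append(
                    AngleTerm(i=i, j=j, k=k, force_k=float(entry["k"]),
                              theta0=float(entry["theta0"]))
                )
    system.angles = angles

    torsions: list[TorsionTerm] = []
    seen_tor = set()
    for j, k in graph.edges:
        for i in graph.neighbors(j):
            if i == k:
                continue
            for l in graph.neighbors(k):
                if l == j or l == i:
                    continue
                key = _canon([elem[i], elem[j], elem[k], elem[l]])
                entry = torsion_table.get(key)
                if entry is None:
                    continue
                sig = tuple(min((i, j, k, l), (l, k, j, i)))
                if sig in seen_tor:
                    continue
                seen_tor.add(sig)
                torsions.append(
                    TorsionTerm(
                        i=i, j=j, k=k, l=l,
                        force_k=float(entry["k"]),
                        periodicity=int(entry.get("n", 3)),
                        phase=float(entry.get("delta", 0.0)),
                    )
                )
    system.torsions = torsions
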