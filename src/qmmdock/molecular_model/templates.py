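"""Residue bond templates for deterministic receptor bond perception.

Heavy-atom connectivity for the 20 standard amino acids, water, and the
heme (porphyrin) core. Hydrogens are attached by the PDB v3 naming rule
implemented in :func:`hydrogen_parent`: the position code of an H name
(``HB2`` -> ``B``) matches the heavy atom carrying the same code
(``CB``). Everything not covered here must come with CONECT records.
"""

from __future__ import annotations

from typing import Optional

BACKBONE = [("N", "CA"), ("CA", "C"), ("C", "O")]

_SIDECHAINS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "PHE": [
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
        ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
    ],
    "TYR": [
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
        ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
        ("CZ", "OH"),
    ],
    "TRP": [
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
        ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
        ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2"),
    ],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU": [
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2"),
    ],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLN": [
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2"),
    ],
    "HIS": [
        ("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
        ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2"),
    ],
    "LYS": [
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ"),
    ],
    "ARG": [
        ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
        ("CZ", "NH1"), ("CZ", "NH2"),
    ],
}

# Porphyrin macrocycle + iron; ring substituents (methyls, vinyls,
# propionates) require CONECT records since their attachment naming
# varies across depositions.
_HEME_CORE: list[tuple[str, str]] = (
    [("FE", n) for n in ("NA", "NB", "NC", "ND")]
    + [
        ("NA", "C1A"), ("C1A", "C2A"), ("C2A", "C3A"), ("C3A", "C4A"), ("C4A", "NA"),
        ("NB", "C1B"), ("C1B", "C2B"), ("C2B", "C3B"), ("C3B", "C4B"), ("C4B", "NB"),
        ("NC", "C1C"), ("C1C", "C2C"), ("C2C", "C3C"), ("C3C", "C4C"), ("C4C", "NC"),
        ("ND", "C1D"), ("C1D", "C2D"), ("C2D", "C3D"), ("C3D", "C4D"), ("C4D", "ND"),
        ("C4A", "CHB"), ("CHB", "C1B"),
        ("C4B", "CHC"), ("CHC", "C1C"),
        ("C4C", "CHD"), ("CHD", "C1D"),
        ("C4D", "CHA"), ("CHA", "C1A"),
    ]
)

RESIDUE_BONDS: dict[str, list[tuple[str, str]]] = {
    name: BACKBONE + side for name, side in _SIDECHAINS.items()
}
RESIDUE_BONDS["HOH"] = []
RESIDUE_BONDS["TIP3"] = []
RESIDUE_BONDS["HEM"] = list(_HEME_CORE)

AMINO_ACIDS = frozenset(_SIDECHAINS)


def is_templated(residue_name: str) -> bool:
    return residue_name.strip().upper() in RESIDUE_BONDS


def template_bonds(residue_name: str) -> list[tuple[str, str]]:
    return RESIDUE_BONDS[residue_name.strip().upper()]


def hydrogen_parent(h_name: str, heavy_names: list[str]) -> Optional[str]:
    """Heavy atom a hydrogen bonds to, by PDB v3 position-code naming.

    ``HB2`` -> code ``B2`` -> no heavy ``?B2`` -> strip digit -> ``B``
    -> matches ``CB``. Water hydrogens (``H1``/``H2``) map to ``O``.
    Returns None when no deterministic match exists.
    """
    name = h_name.strip().upper()
    if not name.startswith("H"):
        return None
    code = name[1:]
    # backbone amide H and N-terminal H1/H2/H3
    if code == "" or code.isdigit():
        for cand in ("N", "O"):
            if cand in heavy_names:
                return cand
        return None
    candidates = [code]
    while candidates[-1] and candidates[-1][-1].isdigit():
        candidates.append(candidates[-1][:-1])
    for cand in candidates:
        if not cand:
            continue
        matches = [h for h in heavy_names if len(h) >= 2 and h[1:] == cand]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            # prefer carbon, then nitrogen/oxygen/sulfur, for stability
            for pref in ("C", "N", "O", "S"):
                hits = [m for m in matches if m.startswith(pref)]
                if hits:
                    return hits[0]
    return None
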