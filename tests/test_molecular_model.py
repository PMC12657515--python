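"""molecular_model: I/O round trips, parameter assignment, invariants."""

import numpy as np
import pytest

from qmmdock.errors import EmptyInputError, FormatError, ParameterError, QmmdockError
from qmmdock.fixtures import make_toy_complex, write_toy_complex
from qmmdock.molecular_model import (
    Atom,
    BondTerm,
    MolecularSystem,
    assign_parameters,
    load_parameter_table,
    read_ligand,
    read_receptor,
    write_mol2,
    write_pdb,
    write_sdf,
)
from qmmdock.pipeline import make_pose


# ----------------------------------------------------------------------
# PDB


def test_read_receptor_roundtrip_atom_count(toy, tmp_path):
    paths = write_toy_complex(toy, tmp_path)
    system = read_receptor(paths["receptor"])
    n_receptor = toy.system.n_atoms - len(toy.system.ligand_idx)
    assert system.n_atoms == n_receptor
    assert [a.element for a in system.atoms] == [
        toy.system.atoms[i].element for i in toy.system.receptor_idx
    ]


def test_read_receptor_roundtrip_coordinates(toy, tmp_path):
    paths = write_toy_complex(toy, tmp_path)
    system = read_receptor(paths["complex"])
    ref = toy.system.copy()
    from qmmdock.pipeline import apply_pose

    apply_pose(ref, toy.native)
    np.testing.assert_allclose(system.coords, ref.coords, atol=1.5e-3)


def test_read_receptor_roundtrip_bonds(toy, tmp_path):
    paths = write_toy_complex(toy, tmp_path)
    system = read_receptor(paths["complex"])
    got = {(min(b.i, b.j), max(b.i, b.j)) for b in system.bonds}
    want = {(min(b.i, b.j), max(b.i, b.j)) for b in toy.system.bonds}
    assert got == want


def test_read_receptor_two_models(tmp_path, toy):
    paths = write_toy_complex(toy, tmp_path)
    single = read_receptor(paths["receptor"])
    text = paths["receptor"].read_text().splitlines()
    atoms = [l for l in text if l.startswith(("ATOM", "HETATM"))]
    other = [l for l in text if not l.startswith(("ATOM", "HETATM", "END"))]
    two = (
        ["MODEL     1"] + atoms + ["ENDMDL", "MODEL     2"] + atoms + ["ENDMDL"]
        + other + ["END"]
    )
    p = tmp_path / "two_models.pdb"
    p.write_text("\n".join(two) + "\n")
    systems = read_receptor(p)
    assert isinstance(systems, list) and len(systems) == 2
    assert systems[0].n_atoms == systems[1].n_atoms == single.n_atoms


def test_read_receptor_zn_hetatm(tmp_path):
    p = tmp_path / "zn.pdb"
    p.write_text(
        "ATOM      1  CB  PSA A   1       0.000   0.000   0.000  1.00 10.00"
        "           C\n"
        "HETATM    2 ZN    ZN M   1       2.000   0.000   0.000  1.00 10.00"
        "          ZN\n"
        "END\n"
    )
    system = read_receptor(p)
    assert system.metals == {1}
    assert system.atoms[1].element.upper() == "ZN"


def test_read_receptor_empty_is_error(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(EmptyInputError):
        read_receptor(p)


def test_read_receptor_bad_line_reports_lineno(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text(
        "ATOM      1  CB  PSA A   1       0.000   0.000   0.000  1.00 10.00"
        "           C\n"
        "ATOM      2  CB  PSA A   x       0.000   0.000   0.000\n"
    )
    with pytest.raises(FormatError, match=":2"):
        read_receptor(p)


def test_read_receptor_insertion_code_rejected(tmp_path):
    p = tmp_path / "icode.pdb"
    p.write_text(
        "ATOM      1  CB  PSA A   1A      0.000   0.000   0.000  1.00 10.00"
        "           C\nEND\n"
    )
    with pytest.raises(FormatError, match="insertion"):
        read_receptor(p)


def test_amino_acid_template_bonds(tmp_path):
    lines = [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C",
        "ATOM      4  O   ALA A   1       1.400   2.400   0.000  1.00  0.00           O",
        "ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00  0.00           C",
        "ATOM      6  N   SER A   2       3.300   1.500   0.000  1.00  0.00           N",
        "ATOM      7  CA  SER A   2       4.000   2.800   0.000  1.00  0.00           C",
        "ATOM      8  C   SER A   2       5.500   2.600   0.000  1.00  0.00           C",
        "ATOM      9  O   SER A   2       6.100   1.500   0.000  1.00  0.00           O",
        "ATOM     10  CB  SER A   2       3.600   3.600   1.300  1.00  0.00           C",
        "ATOM     11  OG  SER A   2       4.200   4.900   1.300  1.00  0.00           O",
        "END",
    ]
    p = tmp_path / "dipeptide.pdb"
    p.write_text("\n".join(lines) + "\n")
    system = read_receptor(p)
    bonds = {(min(b.i, b.j), max(b.i, b.j)) for b in system.bonds}
    assert (0, 1) in bonds  # N-CA
    assert (1, 4) in bonds  # CA-CB
    assert (2, 5) in bonds  # peptide C-N
    assert (9, 10) in bonds  # CB-OG


# ----------------------------------------------------------------------
# ligands


def _ethane_sdf(tmp_path):
    block = """ethane
     RDKit          3D

  8  7  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.5300    0.0000    0.0000 C   0  0
   -0.4000    0.9000    0.5000 H   0  0
   -0.4000   -0.9000    0.5000 H   0  0
   -0.4000    0.0000   -1.0000 H   0  0
    1.9300    0.9000   -0.5000 H   0  0
    1.9300   -0.9000   -0.5000 H   0  0
    1.9300    0.0000    1.0000 H   0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  2  6  1  0
  2  7  1  0
  2  8  1  0
M  END
$$$$
"""
    p = tmp_path / "ethane.sdf"
    p.write_text(block)
    return p


def test_read_ligand_ethane(tmp_path):
    system = read_ligand(_ethane_sdf(tmp_path))
    heavy = system.heavy_idx(system.ligand_idx)
    assert len(heavy) == 2
    assert system.n_atoms == 8
    cc = [
        b for b in system.bonds
        if system.atoms[b.i].element == "C" and system.atoms[b.j].element == "C"
    ]
    assert len(cc) == 1
    assert all(a.is_ligand for a in system.atoms)


def test_read_ligand_formal_charge(tmp_path):
    block = """anion
     RDKit          3D

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.3000    0.0000    0.0000 O   0  0
  1  2  1  0
M  CHG  1   2  -1
M  END
$$$$
"""
    p = tmp_path / "anion.sdf"
    p.write_text(block)
    assert read_ligand(p).net_charge == -1


def test_read_ligand_missing_bond_block(tmp_path):
    block = """nobonds
     RDKit          3D

  2  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.3000    0.0000    0.0000 O   0  0
M  END
$$$$
"""
    p = tmp_path / "nobonds.sdf"
    p.write_text(block)
    with pytest.raises(FormatError):
        read_ligand(p)


def test_mol2_roundtrip(toy, tmp_path):
    lig_idx = toy.system.ligand_idx
    ligand = MolecularSystem(
        atoms=[toy.system.atoms[i].copy() for i in lig_idx],
        net_charge=0,
    )
    remap = {old: new for new, old in enumerate(lig_idx)}
    for new, atom in enumerate(ligand.atoms):
        atom.index = new
    ligand.bonds = [
        BondTerm(i=remap[b.i], j=remap[b.j], order=b.order)
        for b in toy.system.bonds
        if b.i in remap and b.j in remap
    ]
    p = tmp_path / "lig.mol2"
    write_mol2(ligand, p)
    back = read_ligand(p)
    assert back.n_atoms == ligand.n_atoms
    np.testing.assert_allclose(back.coords, ligand.coords, atol=1e-4)
    assert len(back.bonds) == len(ligand.bonds)


def test_sdf_roundtrip_coordinates(toy, tmp_path):
    p = tmp_path / "lig.sdf"
    write_sdf(toy.system, p, subset=toy.system.ligand_idx)
    back = read_ligand(p)
    ref = toy.system.coords[toy.system.ligand_idx]
    np.testing.assert_allclose(back.coords, ref, atol=1e-4)
    assert [a.element for a in back.atoms] == [
        toy.system.atoms[i].element for i in toy.system.ligand_idx
    ]


# ----------------------------------------------------------------------
# parameters


def test_assign_parameters_all_heavy_lj_positive(toy):
    for i in toy.system.heavy_idx():
        assert toy.system.atoms[i].lj_epsilon > 0


def test_assign_parameters_missing_atom_named(toy):
    system = toy.system.copy()
    table = {"atoms": {k: dict(v) for k, v in toy.params["atoms"].items()}}
    del table["atoms"]["LIG"]["C1"]
    with pytest.raises(ParameterError, match="C1"):
        assign_parameters(system, table)


def test_assign_parameters_idempotent(toy):
    system = toy.system.copy()
    before = [(a.charge, a.lj_epsilon, a.lj_rmin_half) for a in system.atoms]
    n_angles = len(system.angles)
    assign_parameters(system, toy.params)
    after = [(a.charge, a.lj_epsilon, a.lj_rmin_half) for a in system.atoms]
    assert before == after
    assert len(system.angles) == n_angles


def test_charge_sum_matches_net_charge(toy, toy_metal, toy_covalent):
    for tc in (toy, toy_metal, toy_covalent):
        total = float(np.sum(tc.system.charges))
        assert abs(total - tc.system.net_charge) <= 0.01


# ----------------------------------------------------------------------
# pose output


def test_write_poses_order_and_roundtrip(toy, tmp_path):
    from qmmdock.fixtures import perturb_pose
    from qmmdock.molecular_model import read_pose_coords, write_poses

    poses = [perturb_pose(toy.native, seed, 1.0, system=toy.system) for seed in range(10)]
    sdf = tmp_path / "poses.sdf"
    pdb = tmp_path / "poses.pdb"
    write_poses(poses, toy.system, sdf_path=sdf, pdb_path=pdb)
    back = read_pose_coords(sdf)
    assert len(back) == 10
    lig = toy.system.ligand_idx
    rows = [list(poses[0].movable).index(i) for i in lig]
    for pose, (coords, _tags) in zip(poses, back):
        np.testing.assert_allclose(coords, pose.coords[rows], atol=1e-4)


def test_write_poses_empty_list(toy, tmp_path):
    from qmmdock.molecular_model import write_poses

    sdf = tmp_path / "empty.sdf"
    write_poses([], toy.system, sdf_path=sdf)
    assert sdf.exists()


def test_write_poses_heterogeneous_topology(toy, tmp_path):
    from qmmdock.molecular_model import write_poses

    good = make_pose(toy.system)
    bad = make_pose(toy.system, movable=toy.system.ligand_idx[:-1])
    with pytest.raises(QmmdockError, match="heterogeneous"):
        write_poses([good, bad], toy.system, sdf_path=tmp_path / "x.sdf")


# ----------------------------------------------------------------------
# data model invariants


def test_atom_nonfinite_coords_rejected():
    with pytest.raises(QmmdockError):
        Atom(index=0, element="C", coords=[np.nan, 0, 0], atom_name="C1",
             residue_name="LIG", residue_id="L:1")


def test_self_bond_rejected():
    system = MolecularSystem(
        atoms=[Atom(index=0, element="C", coords=[0, 0, 0], atom_name="C1",
                    residue_name="LIG", residue_id="L:1")],
        bonds=[BondTerm(i=0, j=0)],
    )
    with pytest.raises(QmmdockError):
        system.validate()


def test_disconnected_ligand_rejected():
    atoms = [
        Atom(index=k, element="C", coords=[float(k) * 3, 0, 0], atom_name=f"C{k+1}",
             residue_name="LIG", residue_id="L:1", is_ligand=True)
        for k in range(3)
    ]
    system = MolecularSystem(atoms=atoms, bonds=[BondTerm(i=0, j=1)])
    with pytest.raises(QmmdockError, match="bonded component"):
        system.validate()
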