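"""evaluation: symmetry RMSD, success bookkeeping, quality filters."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmmdock.evaluation import (
    FilterResult,
    QUALITY_FILTERS,
    apply_quality_filters,
    detect_scoring_failure,
    graph_automorphisms,
    judge_success,
    ligand_graph,
    rule_pass_counts,
    success_rate,
    symmetry_rmsd,
)
from qmmdock.fixtures import make_benchmark_records, planted_violation_name
from qmmdock.molecular_model import Atom, BenchmarkRecord, BondTerm, MolecularSystem


def _ring_system(n=6, alternating=False):
    """Planar n-ring of carbons (2-fold or n-fold graph symmetry)."""
    atoms, bonds = [], []
    for k in range(n):
        angle = 2 * np.pi * k / n
        atoms.append(
            Atom(index=k, element="C", coords=[np.cos(angle), np.sin(angle), 0.0],
                 atom_name=f"C{k+1}", residue_name="LIG", residue_id="L:1",
                 is_ligand=True)
        )
        order = (2.0 if k % 2 == 0 else 1.0) if alternating else 1.0
        bonds.append(BondTerm(i=k, j=(k + 1) % n, order=order))
    return MolecularSystem(atoms=atoms, bonds=bonds)


class _P:
    """Minimal ranked-pose record."""

    def __init__(self, score, converged=True):
        self.score = score
        self.converged = converged


# ----------------------------------------------------------------------
# symmetry RMSD


def test_identical_poses_zero(toy):
    graph = ligand_graph(toy.system)
    coords = toy.system.coords[toy.system.heavy_idx(toy.system.ligand_idx)]
    assert symmetry_rmsd(coords, coords, graph) == 0.0


def test_flipped_symmetric_ring_zero():
    """180-degree flip about a symmetry axis: symmetry-adapted RMSD is 0
    while the identity mapping RMSD is positive."""
    system = _ring_system(6)
    graph = ligand_graph(system)
    coords = system.coords
    flipped = coords.copy()
    flipped[:, 1] = -flipped[:, 1]  # mirror across the x axis = ring flip
    identity_rmsd = float(np.sqrt(np.mean(np.sum((coords - flipped) ** 2, axis=1))))
    assert identity_rmsd > 0.5
    assert symmetry_rmsd(coords, flipped, graph) == pytest.approx(0.0, abs=1e-12)


def test_translation_rmsd_closed_form(toy):
    """Rigid translation by t of an asymmetric ligand gives RMSD |t|."""
    system = toy.system.copy()
    # break the head-tail graph symmetry by tagging one end atom's element
    heavy = system.heavy_idx(system.ligand_idx)
    system.atoms[heavy[0]].element = "N"
    graph = ligand_graph(system)
    assert len(graph_automorphisms(graph)) == 1
    coords = system.coords[heavy]
    t = np.array([1.0, 0.0, 0.0])
    assert symmetry_rmsd(coords, coords + t, graph) == pytest.approx(1.0, abs=1e-12)


def test_symmetry_rmsd_never_exceeds_identity(toy_long):
    rng = np.random.default_rng(0)
    graph = ligand_graph(toy_long.system)
    heavy = toy_long.system.heavy_idx(toy_long.system.ligand_idx)
    base = toy_long.system.coords[heavy]
    for _ in range(20):
        other = base + rng.normal(scale=1.0, size=base.shape)
        identity = float(np.sqrt(np.mean(np.sum((base - other) ** 2, axis=1))))
        assert symmetry_rmsd(base, other, graph) <= identity + 1e-12


def test_symmetry_rmsd_is_symmetric_metric(toy_long):
    rng = np.random.default_rng(1)
    graph = ligand_graph(toy_long.system)
    heavy = toy_long.system.heavy_idx(toy_long.system.ligand_idx)
    a = toy_long.system.coords[heavy]
    b = a + rng.normal(scale=0.8, size=a.shape)
    c = a + rng.normal(scale=0.8, size=a.shape)
    assert symmetry_rmsd(a, b, graph) == pytest.approx(symmetry_rmsd(b, a, graph))
    assert symmetry_rmsd(a, b, graph) >= 0
    # triangle inequality (holds for min-over-group of a metric)
    assert symmetry_rmsd(a, c, graph) <= (
        symmetry_rmsd(a, b, graph) + symmetry_rmsd(b, c, graph) + 1e-9
    )


def test_bond_order_restricts_automorphisms():
    plain = _ring_system(6, alternating=False)
    kekule = _ring_system(6, alternating=True)
    assert len(graph_automorphisms(ligand_graph(plain))) == 12  # dihedral D6
    assert len(graph_automorphisms(ligand_graph(kekule))) == 6  # orders must match


def test_element_mismatch_rejected(toy):
    graph = ligand_graph(toy.system)
    coords = toy.system.coords[toy.system.heavy_idx(toy.system.ligand_idx)]
    import qmmdock.errors

    with pytest.raises(qmmdock.errors.QmmdockError):
        symmetry_rmsd(coords[:-1], coords, graph)


# ----------------------------------------------------------------------
# judge_success / scoring failure


def _coords_at_rmsd(base, rmsd, rng):
    d = rng.normal(size=base.shape)
    d *= rmsd / np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return base + d


def test_success_inclusive_at_cutoff():
    system = _ring_system(6)
    heavy = system.heavy_idx(system.ligand_idx)
    system.atoms[heavy[0]].element = "N"  # kill symmetry for exactness
    graph = ligand_graph(system)
    native = system.coords[heavy]
    t = np.array([1.5, 0.0, 0.0])
    out = judge_success([_P(-5.0)], native, graph, [native + t], cutoff=1.5)
    assert out["success"] is True
    assert out["best_rmsd"] == pytest.approx(1.5, abs=1e-12)
    t = np.array([1.51, 0.0, 0.0])
    out = judge_success([_P(-5.0)], native, graph, [native + t], cutoff=1.5)
    assert out["success"] is False


def test_only_best_scored_pose_counts(toy):
    graph = ligand_graph(toy.system)
    heavy = toy.system.heavy_idx(toy.system.ligand_idx)
    native = toy.system.coords[heavy]
    rng = np.random.default_rng(2)
    far = _coords_at_rmsd(native, 3.0, rng)
    near = _coords_at_rmsd(native, 0.2, rng)
    out = judge_success([_P(-10.0), _P(-9.0)], native, graph, [far, near])
    assert out["success"] is False  # best-scored pose is the far one


def test_non_converged_poses_skipped(toy):
    graph = ligand_graph(toy.system)
    heavy = toy.system.heavy_idx(toy.system.ligand_idx)
    native = toy.system.coords[heavy]
    rng = np.random.default_rng(3)
    far = _coords_at_rmsd(native, 3.0, rng)
    near = _coords_at_rmsd(native, 0.2, rng)
    out = judge_success(
        [_P(-10.0, converged=False), _P(-9.0)], native, graph, [far, near]
    )
    assert out["success"] is True
    out = judge_success([_P(-10.0, converged=False)], native, graph, [far])
    assert out["status"] == "non-converged"
    assert out["success"] is None


def test_success_monotone_in_cutoff(toy):
    graph = ligand_graph(toy.system)
    heavy = toy.system.heavy_idx(toy.system.ligand_idx)
    native = toy.system.coords[heavy]
    rng = np.random.default_rng(4)
    pose = _coords_at_rmsd(native, 1.2, rng)
    cuts = [0.5, 1.0, 1.5, 2.0, 3.0]
    flags = [
        judge_success([_P(0.0)], native, graph, [pose], cutoff=c)["success"]
        for c in cuts
    ]
    assert flags == sorted(flags)  # False..False True..True


def test_scoring_failure_definition(toy):
    graph = ligand_graph(toy.system)
    heavy = toy.system.heavy_idx(toy.system.ligand_idx)
    native = toy.system.coords[heavy]
    rng = np.random.default_rng(5)
    far = _coords_at_rmsd(native, 3.0, rng)
    near = _coords_at_rmsd(native, 0.4, rng)
    # better-scored far pose -> scoring failure
    assert detect_scoring_failure([_P(-52.0)], [far], -50.0, native, graph)
    # all poses worse than native -> no failure
    assert not detect_scoring_failure([_P(-49.0)], [far], -50.0, native, graph)
    # better-scored near-native pose -> not a failure
    assert not detect_scoring_failure([_P(-52.0)], [near], -50.0, native, graph)


# ----------------------------------------------------------------------
# success_rate


def test_success_rate_simple():
    results = [{"converged": True, "success": k < 7} for k in range(10)]
    out = success_rate(results)
    assert out["succ"] == pytest.approx(70.0)
    assert out["conv"] == pytest.approx(100.0)


def test_success_rate_denominator_rule():
    results = [{"converged": k < 9, "success": k < 7} for k in range(10)]
    out = success_rate(results)
    assert out["succ"] == pytest.approx(100.0 * 7 / 9, abs=0.05)
    assert round(out["succ"], 1) == 77.8
    assert out["conv"] == pytest.approx(90.0)


def test_success_rate_zero_converged_is_status():
    out = success_rate([{"converged": False, "success": None}] * 3)
    assert out["status"] == "no converged complexes"
    assert "succ" not in out


def test_success_rate_brute_force_recount():
    """50-complex synthetic outcome table vs an independent recount."""
    rng = np.random.default_rng(6)
    results = []
    for _ in range(50):
        converged = bool(rng.uniform() < 0.9)
        results.append(
            {
                "converged": converged,
                "success": bool(rng.uniform() < 0.7),
                "success_ns": bool(rng.uniform() < 0.6),
            }
        )
    out = success_rate(results)
    n_conv = n_succ = n_succ_ns = 0
    for r in results:  # independent counting oracle
        if r["converged"]:
            n_conv += 1
            n_succ += r["success"]
            n_succ_ns += r["success_ns"]
    assert out["conv"] == pytest.approx(100.0 * n_conv / 50)
    assert out["succ"] == pytest.approx(100.0 * n_succ / n_conv)
    assert out["succ_ns"] == pytest.approx(100.0 * n_succ_ns / n_conv)


# ----------------------------------------------------------------------
# quality filters


def _passing_record(**overrides):
    fields = dict(
        complex_id="X",
        resolution=2.0,
        dpi=0.3,
        ligand_b_factor_avg=40.0,
        ediam=0.7,
        mw=300.0,
        n_rotatable_bonds=5,
        ghose_pass_count=4,
        lipinski_pass_count=4,
        has_missing_atoms=False,
        has_altlocs=False,
        min_crystal_contact=5.0,
    )
    fields.update(overrides)
    return BenchmarkRecord(**fields)


def test_filters_all_pass():
    out = apply_quality_filters(_passing_record())
    assert out.passed and out.violated == []


def test_filter_mw_low():
    out = apply_quality_filters(_passing_record(mw=49.0))
    assert not out.passed and out.violated == ["mw-range"]


def test_filter_rotatable_strict():
    assert not apply_quality_filters(_passing_record(n_rotatable_bonds=18)).passed
    assert apply_quality_filters(_passing_record(n_rotatable_bonds=17)).passed


@pytest.mark.parametrize(
    "override,expected",
    [
        ({"resolution": 2.51}, "resolution"),
        ({"dpi": 0.51}, "dpi"),
        ({"ligand_b_factor_avg": 80.01}, "b-factor"),
        ({"ediam": 0.39}, "ediam"),
        ({"mw": 500.5}, "mw-range"),
        ({"ghose_pass_count": 2}, "ghose"),
        ({"lipinski_pass_count": 2}, "lipinski"),
        ({"has_missing_atoms": True}, "missing-atoms"),
        ({"has_altlocs": True}, "altlocs"),
        ({"min_crystal_contact": 4.49}, "crystal-contact"),
    ],
)
def test_each_filter_boundary(override, expected):
    out = apply_quality_filters(_passing_record(**override))
    assert out.violated == [expected]


def test_filter_boundaries_inclusive():
    # bounds themselves pass
    rec = _passing_record(resolution=2.5, dpi=0.5, ligand_b_factor_avg=80.0,
                          ediam=0.4, mw=500.0, ghose_pass_count=3,
                          lipinski_pass_count=3, min_crystal_contact=4.5)
    assert apply_quality_filters(rec).passed


def test_missing_field_unevaluable():
    rec = _passing_record()
    rec.ediam = None
    out = apply_quality_filters(rec)
    assert not out.passed
    assert any("unevaluable" in v for v in out.violated)


def test_filters_agree_with_independent_predicate():
    """Filter-by-filter truth table on the 12-record battery."""
    records = make_benchmark_records(seed=3, n=12, planted_pass_count=5)

    def independent(r):  # spelled out separately from QUALITY_FILTERS
        checks = {
            "resolution": r.resolution <= 2.5,
            "dpi": r.dpi <= 0.5,
            "b-factor": r.ligand_b_factor_avg <= 80,
            "ediam": r.ediam >= 0.4,
            "mw-range": 50 <= r.mw <= 500,
            "rotatable-bonds": r.n_rotatable_bonds < 18,
            "ghose": r.ghose_pass_count >= 3,
            "lipinski": r.lipinski_pass_count >= 3,
            "missing-atoms": not r.has_missing_atoms,
            "altlocs": not r.has_altlocs,
            "crystal-contact": r.min_crystal_contact >= 4.5,
        }
        return {name for name, ok in checks.items() if not ok}

    for rec in records:
        got = apply_quality_filters(rec)
        assert set(got.violated) == independent(rec)
        assert got.passed == (not independent(rec))


# ----------------------------------------------------------------------
# drug-likeness helper


def test_rule_pass_counts_aspirin_like():
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O"))
    ghose, lip = rule_pass_counts(mol)
    assert lip == 4  # aspirin satisfies all Lipinski rules
    assert 0 <= ghose <= 4
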