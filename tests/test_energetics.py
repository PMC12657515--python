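"""energetics: oracles for every term, gradients, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmmdock import constants
from qmmdock.energetics import (
    EnergyBreakdown,
    born_radii_hct,
    coulomb_point_sets,
    exclusion_pairs,
    gb_polar_energy,
    gb_sa_solvation,
    mm_gradient,
    mm_interaction,
    mm_terms,
    mmbp_energy,
    sasa_shrake_rupley,
    ss_self_repulsion,
    unit_sphere_points,
)
from qmmdock.errors import ConfigError, SingularityError
from qmmdock.molecular_model import Atom, BondTerm, MolecularSystem


def _two_atoms(q1, q2, r, eps=0.0, rmin_half=1.0):
    atoms = [
        Atom(index=0, element="C", coords=[0, 0, 0], atom_name="C1",
             residue_name="LIG", residue_id="L:1", charge=q1,
             lj_epsilon=eps, lj_rmin_half=rmin_half),
        Atom(index=1, element="C", coords=[r, 0, 0], atom_name="C2",
             residue_name="LIG", residue_id="L:1", charge=q2,
             lj_epsilon=eps, lj_rmin_half=rmin_half),
    ]
    return MolecularSystem(atoms=atoms)


# ----------------------------------------------------------------------
# MM terms


def test_coulomb_unit_charges_one_angstrom():
    system = _two_atoms(1.0, 1.0, 1.0)
    terms = mm_terms(system)
    # k q1 q2 / r with the CHARMM Coulomb constant
    assert terms.elec == pytest.approx(332.0637, abs=1e-10)


def test_lj_minimum_is_minus_epsilon():
    system = _two_atoms(0.0, 0.0, 2.0, eps=0.25, rmin_half=1.0)
    terms = mm_terms(system)  # r == rmin_half_i + rmin_half_j
    assert terms.lj == pytest.approx(-0.25, abs=1e-12)


def test_cutoff_excludes_beyond_12():
    system = _two_atoms(1.0, 1.0, 12.01, eps=0.1, rmin_half=2.0)
    terms = mm_terms(system, cutoff=12.0)
    assert terms.lj == 0.0 and terms.elec == 0.0


def test_exclusions_12_13_excluded_14_full(toy_long):
    system = toy_long.system
    excl = exclusion_pairs(system)
    lig = system.ligand_idx
    heavy = system.heavy_idx(lig)
    # consecutive chain atoms are 1-2; separated by one is 1-3
    assert (min(heavy[0], heavy[1]), max(heavy[0], heavy[1])) in excl
    assert (min(heavy[0], heavy[2]), max(heavy[0], heavy[2])) in excl
    # 1-4 pair is not excluded
    assert (min(heavy[0], heavy[3]), max(heavy[0], heavy[3])) not in excl


def test_pair_sum_matches_naive_double_loop(toy):
    """Vectorized nonbonded energies equal an O(n^2) oracle to 1e-10."""
    system = toy.system
    excl = exclusion_pairs(system)
    sel = list(range(system.n_atoms))
    terms = mm_terms(system, sel, cutoff=constants.NB_CUTOFF)
    lj_naive = elec_naive = 0.0
    coords, q = system.coords, system.charges
    for i in range(system.n_atoms):
        for j in range(i + 1, system.n_atoms):
            if (i, j) in excl:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r > constants.NB_CUTOFF:
                continue
            ai, aj = system.atoms[i], system.atoms[j]
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            sr6 = ((ai.lj_rmin_half + aj.lj_rmin_half) / r) ** 6
            lj_naive += eps * (sr6 * sr6 - 2 * sr6)
            elec_naive += constants.COULOMB_KCAL * ai.charge * aj.charge / r
    assert terms.lj == pytest.approx(lj_naive, abs=1e-10)
    assert terms.elec == pytest.approx(elec_naive, abs=1e-10)


def test_mm_gradient_matches_finite_differences(toy):
    system = toy.system.copy()
    sel = system.ligand_idx
    grad = mm_gradient(system, sel)
    h = 1e-5
    base_coords = system.coords
    rng = np.random.default_rng(3)
    for i in rng.choice(sel, size=4, replace=False):
        for axis in range(3):
            for sign, out in ((+1, "p"), (-1, "m")):
                c = base_coords.copy()
                c[i, axis] += sign * h
                system.set_coords(c)
                e = mm_terms(system, sel).total
                if out == "p":
                    ep = e
                else:
                    em = e
            system.set_coords(base_coords)
            assert grad[i, axis] == pytest.approx((ep - em) / (2 * h), abs=2e-4)


def test_mm_interaction_symmetry(toy):
    system = toy.system
    lig, rec = system.ligand_idx, system.receptor_idx
    assert mm_interaction(system, lig, rec) == pytest.approx(
        mm_interaction(system, rec, lig)
    )


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_energy_rigid_motion_invariance(seed):
    """Every MM term is invariant under rigid motion of the whole system."""
    from qmmdock.fixtures import make_toy_complex
    from scipy.spatial.transform import Rotation

    tc = make_toy_complex(7)
    system = tc.system.copy()
    ref = mm_terms(system)
    rng = np.random.default_rng(seed)
    rot = Rotation.from_rotvec(rng.uniform(0, np.pi) * _unit(rng.normal(size=3)))
    shift = rng.uniform(-20, 20, size=3)
    system.set_coords(system.coords @ rot.as_matrix().T + shift)
    moved = mm_terms(system)
    for name in ("bond", "angle", "torsion", "lj", "elec"):
        assert getattr(moved, name) == pytest.approx(getattr(ref, name), abs=1e-8)


def _unit(v):
    return v / np.linalg.norm(v)


# ----------------------------------------------------------------------
# solvation surrogate


def test_zero_charges_zero_polar(toy):
    g_elec, g_np = gb_sa_solvation(toy.system, np.zeros(toy.system.n_atoms))
    assert g_elec == 0.0
    assert g_np > 0.0


def test_born_limit_single_ion():
    """Single ion matches the closed-form Born expression within 1e-6."""
    for radius, q in ((2.0, 1.0), (1.5, -2.0), (3.0, 0.5)):
        system = MolecularSystem(
            atoms=[Atom(index=0, element="C", coords=[0, 0, 0], atom_name="C1",
                        residue_name="LIG", residue_id="L:1", charge=q,
                        lj_epsilon=0.1, lj_rmin_half=radius)]
        )
        g_elec, _ = gb_sa_solvation(system, [q])
        eps_in, eps_out = constants.DIELECTRIC_SOLUTE, constants.DIELECTRIC_SOLVENT
        born = -0.5 * constants.COULOMB_KCAL * (1 / eps_in - 1 / eps_out) * q * q / radius
        assert g_elec == pytest.approx(born, abs=1e-6)


def test_single_sphere_nonpolar_analytic():
    """SASA of one sphere: 0.015 * 4*pi*(R+probe)^2, numeric within 1%."""
    system = MolecularSystem(
        atoms=[Atom(index=0, element="C", coords=[0, 0, 0], atom_name="C1",
                    residue_name="LIG", residue_id="L:1", charge=0.0,
                    lj_epsilon=0.1, lj_rmin_half=2.0)]
    )
    _, g_np = gb_sa_solvation(system, [0.0], gamma=0.015, probe=1.4)
    analytic = 0.015 * 4.0 * np.pi * 3.4**2
    assert abs(g_np - analytic) / analytic < 0.01
    assert g_np == pytest.approx(2.179, abs=0.03)


def test_two_overlapping_spheres_sasa_oracle():
    """Two equal spheres: exact overlap area from the spherical-cap formula."""
    R, d = 2.0 + 1.4, 2.0
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    radii = np.array([2.0, 2.0])
    # each sphere loses a cap of height h = R - d/2
    h = R - d / 2
    analytic = 2 * (4 * np.pi * R * R - 2 * np.pi * R * h)
    numeric = sasa_shrake_rupley(coords, radii, probe=1.4, n_points=960)
    assert abs(numeric - analytic) / analytic < 0.01


def test_gb_polar_nonpositive_single_charge():
    rng = np.random.default_rng(0)
    for _ in range(20):
        coords = rng.normal(size=(1, 3))
        radius = rng.uniform(1.0, 3.0, size=1)
        q = rng.uniform(-2, 2, size=1)
        born = born_radii_hct(coords, radius)
        assert gb_polar_energy(coords, q, born) <= 0.0


def test_gb_negative_gamma_rejected(toy):
    with pytest.raises(ConfigError):
        gb_sa_solvation(toy.system, np.zeros(toy.system.n_atoms), gamma=-0.1)


def test_nonpolar_nonnegative(toy, toy_metal):
    for tc in (toy, toy_metal):
        _, g_np = gb_sa_solvation(tc.system, tc.system.charges)
        assert g_np >= 0.0


def test_unit_sphere_points_deterministic():
    a = unit_sphere_points(240)
    b = unit_sphere_points(240)
    assert a is b
    np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)


# ----------------------------------------------------------------------
# SS self-repulsion


def test_ss_self_repulsion_single_charge_zero():
    assert ss_self_repulsion(np.array([[0.0, 0, 0]]), [1.0]) == 0.0


def test_ss_self_repulsion_two_charges_oracle():
    pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    e = ss_self_repulsion(pos, [0.5, 0.5])
    assert e == pytest.approx(332.0637 * 0.25 / 2.0, abs=1e-10)
    assert e == pytest.approx(41.508, abs=1e-3)


def test_ss_self_repulsion_identical_positions():
    pos = np.array([[0.0, 0, 0], [0.0, 0, 0]])
    with pytest.raises(SingularityError):
        ss_self_repulsion(pos, [0.5, 0.5])


def test_ss_self_repulsion_matches_double_loop():
    rng = np.random.default_rng(5)
    pos = rng.normal(scale=4.0, size=(12, 3))
    q = rng.uniform(-1, 1, size=12)
    naive = sum(
        constants.COULOMB_KCAL * q[i] * q[j] / np.linalg.norm(pos[i] - pos[j])
        for i in range(12)
        for j in range(i + 1, 12)
    )
    assert ss_self_repulsion(pos, q) == pytest.approx(naive, abs=1e-10)


# ----------------------------------------------------------------------
# MMBP


def test_mmbp_minimum_at_r0():
    assert mmbp_energy(2.1, D=30.0, a=1.5, r0=2.1) == pytest.approx(-30.0)


def test_mmbp_dissociation_limit():
    D, a, r0 = 30.0, 1.5, 2.1
    assert abs(mmbp_energy(r0 + 50.0 / a, D, a, r0)) < 1e-6 * D


def test_mmbp_direct_evaluation():
    val = mmbp_energy(2.6, D=30.0, a=1.5, r0=2.1)
    assert val == pytest.approx(30.0 * (1 - np.exp(-0.75)) ** 2 - 30.0, abs=1e-12)


def test_mmbp_invalid_params():
    with pytest.raises(ConfigError):
        mmbp_energy(2.0, D=-1.0, a=1.0, r0=2.0)


# ----------------------------------------------------------------------
# breakdown bookkeeping


def test_breakdown_totals_are_component_sums():
    rng = np.random.default_rng(1)
    for _ in range(100):
        values = rng.normal(size=13)
        bd = EnergyBreakdown(*values)
        assert bd.e_qmmm == pytest.approx(
            bd.e_qm_ps + bd.e_qm_elec_ps_ss + bd.e_mm_complex
            - bd.e_mm_ps - bd.e_mm_elec_ps_ss - bd.ss_self_correction,
            abs=1e-8,
        )
        assert bd.score_class == pytest.approx(
            bd.e_intra_lig + bd.e_intra_recflex + bd.e_vdw_lig_rec
            + bd.e_elec_lig_rec + bd.g_solv_elec + bd.g_solv_np + bd.e_mmbp,
            abs=1e-8,
        )
        assert bd.score_qmmm == pytest.approx(
            bd.e_qmmm + bd.g_solv_elec + bd.g_solv_np, abs=1e-8
        )


def test_coulomb_point_sets_oracle():
    pos_a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    pos_b = np.array([[0.0, 3.0, 0]])
    e = coulomb_point_sets(pos_a, [1.0, -0.5], pos_b, [2.0])
    expect = constants.COULOMB_KCAL * (
        1.0 * 2.0 / 3.0 + (-0.5) * 2.0 / np.sqrt(1 + 9)
    )
    assert e == pytest.approx(expect, abs=1e-10)
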