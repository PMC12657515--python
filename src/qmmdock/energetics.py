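"""Classical energy terms, GB/SA solvation surrogate, secondary-system
self-repulsion, and the Morse-like metal binding potential.

Conventions: LJ uses the Rmin convention (pair minimum at
``rmin_half_i + rmin_half_j``, depth ``sqrt(eps_i*eps_j)``); bond and
angle terms are ``k*(x-x0)**2`` (no 1/2); nonbonded pairs separated by
one or two bonds are excluded, 1-4 pairs count at full strength; plain
truncation at the nonbonded cutoff.

The polar solvation surrogate is a generalized-Born model with
Hawkins-Cramer-Truhlar pairwise-descreening radii; the nonpolar term is
surface tension times a point-sampled (Shrake-Rupley style) SASA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import numpy as np

from qmmdock import constants
from qmmdock.errors import ConfigError, ParameterError, SingularityError
from qmmdock.molecular_model.types import MolecularSystem

# ----------------------------------------------------------------------
# containers


@dataclass
class MMTerms:
    """One MM evaluation split by term."""

    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    lj: float = 0.0
    elec: float = 0.0

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.torsion + self.lj + self.elec


@dataclass
class EnergyBreakdown:
    """Every scored term stored separately; totals are derived sums."""

    e_qm_ps: float = 0.0
    e_qm_elec_ps_ss: float = 0.0
    e_mm_complex: float = 0.0
    e_mm_ps: float = 0.0
    e_mm_elec_ps_ss: float = 0.0
    e_intra_lig: float = 0.0
    e_intra_recflex: float = 0.0
    e_vdw_lig_rec: float = 0.0
    e_elec_lig_rec: float = 0.0
    g_solv_elec: float = 0.0
    g_solv_np: float = 0.0
    e_mmbp: float = 0.0
    ss_self_correction: float = 0.0

    @property
    def e_qmmm(self) -> float:
        """Subtractive hybrid energy of the complex."""
        return (
            self.e_qm_ps
            + self.e_qm_elec_ps_ss
            + self.e_mm_complex
            - self.e_mm_ps
            - self.e_mm_elec_ps_ss
            - self.ss_self_correction
        )

    @property
    def score_class(self) -> float:
        return (
            self.e_intra_lig
            + self.e_intra_recflex
            + self.e_vdw_lig_rec
            + self.e_elec_lig_rec
            + self.g_solv_elec
            + self.g_solv_np
            + self.e_mmbp
        )

    @property
    def score_qmmm(self) -> float:
        return self.e_qmmm + self.g_solv_elec + self.g_solv_np

    def as_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["e_qmmm"] = self.e_qmmm
        out["score_class"] = self.score_class
        out["score_qmmm"] = self.score_qmmm
        return out


# ----------------------------------------------------------------------
# exclusions


def exclusion_pairs(system: MolecularSystem) -> set[tuple[int, int]]:
    """1-2 and 1-3 pairs (as sorted tuples) from the bond graph."""
    adj: dict[int, set[int]] = {i: set() for i in range(system.n_atoms)}
    for b in system.bonds:
        adj[b.i].add(b.j)
        adj[b.j].add(b.i)
    excl: set[tuple[int, int]] = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            excl.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
    return excl


def _require_params(system: MolecularSystem, idx: Iterable[int]) -> None:
    for i in idx:
        a = system.atoms[i]
        if a.lj_epsilon is None or a.lj_rmin_half is None:
            raise ParameterError(
                f"atom {a.atom_name!r} ({a.residue_id}) has no LJ parameters; "
                "run assign_parameters first"
            )


# ----------------------------------------------------------------------
# MM terms


def mm_terms(
    system: MolecularSystem,
    selection: Optional[Sequence[int]] = None,
    cutoff: float = constants.NB_CUTOFF,
    exclusions: Optional[set[tuple[int, int]]] = None,
) -> MMTerms:
    """MM energy of a subsystem: bonded terms fully inside ``selection``
    plus nonbonded pairs within it."""
    sel = list(range(system.n_atoms)) if selection is None else sorted(selection)
    sel_set = set(sel)
    _require_params(system, sel)
    if exclusions is None:
        exclusions = exclusion_pairs(system)
    coords = system.coords
    out = MMTerms()

    for b in system.bonds:
        if b.force_k is None or b.i not in sel_set or b.j not in sel_set:
            continue
        r = float(np.linalg.norm(coords[b.i] - coords[b.j]))
        out.bond += b.force_k * (r - b.r0) ** 2
    for a in system.angles:
        if a.force_k is None or not {a.i, a.j, a.k} <= sel_set:
            continue
        out.angle += a.force_k * (_angle(coords, a.i, a.j, a.k) - np.radians(a.theta0)) ** 2
    for t in system.torsions:
        if t.force_k is None or not {t.i, t.j, t.k, t.l} <= sel_set:
            continue
        phi = _dihedral(coords, t.i, t.j, t.k, t.l)
        out.torsion += t.force_k * (1.0 + np.cos(t.periodicity * phi - np.radians(t.phase)))

    lj, elec = _nonbonded_pairs(system, sel, sel, cutoff, exclusions, same=True)
    out.lj = lj
    out.elec = elec
    return out


def mm_interaction(
    system: MolecularSystem,
    set_a: Sequence[int],
    set_b: Sequence[int],
    cutoff: float = constants.NB_CUTOFF,
    exclusions: Optional[set[tuple[int, int]]] = None,
) -> tuple[float, float]:
    """(vdW, electrostatic) interaction between two disjoint atom sets."""
    if set(set_a) & set(set_b):
        raise ConfigError("mm_interaction: atom sets overlap")
    _require_params(system, list(set_a) + list(set_b))
    if exclusions is None:
        exclusions = exclusion_pairs(system)
    return _nonbonded_pairs(system, list(set_a), list(set_b), cutoff, exclusions, same=False)


def _nonbonded_pairs(system, sel_a, sel_b, cutoff, exclusions, same: bool):
    if not sel_a or not sel_b:
        return 0.0, 0.0
    coords = system.coords
    eps = np.array([system.atoms[i].lj_epsilon for i in range(system.n_atoms)])
    rmh = np.array([system.atoms[i].lj_rmin_half for i in range(system.n_atoms)])
    q = system.charges

    ia = np.asarray(sel_a)
    ib = np.asarray(sel_b)
    if same:
        ii, jj = np.triu_indices(len(ia), k=1)
        pi, pj = ia[ii], ia[jj]
    else:
        pi = np.repeat(ia, len(ib))
        pj = np.tile(ib, len(ia))
    d = coords[pi] - coords[pj]
    r = np.sqrt(np.sum(d * d, axis=1))
    mask = r <= cutoff
    if exclusions:
        lo = np.minimum(pi, pj)
        hi = np.maximum(pi, pj)
        excl_mask = np.fromiter(
            ((int(a), int(b)) in exclusions for a, b in zip(lo, hi)),
            dtype=bool,
            count=len(lo),
        )
        mask &= ~excl_mask
    pi, pj, r = pi[mask], pj[mask], r[mask]
    if len(r) == 0:
        return 0.0, 0.0
    epsij = np.sqrt(eps[pi] * eps[pj])
    rmin = rmh[pi] + rmh[pj]
    sr6 = (rmin / r) ** 6
    lj = float(np.sum(epsij * (sr6 * sr6 - 2.0 * sr6)))
    elec = float(constants.COULOMB_KCAL * np.sum(q[pi] * q[pj] / r))
    return lj, elec


# ----------------------------------------------------------------------
# geometry helpers


def _angle(coords, i, j, k) -> float:
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _dihedral(coords, i, j, k, l) -> float:
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


# ----------------------------------------------------------------------
# analytic gradient of the MM terms


def mm_gradient(
    system: MolecularSystem,
    selection: Optional[Sequence[int]] = None,
    cutoff: float = constants.NB_CUTOFF,
    exclusions: Optional[set[tuple[int, int]]] = None,
) -> np.ndarray:
    """Analytic gradient (n_atoms, 3) of ``mm_terms(...).total``."""
    sel = list(range(system.n_atoms)) if selection is None else sorted(selection)
    sel_set = set(sel)
    _require_params(system, sel)
    if exclusions is None:
        exclusions = exclusion_pairs(system)
    coords = system.coords
    grad = np.zeros_like(coords)

    for b in system.bonds:
        if b.force_k is None or b.i not in sel_set or b.j not in sel_set:
            continue
        d = coords[b.i] - coords[b.j]
        r = float(np.linalg.norm(d))
        g = 2.0 * b.force_k * (r - b.r0) * d / r
        grad[b.i] += g
        grad[b.j] -= g

    for a in system.angles:
        if a.force_k is None or not {a.i, a.j, a.k} <= sel_set:
            continue
        _angle_gradient(coords, a, grad)

    for t in system.torsions:
        if t.force_k is None or not {t.i, t.j, t.k, t.l} <= sel_set:
            continue
        _torsion_gradient(coords, t, grad)

    _nonbonded_gradient(system, sel, sel, cutoff, exclusions, grad, same=True)
    return grad


def interaction_gradient(
    system: MolecularSystem,
    set_a: Sequence[int],
    set_b: Sequence[int],
    cutoff: float = constants.NB_CUTOFF,
    exclusions: Optional[set[tuple[int, int]]] = None,
) -> np.ndarray:
    if exclusions is None:
        exclusions = exclusion_pairs(system)
    grad = np.zeros((system.n_atoms, 3))
    _nonbonded_gradient(system, list(set_a), list(set_b), cutoff, exclusions, grad, same=False)
    return grad


def _angle_gradient(coords, a, grad) -> None:
    u = coords[a.i] - coords[a.j]
    v = coords[a.k] - coords[a.j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    s = np.sqrt(max(1.0 - c * c, 1e-12))
    theta = np.arccos(c)
    de = 2.0 * a.force_k * (theta - np.radians(a.theta0))
    dth_di = -(vh - c * uh) / (nu * s)
    dth_dk = -(uh - c * vh) / (nv * s)
    grad[a.i] += de * dth_di
    grad[a.k] += de * dth_dk
    grad[a.j] -= de * (dth_di + dth_dk)


def _torsion_gradient(coords, t, grad) -> None:
    b1 = coords[t.j] - coords[t.i]
    b2 = coords[t.k] - coords[t.j]
    b3 = coords[t.l] - coords[t.k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    if n1sq < 1e-12 or n2sq < 1e-12:
        return  # collinear; dihedral undefined, no force
    m = np.cross(n1, b2 / nb2)
    phi = float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    de = -t.force_k * t.periodicity * np.sin(t.periodicity * phi - np.radians(t.phase))
    # signs fixed by the atan2((n1 x b2_hat).n2, n1.n2) convention above
    dphi_di = nb2 / n1sq * n1
    dphi_dl = -nb2 / n2sq * n2
    f1 = float(np.dot(b1, b2)) / (nb2 * nb2)
    f3 = float(np.dot(b3, b2)) / (nb2 * nb2)
    dphi_dj = -(1.0 + f1) * dphi_di + f3 * dphi_dl
    dphi_dk = f1 * dphi_di - (1.0 + f3) * dphi_dl
    grad[t.i] += de * dphi_di
    grad[t.j] += de * dphi_dj
    grad[t.k] += de * dphi_dk
    grad[t.l] += de * dphi_dl


def _nonbonded_gradient(system, sel_a, sel_b, cutoff, exclusions, grad, same: bool):
    if not sel_a or not sel_b:
        return
    coords = system.coords
    eps = np.array([a.lj_epsilon if a.lj_epsilon is not None else 0.0 for a in system.atoms])
    rmh = np.array([a.lj_rmin_half if a.lj_rmin_half is not None else 0.0 for a in system.atoms])
    q = system.charges
    ia, ib = np.asarray(sel_a), np.asarray(sel_b)
    if same:
        ii, jj = np.triu_indices(len(ia), k=1)
        pi, pj = ia[ii], ia[jj]
    else:
        pi = np.repeat(ia, len(ib))
        pj = np.tile(ib, len(ia))
    d = coords[pi] - coords[pj]
    r = np.sqrt(np.sum(d * d, axis=1))
    mask = r <= cutoff
    if exclusions:
        lo, hi = np.minimum(pi, pj), np.maximum(pi, pj)
        excl_mask = np.fromiter(
            ((int(a), int(b)) in exclusions for a, b in zip(lo, hi)),
            dtype=bool,
            count=len(lo),
        )
        mask &= ~excl_mask
    pi, pj, d, r = pi[mask], pj[mask], d[mask], r[mask]
    if len(r) == 0:
        return
    epsij = np.sqrt(eps[pi] * eps[pj])
    rmin = rmh[pi] + rmh[pj]
    sr6 = (rmin / r) ** 6
    dlj = epsij * 12.0 * (sr6 - sr6 * sr6) / r
    delec = -constants.COULOMB_KCAL * q[pi] * q[pj] / (r * r)
    dtotal = (dlj + delec) / r  # dE/dr * 1/r, times d gives the vector
    np.add.at(grad, pi, dtotal[:, None] * d)
    np.add.at(grad, pj, -dtotal[:, None] * d)


# ----------------------------------------------------------------------
# solvation surrogate


def born_radii_hct(
    coords: np.ndarray, rho: np.ndarray, cutoff: Optional[float] = None
) -> np.ndarray:
    """Hawkins-Cramer-Truhlar pairwise-descreening effective Born radii."""
    coords = np.asarray(coords, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n = len(rho)
    if n == 1:
        return rho.copy()
    diff = coords[:, None, :] - coords[None, :, :]
    rij = np.sqrt(np.sum(diff * diff, axis=-1))
    sj = rho[None, :]
    ri = rho[:, None]
    eye = np.eye(n, dtype=bool)
    active = ~eye
    if cutoff is not None:
        active &= rij <= cutoff
    active &= rij + sj > ri  # atom i fully engulfed in j's sphere: skip pair
    rij = np.where(active, rij, 1.0)  # placeholder to avoid divide warnings
    lij = np.where(rij >= ri + sj, rij - sj, ri)
    uij = rij + sj
    active &= lij < uij
    lij = np.where(active, lij, 1.0)
    uij = np.where(active, uij, 2.0)
    term = 0.5 * (
        1.0 / lij
        - 1.0 / uij
        + 0.25 * rij * (1.0 / uij**2 - 1.0 / lij**2)
        + 0.5 / rij * np.log(lij / uij)
        + 0.25 * sj * sj / rij * (1.0 / lij**2 - 1.0 / uij**2)
    )
    acc = np.sum(np.where(active, term, 0.0), axis=1)
    inv_r = np.maximum(1.0 / rho - acc, 1e-3)
    return 1.0 / inv_r


def gb_polar_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    born_r: np.ndarray,
    eps_in: float = constants.DIELECTRIC_SOLUTE,
    eps_out: float = constants.DIELECTRIC_SOLVENT,
    cutoff: Optional[float] = constants.NB_CUTOFF,
) -> float:
    """Still-style GB polar solvation energy (kcal/mol, <= 0 for one charge)."""
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    tau = 1.0 / eps_in - 1.0 / eps_out
    e = float(np.sum(q * q / born_r)) * 0.5  # self terms
    n = len(q)
    if n > 1:
        ii, jj = np.triu_indices(n, k=1)
        d = coords[ii] - coords[jj]
        r2 = np.sum(d * d, axis=1)
        if cutoff is not None:
            keep = r2 <= cutoff * cutoff
            ii, jj, r2 = ii[keep], jj[keep], r2[keep]
        a = born_r[ii] * born_r[jj]
        fgb = np.sqrt(r2 + a * np.exp(-r2 / (4.0 * a)))
        e += float(np.sum(q[ii] * q[jj] / fgb))
    return -constants.COULOMB_KCAL * tau * e


def gb_polar_gradient(
    coords: np.ndarray,
    charges: np.ndarray,
    born_r: np.ndarray,
    eps_in: float = constants.DIELECTRIC_SOLUTE,
    eps_out: float = constants.DIELECTRIC_SOLVENT,
    cutoff: Optional[float] = constants.NB_CUTOFF,
) -> np.ndarray:
    """Gradient of the GB pair term with Born radii held fixed.

    Neglecting the radii derivative is a documented approximation; the
    optimizer only uses this as a search direction and verifies descent
    on the exact energy.
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    tau = 1.0 / eps_in - 1.0 / eps_out
    grad = np.zeros_like(coords)
    n = len(q)
    if n < 2:
        return grad
    ii, jj = np.triu_indices(n, k=1)
    d = coords[ii] - coords[jj]
    r2 = np.sum(d * d, axis=1)
    if cutoff is not None:
        keep = r2 <= cutoff * cutoff
        ii, jj, d, r2 = ii[keep], jj[keep], d[keep], r2[keep]
    a = born_r[ii] * born_r[jj]
    expo = np.exp(-r2 / (4.0 * a))
    fgb2 = r2 + a * expo
    fgb = np.sqrt(fgb2)
    # dE/d(r^2) = k*tau*qiqj/(2 fgb^3) * d(fgb^2)/d(r^2); d(fgb^2)/d(r^2) = 1 - expo/4
    coef = constants.COULOMB_KCAL * tau * q[ii] * q[jj] / (2.0 * fgb2 * fgb) * (1.0 - expo / 4.0)
    vec = coef[:, None] * 2.0 * d
    np.add.at(grad, ii, vec)
    np.add.at(grad, jj, -vec)
    return grad


_SPHERE_CACHE: dict[int, np.ndarray] = {}


def unit_sphere_points(n: int = 240) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    if n not in _SPHERE_CACHE:
        k = np.arange(n, dtype=float)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * k
        z = 1.0 - 2.0 * (k + 0.5) / n
        rho = np.sqrt(1.0 - z * z)
        _SPHERE_CACHE[n] = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return _SPHERE_CACHE[n]


def sasa_shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = constants.PROBE_RADIUS,
    n_points: int = 240,
) -> float:
    """Total solvent-accessible surface area by sphere point sampling (A^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    n = len(radii)
    pts = unit_sphere_points(n_points)
    total = 0.0
    for i in range(n):
        ri = radii[i]
        d = coords - coords[i]
        dist = np.sqrt(np.sum(d * d, axis=1))
        nbr = np.where((dist < ri + radii) & (np.arange(n) != i))[0]
        if len(nbr) == 0:
            total += 4.0 * np.pi * ri * ri
            continue
        surf = coords[i] + ri * pts
        diff = surf[:, None, :] - coords[nbr][None, :, :]
        buried = np.any(
            np.sum(diff * diff, axis=2) < (radii[nbr] ** 2)[None, :], axis=1
        )
        frac = 1.0 - np.count_nonzero(buried) / n_points
        total += 4.0 * np.pi * ri * ri * frac
    return float(total)


def gb_sa_solvation(
    system: MolecularSystem,
    charges: Sequence[float],
    dielectric_solute: float = constants.DIELECTRIC_SOLUTE,
    dielectric_solvent: float = constants.DIELECTRIC_SOLVENT,
    gamma: float = constants.SURFACE_TENSION,
    probe: float = constants.PROBE_RADIUS,
    cutoff: float = constants.NB_CUTOFF,
) -> tuple[float, float]:
    """(polar, nonpolar) solvation energy of the whole system.

    The charge vector is an explicit argument so the primary-system
    charges can be force-field charges or QM-derived ones.
    """
    if gamma < 0:
        raise ConfigError("nonpolar surface tension gamma must be >= 0")
    charges = np.asarray(charges, dtype=float)
    if len(charges) != system.n_atoms:
        raise ConfigError(
            f"charge vector length {len(charges)} != atom count {system.n_atoms}"
        )
    _require_params(system, range(system.n_atoms))
    coords = system.coords
    rho = np.array(
        [max(a.lj_rmin_half, constants.MIN_BORN_RADIUS) for a in system.atoms]
    )
    if np.any(charges != 0.0):
        born = born_radii_hct(coords, rho, cutoff=cutoff)
        g_elec = gb_polar_energy(
            coords, charges, born, dielectric_solute, dielectric_solvent, cutoff
        )
    else:
        g_elec = 0.0
    g_np = gamma * sasa_shrake_rupley(coords, rho, probe)
    return g_elec, g_np


# ----------------------------------------------------------------------
# secondary-system self-repulsion and metal potential


def ss_self_repulsion(
    positions: np.ndarray, charges: Sequence[float]
) -> float:
    """Coulomb energy among the embedding charges themselves.

    Subtracted a posteriori from hybrid scores when the QM engine folds
    this term into its energy (HF/DFT-like behavior).
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    q = np.asarray(charges, dtype=float)
    n = len(q)
    if n < 2:
        return 0.0
    ii, jj = np.triu_indices(n, k=1)
    d = positions[ii] - positions[jj]
    r = np.sqrt(np.sum(d * d, axis=1))
    if np.any(r < 1e-9):
        raise SingularityError("two embedding charges at identical positions")
    return float(constants.COULOMB_KCAL * np.sum(q[ii] * q[jj] / r))


def mmbp_energy(r: float, D: float, a: float, r0: float) -> float:
    """Morse-like metal binding potential: D*(1-exp(-a*(r-r0)))**2 - D."""
    if D <= 0 or a <= 0 or r0 <= 0:
        raise ConfigError("MMBP parameters D, a, r0 must all be positive")
    return D * (1.0 - np.exp(-a * (r - r0))) ** 2 - D


def mmbp_total(
    system: MolecularSystem,
    params: dict,
    ligand_idx: Optional[Sequence[int]] = None,
) -> float:
    """Sum MMBP over metal / ligand-heavy-atom pairs with configured types.

    ``params`` maps ``"<METAL>-<ELEMENT>"`` (e.g. ``"FE-N"``) to
    ``{"D": ..., "a": ..., "r0": ...}``. Parameter values are user
    configuration, never defaults.
    """
    if not params or not system.metals:
        return 0.0
    lig = system.ligand_idx if ligand_idx is None else list(ligand_idx)
    coords = system.coords
    total = 0.0
    for m in system.metals:
        mel = system.atoms[m].element.upper()
        for i in lig:
            el = system.atoms[i].element.upper()
            if el == "H":
                continue
            entry = params.get(f"{mel}-{el}")
            if entry is None:
                continue
            r = float(np.linalg.norm(coords[m] - coords[i]))
            total += mmbp_energy(r, entry["D"], entry["a"], entry["r0"])
    return total


def coulomb_point_sets(
    pos_a: np.ndarray,
    q_a: Sequence[float],
    pos_b: np.ndarray,
    q_b: Sequence[float],
) -> float:
    """Plain Coulomb energy between two point-charge sets (no cutoff)."""
    pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 3)
    pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 3)
    qa = np.asarray(q_a, dtype=float)
    qb = np.asarray(q_b, dtype=float)
    if len(qa) == 0 or len(qb) == 0:
        return 0.0
    d = pos_a[:, None, :] - pos_b[None, :, :]
    r = np.sqrt(np.sum(d * d, axis=-1))
    if np.any(r < 1e-9):
        raise SingularityError("point charges from the two sets coincide")
    return float(constants.COULOMB_KCAL * np.sum(qa[:, None] * qb[None, :] / r))
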