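"""Hybrid scoring pipeline: subtractive QM/MM energy, classical and
hybrid scores, pose clustering, selection, optimization, refinement.

The subtractive total is

    E_hybrid = E_QM(PS) + E_QM_elec(PS<->SS) + E_MM(Complex)
               - E_MM(PS) - E_MM_elec(PS<->SS)

with the embedding self-repulsion subtracted additionally when the
engine folds it into its energy. ``E_MM(Complex)`` is referenced to the
(constant) internal energy of the rigid receptor, so for a rigid
receptor it reduces to the classical interaction + intra-ligand energy;
``E_MM(PS)`` is evaluated on the extracted capped subsystem with the
same conventions the mirror engine uses, which makes the mirror-engine
pipeline cancel term by term against the classical score.

Scores (kcal/mol):

    Score_class = E_intra(Lig) + E_intra(Rec_flex) + E_vdW(Lig<->Rec)
                  + E_elec(Lig<->Rec) + dG_solv_elec + dG_solv_np
                  [+ E_MMBP]
    Score_hybrid = E_hybrid + dG_solv_elec + dG_solv_np
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from qmmdock import constants
from qmmdock.energetics import (
    EnergyBreakdown,
    exclusion_pairs,
    gb_polar_energy,
    gb_polar_gradient,
    born_radii_hct,
    interaction_gradient,
    mm_gradient,
    mm_interaction,
    mm_terms,
    mmbp_total,
    sasa_shrake_rupley,
    ss_self_repulsion,
    coulomb_point_sets,
)
from qmmdock.errors import ConfigError, ConvergenceError, QmmdockError
from qmmdock.evaluation import ligand_graph, symmetry_rmsd
from qmmdock.molecular_model.types import MolecularSystem, plain_rmsd
from qmmdock.partitioning import (
    Partition,
    PSGeometry,
    extract_ps_geometry,
    refresh_geometry,
)
from qmmdock.qm_engines import QMEngine, QMEngineSpec, QMResult, get_engine

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# pose containers


@dataclass
class Pose:
    """Coordinates of the movable atoms plus bookkeeping."""

    coords: np.ndarray
    movable: tuple[int, ...]
    score_class: Optional[float] = None
    score_qmmm: Optional[float] = None
    breakdown: Optional[EnergyBreakdown] = None
    rmsd_to_native: Optional[float] = None
    provenance: str = "sampled"
    converged: bool = True
    n_steps: int = 0
    index: Optional[int] = None
    trajectory: Optional[list] = None  # accepted-step energies, optimizer output

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.movable = tuple(int(i) for i in self.movable)
        if len(self.movable) != len(self.coords):
            raise QmmdockError("pose coords and movable index count differ")
        if self.rmsd_to_native is not None and self.rmsd_to_native < 0:
            raise QmmdockError("rmsd_to_native must be >= 0")

    @property
    def score(self) -> float:
        """Ranking score: hybrid when present, classical otherwise."""
        if not self.converged:
            return math.inf
        if self.score_qmmm is not None:
            return self.score_qmmm
        if self.score_class is not None:
            return self.score_class
        return math.inf

    def copy(self) -> "Pose":
        return Pose(
            coords=self.coords.copy(),
            movable=self.movable,
            score_class=self.score_class,
            score_qmmm=self.score_qmmm,
            breakdown=self.breakdown,
            rmsd_to_native=self.rmsd_to_native,
            provenance=self.provenance,
            converged=self.converged,
            n_steps=self.n_steps,
            index=self.index,
        )


@dataclass
class Cluster:
    members: list[Pose] = field(default_factory=list)

    @property
    def representative(self) -> Pose:
        return self.members[0]

    @property
    def size(self) -> int:
        return len(self.members)


def make_pose(system: MolecularSystem, movable: Optional[Sequence[int]] = None,
              provenance: str = "sampled", index: Optional[int] = None) -> Pose:
    movable = system.ligand_idx if movable is None else sorted(movable)
    return Pose(
        coords=system.coords[list(movable)],
        movable=tuple(movable),
        provenance=provenance,
        index=index,
    )


def apply_pose(system: MolecularSystem, pose: Pose) -> None:
    """Write the pose coordinates into the system (in place)."""
    coords = system.coords
    coords[list(pose.movable)] = pose.coords
    system.set_coords(coords)


def pose_ligand_heavy_coords(system: MolecularSystem, pose: Pose) -> np.ndarray:
    heavy = system.heavy_idx(system.ligand_idx)
    pos_of = {idx: k for k, idx in enumerate(pose.movable)}
    missing = [i for i in heavy if i not in pos_of]
    if missing:
        raise QmmdockError("pose does not move all ligand heavy atoms")
    return pose.coords[[pos_of[i] for i in heavy]]


# ----------------------------------------------------------------------
# solvation settings


@dataclass
class SolvationConfig:
    dielectric_solute: float = constants.DIELECTRIC_SOLUTE
    dielectric_solvent: float = constants.DIELECTRIC_SOLVENT
    gamma: float = constants.SURFACE_TENSION
    probe: float = constants.PROBE_RADIUS
    enabled: bool = True


def _solvation(system: MolecularSystem, charges: np.ndarray, solv: SolvationConfig,
               cutoff: float) -> tuple[float, float]:
    if not solv.enabled:
        return 0.0, 0.0
    from qmmdock.energetics import gb_sa_solvation

    return gb_sa_solvation(
        system,
        charges,
        dielectric_solute=solv.dielectric_solute,
        dielectric_solvent=solv.dielectric_solvent,
        gamma=solv.gamma,
        probe=solv.probe,
        cutoff=cutoff,
    )


# ----------------------------------------------------------------------
# classical score


def score_classical(
    system: MolecularSystem,
    pose: Optional[Pose] = None,
    flexible: Sequence[int] = (),
    solv: Optional[SolvationConfig] = None,
    mmbp_params: Optional[dict] = None,
    cutoff: float = constants.NB_CUTOFF,
) -> tuple[float, EnergyBreakdown]:
    """MM-GBSA-style score of the current (or posed) geometry."""
    work = system
    if pose is not None:
        work = system.copy()
        apply_pose(work, pose)
    solv = solv or SolvationConfig()
    lig = work.ligand_idx
    rec = work.receptor_idx
    flex = sorted(flexible)
    rigid = [i for i in rec if i not in set(flex)]
    excl = exclusion_pairs(work)

    bd = EnergyBreakdown()
    bd.e_intra_lig = mm_terms(work, lig, cutoff, excl).total + _spanning_bonded(
        work, set(lig)
    )
    if flex:
        bd.e_intra_recflex = mm_terms(work, flex, cutoff, excl).total
        vdw_f, elec_f = mm_interaction(work, flex, rigid, cutoff, excl)
        bd.e_intra_recflex += vdw_f + elec_f
    vdw, elec = mm_interaction(work, lig, rec, cutoff, excl)
    bd.e_vdw_lig_rec = vdw
    bd.e_elec_lig_rec = elec
    bd.g_solv_elec, bd.g_solv_np = _solvation(work, work.charges, solv, cutoff)
    if mmbp_params:
        bd.e_mmbp = mmbp_total(work, mmbp_params)
    return bd.score_class, bd


def _spanning_bonded(system: MolecularSystem, set_a: set[int]) -> float:
    """Bonded terms that straddle the ligand/receptor split (covalent anchor)."""
    total = 0.0
    coords = system.coords
    for b in system.bonds:
        if b.force_k is None:
            continue
        ins = (b.i in set_a) + (b.j in set_a)
        if ins == 1:
            r = float(np.linalg.norm(coords[b.i] - coords[b.j]))
            total += b.force_k * (r - b.r0) ** 2
    for a in system.angles:
        if a.force_k is None:
            continue
        ins = sum(x in set_a for x in (a.i, a.j, a.k))
        if 0 < ins < 3:
            from qmmdock.energetics import _angle

            total += a.force_k * (_angle(coords, a.i, a.j, a.k) - np.radians(a.theta0)) ** 2
    for t in system.torsions:
        if t.force_k is None:
            continue
        ins = sum(x in set_a for x in (t.i, t.j, t.k, t.l))
        if 0 < ins < 4:
            from qmmdock.energetics import _dihedral

            phi = _dihedral(coords, t.i, t.j, t.k, t.l)
            total += t.force_k * (1.0 + np.cos(t.periodicity * phi - np.radians(t.phase)))
    return total


# ----------------------------------------------------------------------
# hybrid score


def qmmm_energy(
    partition: Partition,
    qm: QMResult,
    system: MolecularSystem,
    spec: QMEngineSpec,
    ps_geometry: Optional[PSGeometry] = None,
    flexible: Sequence[int] = (),
    cutoff: float = constants.NB_CUTOFF,
    exclusions: Optional[set[tuple[int, int]]] = None,
) -> EnergyBreakdown:
    """Fill the subtractive-scheme terms of an :class:`EnergyBreakdown`.

    Raises :class:`ConvergenceError` for a non-converged QM result; the
    caller scores such poses as +inf and logs the failure.
    """
    if not qm.converged:
        raise ConvergenceError("QM result not converged; pose scored as +inf")
    if ps_geometry is None:
        ps_geometry = extract_ps_geometry(system, partition)

    bd = EnergyBreakdown()
    bd.e_qm_ps = qm.e_qm_ps
    bd.e_qm_elec_ps_ss = qm.e_qm_elec_ps_ss

    lig = system.ligand_idx
    rec = system.receptor_idx
    flex = sorted(flexible)
    rigid = [i for i in rec if i not in set(flex)]
    excl = exclusion_pairs(system) if exclusions is None else exclusions
    bd.e_intra_lig = mm_terms(system, lig, cutoff, excl).total + _spanning_bonded(
        system, set(lig)
    )
    if flex:
        bd.e_intra_recflex = mm_terms(system, flex, cutoff, excl).total
        vdw_f, elec_f = mm_interaction(system, flex, rigid, cutoff, excl)
        bd.e_intra_recflex += vdw_f + elec_f
    vdw, elec = mm_interaction(system, lig, rec, cutoff, excl)
    bd.e_vdw_lig_rec = vdw
    bd.e_elec_lig_rec = elec
    bd.e_mm_complex = (
        bd.e_intra_lig + bd.e_intra_recflex + bd.e_vdw_lig_rec + bd.e_elec_lig_rec
    )

    bd.e_mm_ps = mm_terms(ps_geometry.subsystem, cutoff=cutoff).total
    pos, q = partition.embedding_arrays()
    ps_charges = ps_geometry.subsystem.charges
    bd.e_mm_elec_ps_ss = (
        coulomb_point_sets(ps_geometry.coords, ps_charges, pos, q) if len(q) else 0.0
    )
    if spec.includes_ss_self_energy and len(q):
        bd.ss_self_correction = ss_self_repulsion(pos, q)
    return bd


def solvation_charge_vector(
    system: MolecularSystem,
    partition: Partition,
    qm: QMResult,
    ps_geometry: PSGeometry,
    charge_source: str = "ff",
) -> np.ndarray:
    """Charges used for solvation: FF everywhere, PS replaced by
    QM-derived charges when requested (link-atom charge folded into its
    host atom)."""
    if charge_source not in ("ff", "qm-derived"):
        raise ConfigError(f"unknown charge_source {charge_source!r}")
    q = system.charges
    if charge_source == "ff":
        return q
    q = q.copy()
    for local, parent in enumerate(ps_geometry.index_map):
        q[parent] = qm.qm_charges[local]
    for k, link in enumerate(partition.link_atoms):
        q[link.qm_host] += qm.qm_charges[ps_geometry.n_real + k]
    return q


def score_qmmm(
    partition: Partition,
    qm: QMResult,
    system: MolecularSystem,
    spec: QMEngineSpec,
    charge_source: str = "ff",
    ps_geometry: Optional[PSGeometry] = None,
    flexible: Sequence[int] = (),
    solv: Optional[SolvationConfig] = None,
    cutoff: float = constants.NB_CUTOFF,
) -> tuple[float, EnergyBreakdown]:
    """Hybrid score = subtractive energy + solvation terms."""
    if ps_geometry is None:
        ps_geometry = extract_ps_geometry(system, partition)
    bd = qmmm_energy(
        partition, qm, system, spec, ps_geometry, flexible=flexible, cutoff=cutoff
    )
    solv = solv or SolvationConfig()
    charges = solvation_charge_vector(system, partition, qm, ps_geometry, charge_source)
    bd.g_solv_elec, bd.g_solv_np = _solvation(system, charges, solv, cutoff)
    return bd.score_qmmm, bd


# ----------------------------------------------------------------------
# clustering and selection


def cluster_poses(
    poses: Sequence[Pose],
    system: MolecularSystem,
    radius: float = constants.CLUSTER_RADIUS,
) -> list[Cluster]:
    """Greedy leader clustering by ascending score.

    A pose joins the first cluster whose representative lies within
    ``radius`` (symmetry-adapted RMSD); otherwise it founds a new
    cluster. Clusters come out ordered by representative score.
    """
    if not poses:
        return []
    graph = ligand_graph(system)
    order = sorted(
        range(len(poses)),
        key=lambda k: (poses[k].score, poses[k].index if poses[k].index is not None else k),
    )
    clusters: list[Cluster] = []
    for k in order:
        pose = poses[k]
        coords = pose_ligand_heavy_coords(system, pose)
        placed = False
        for cl in clusters:
            rep = pose_ligand_heavy_coords(system, cl.representative)
            if symmetry_rmsd(coords, rep, graph) <= radius:
                cl.members.append(pose)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(members=[pose]))
    return clusters


def select_for_qmmm(
    clusters: Sequence[Cluster],
    mode: str = "best_of_n",
    n: int = 10,
    native: Optional[Pose] = None,
) -> list[Pose]:
    """Pick the poses handed to the hybrid stage.

    ``best_of_n``: representatives of the n best clusters;
    ``all_of_n``: every member of the n best clusters. A provided
    (relaxed) native pose is appended unless a selected pose already
    sits within 0.01 A of it.
    """
    if n < 1:
        raise ConfigError("selection size n must be >= 1")
    if mode not in ("best_of_n", "all_of_n"):
        raise ConfigError(f"unknown selection mode {mode!r}")
    top = list(clusters)[: n]
    if mode == "best_of_n":
        selected = [cl.representative for cl in top]
    else:
        selected = [p for cl in top for p in cl.members]
    if native is not None:
        dup = any(
            p.coords.shape == native.coords.shape
            and plain_rmsd(p.coords, native.coords) <= 0.01
            for p in selected
        )
        if not dup:
            selected = selected + [native]
    return selected


# ----------------------------------------------------------------------
# optimizer


@dataclass
class OptResult:
    x: np.ndarray
    energy: float
    trajectory: list[float]
    converged: bool
    n_steps: int


def minimize_bfgs(
    f: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    conv: float,
    max_steps: int,
    max_step_norm: float = 0.5,
    grad_fallback: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> OptResult:
    """Quasi-Newton (BFGS) with backtracking line search on the exact
    objective; accepted steps never increase the energy.

    ``grad_fallback`` (typically exact finite differences) is consulted
    once whenever the primary gradient stops producing descent, so an
    approximate primary gradient cannot stall the search early.
    """
    if conv <= 0:
        raise ConfigError("convergence criterion must be > 0")
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    H = np.eye(n)
    e = f(x)
    g = grad(x)
    trajectory = [e]
    converged = False
    steps = 0
    used_fallback = False
    for _ in range(max_steps):
        p = -H @ g
        if float(np.dot(p, g)) >= 0.0:
            H = np.eye(n)
            p = -g
        pnorm = float(np.linalg.norm(p))
        if pnorm < 1e-12:
            converged = True
            break
        t = min(1.0, max_step_norm / pnorm)
        slope = float(np.dot(g, p))
        accepted = False
        for _ in range(30):
            x_new = x + t * p
            e_new = f(x_new)
            if e_new <= e + 1e-4 * t * slope and e_new < e:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            if grad_fallback is not None and not used_fallback:
                used_fallback = True
                g = grad_fallback(x)
                H = np.eye(n)
                continue
            converged = True  # no descent direction improves: local minimum
            break
        used_fallback = False
        g_new = grad(x_new)
        s = x_new - x
        y = g_new - g
        sy = float(np.dot(s, y))
        if sy > 1e-10:
            rho = 1.0 / sy
            I = np.eye(n)
            V = I - rho * np.outer(s, y)
            H = V @ H @ V.T + rho * np.outer(s, s)
        de = e - e_new
        x, e, g = x_new, e_new, g_new
        trajectory.append(e)
        steps += 1
        if de < conv:
            converged = True
            break
    else:
        converged = False
    return OptResult(x=x, energy=e, trajectory=trajectory, converged=converged, n_steps=steps)


class HybridObjective:
    """score_qmmm as a function of the movable coordinates.

    Rebuilds link-atom and embedding positions at every evaluation.
    The gradient is analytic on the mirror-engine fast path (MM terms +
    frozen-radii GB, zero SASA contribution) and falls back to central
    finite differences otherwise; descent is always verified on the
    exact objective by the line search.
    """

    def __init__(
        self,
        system: MolecularSystem,
        partition: Partition,
        engine: QMEngine,
        spec: QMEngineSpec,
        movable: Sequence[int],
        charge_source: str = "ff",
        flexible: Sequence[int] = (),
        solv: Optional[SolvationConfig] = None,
        cutoff: float = constants.NB_CUTOFF,
        reevaluate_solvation: bool = True,
        fd_step: float = 1e-4,
    ) -> None:
        self.system = system.copy()
        self.partition = partition
        self.engine = engine
        self.spec = spec
        self.movable = list(movable)
        self.charge_source = charge_source
        self.flexible = list(flexible)
        self.solv = solv or SolvationConfig()
        self.cutoff = cutoff
        self.reevaluate_solvation = reevaluate_solvation
        self.fd_step = fd_step
        self._frozen_solv: Optional[tuple[float, float]] = None
        self.last_breakdown: Optional[EnergyBreakdown] = None
        self.last_good_x: Optional[np.ndarray] = None
        self._excl = exclusion_pairs(self.system)
        self._use_analytic = (
            engine.provides_gradient
            and isinstance(engine, _analytic_ok_types())
        )

    # -- state -----------------------------------------------------------
    def _apply(self, x: np.ndarray) -> None:
        coords = self.system.coords
        coords[self.movable] = x.reshape(-1, 3)
        self.system.set_coords(coords)
        refresh_geometry(self.partition, self.system)

    # -- energy ----------------------------------------------------------
    def __call__(self, x: np.ndarray) -> float:
        self._apply(x)
        ps_geom = extract_ps_geometry(self.system, self.partition)
        qm = self.engine.compute(
            ps_geom, self.partition.embedding_arrays(), self.spec
        )
        if not qm.converged:
            raise ConvergenceError("engine failed during optimization")
        self.last_good_x = x.copy()
        bd = qmmm_energy(
            self.partition, qm, self.system, self.spec, ps_geom,
            flexible=self.flexible, cutoff=self.cutoff, exclusions=self._excl,
        )
        if self.reevaluate_solvation or self._frozen_solv is None:
            charges = solvation_charge_vector(
                self.system, self.partition, qm, ps_geom, self.charge_source
            )
            solv_pair = _solvation(self.system, charges, self.solv, self.cutoff)
            if not self.reevaluate_solvation:
                self._frozen_solv = solv_pair
        else:
            solv_pair = self._frozen_solv
        bd.g_solv_elec, bd.g_solv_np = solv_pair
        self.last_breakdown = bd
        return bd.score_qmmm

    # -- gradient --------------------------------------------------------
    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self._use_analytic:
            return self._analytic_gradient(x)
        return self._numerical_gradient(x)

    def _analytic_gradient(self, x: np.ndarray) -> np.ndarray:
        # mirror engine: hybrid energy == e_mm_complex, so differentiate
        # the classical terms directly (GB with frozen radii; SASA ~ 0).
        self._apply(x)
        sys_ = self.system
        lig = sys_.ligand_idx
        rec = sys_.receptor_idx
        grad = mm_gradient(sys_, lig, self.cutoff, self._excl)
        grad += interaction_gradient(sys_, lig, rec, self.cutoff, self._excl)
        grad += _spanning_bonded_gradient(sys_, set(lig))
        if self.flexible:
            rigid = [i for i in rec if i not in set(self.flexible)]
            grad += mm_gradient(sys_, self.flexible, self.cutoff, self._excl)
            grad += interaction_gradient(sys_, self.flexible, rigid, self.cutoff, self._excl)
        if self.solv.enabled and self.reevaluate_solvation:
            coords = sys_.coords
            charges = sys_.charges
            if np.any(charges != 0.0):
                rho = np.array(
                    [max(a.lj_rmin_half, constants.MIN_BORN_RADIUS) for a in sys_.atoms]
                )
                born = born_radii_hct(coords, rho, cutoff=self.cutoff)
                grad += gb_polar_gradient(
                    coords, charges, born,
                    self.solv.dielectric_solute, self.solv.dielectric_solvent,
                    self.cutoff,
                )
        return grad[self.movable].ravel()

    def _numerical_gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        for k in range(x.size):
            xp = x.copy()
            xp[k] += self.fd_step
            xm = x.copy()
            xm[k] -= self.fd_step
            g[k] = (self(xp) - self(xm)) / (2.0 * self.fd_step)
        return g


def _analytic_ok_types():
    from qmmdock.qm_engines import MirrorMMEngine

    return MirrorMMEngine


def _spanning_bonded_gradient(system: MolecularSystem, set_a: set[int]) -> np.ndarray:
    from qmmdock.energetics import _angle_gradient, _torsion_gradient

    coords = system.coords
    grad = np.zeros_like(coords)
    for b in system.bonds:
        if b.force_k is None:
            continue
        if (b.i in set_a) + (b.j in set_a) == 1:
            d = coords[b.i] - coords[b.j]
            r = float(np.linalg.norm(d))
            g = 2.0 * b.force_k * (r - b.r0) * d / r
            grad[b.i] += g
            grad[b.j] -= g
    for a in system.angles:
        if a.force_k is None:
            continue
        ins = sum(x in set_a for x in (a.i, a.j, a.k))
        if 0 < ins < 3:
            _angle_gradient(coords, a, grad)
    for t in system.torsions:
        if t.force_k is None:
            continue
        ins = sum(x in set_a for x in (t.i, t.j, t.k, t.l))
        if 0 < ins < 4:
            _torsion_gradient(coords, t, grad)
    return grad


def optimize_pose(
    system: MolecularSystem,
    partition: Partition,
    pose: Pose,
    engine: Optional[QMEngine] = None,
    spec: Optional[QMEngineSpec] = None,
    dof: str = "ligand_only",
    conv: float = constants.DEFAULT_CONV,
    max_steps: int = constants.DEFAULT_MAX_STEPS,
    charge_source: str = "ff",
    flexible: Sequence[int] = (),
    solv: Optional[SolvationConfig] = None,
    cutoff: float = constants.NB_CUTOFF,
    reevaluate_solvation: bool = True,
) -> Pose:
    """Local minimization of the hybrid score over the chosen coordinates."""
    if conv <= 0:
        raise ConfigError("convergence criterion must be > 0")
    if dof not in ("ligand_only", "full_ps"):
        raise ConfigError(f"unknown dof {dof!r}")
    spec = spec or QMEngineSpec()
    engine = engine or get_engine(spec.method)
    movable = (
        system.ligand_idx if dof == "ligand_only" else sorted(partition.ps_atoms)
    )
    # receptor atoms that move count as flexible receptor in the MM terms
    flex = sorted(
        set(flexible)
        | {i for i in movable if not system.atoms[i].is_ligand}
    )
    flexible = flex

    work = system.copy()
    apply_pose(work, pose)
    objective = HybridObjective(
        work, partition, engine, spec, movable,
        charge_source=charge_source, flexible=flexible, solv=solv,
        cutoff=cutoff, reevaluate_solvation=reevaluate_solvation,
    )
    x0 = work.coords[movable].ravel()
    fallback = objective._numerical_gradient if objective._use_analytic else None
    try:
        result = minimize_bfgs(objective, objective.gradient, x0, conv, max_steps,
                               grad_fallback=fallback)
        converged = result.converged
        x_final = result.x
        n_steps = result.n_steps
        energy = result.energy
    except ConvergenceError:
        logger.warning("engine failure mid-trajectory; returning last good pose")
        if objective.last_good_x is not None:
            coords = objective.last_good_x.reshape(-1, 3)
        else:
            coords = work.coords[movable]
        return Pose(
            coords=coords,
            movable=tuple(movable),
            provenance="optimized",
            converged=False,
            index=pose.index,
        )

    final = objective(x_final)  # refresh breakdown at the endpoint
    bd = objective.last_breakdown
    out = Pose(
        coords=x_final.reshape(-1, 3),
        movable=tuple(movable),
        score_qmmm=final,
        breakdown=bd,
        provenance="optimized",
        converged=converged,
        n_steps=n_steps,
        index=pose.index,
        trajectory=list(result.trajectory),
    )
    assert abs(final - energy) < 1e-9
    return out


def relax_native(
    system: MolecularSystem,
    partition: Partition,
    native: Pose,
    engine: Optional[QMEngine] = None,
    spec: Optional[QMEngineSpec] = None,
    max_steps: int = 50,
    **kwargs,
) -> Pose:
    """Short ligand-only relaxation of the experimental pose."""
    out = optimize_pose(
        system, partition, native, engine=engine, spec=spec,
        dof="ligand_only", max_steps=max_steps, **kwargs,
    )
    out.provenance = "native-relaxed"
    return out


def refine(
    poses: Sequence[Pose],
    system: MolecularSystem,
    partition: Partition,
    engine2: QMEngine,
    spec2: QMEngineSpec,
    mode: str = "single_point",
    charge_source: str = "ff",
    flexible: Sequence[int] = (),
    solv: Optional[SolvationConfig] = None,
    cutoff: float = constants.NB_CUTOFF,
    conv: float = constants.DEFAULT_CONV,
    max_steps: int = 25,
) -> dict:
    """Rescore (or shortly re-optimize) poses at a second level of theory.

    Returns ``{"poses": rescored, "ranked": converged sorted by score,
    "conv_fraction": ...}``; when nothing converges, ``ranked`` is empty
    and ``status`` says so.
    """
    if mode not in ("single_point", "optimize"):
        raise ConfigError(f"unknown refinement mode {mode!r}")
    rescored: list[Pose] = []
    for pose in poses:
        if mode == "single_point":
            work = system.copy()
            apply_pose(work, pose)
            refresh_geometry(partition, work)
            ps_geom = extract_ps_geometry(work, partition)
            try:
                qm = engine2.compute(ps_geom, partition.embedding_arrays(), spec2)
                if not qm.converged:
                    raise ConvergenceError("refinement engine did not converge")
                score, bd = score_qmmm(
                    partition, qm, work, spec2, charge_source=charge_source,
                    ps_geometry=ps_geom, flexible=flexible, solv=solv, cutoff=cutoff,
                )
                new = pose.copy()
                new.score_qmmm = score
                new.breakdown = bd
                new.provenance = "refined"
                new.converged = True
            except (ConvergenceError, QmmdockError):
                new = pose.copy()
                new.converged = False
                new.score_qmmm = None
                new.provenance = "refined"
        else:
            new = optimize_pose(
                system, partition, pose, engine=engine2, spec=spec2,
                conv=conv, max_steps=max_steps, charge_source=charge_source,
                flexible=flexible, solv=solv, cutoff=cutoff,
            )
            new.provenance = "refined"
            new.rmsd_to_native = pose.rmsd_to_native if new.converged else None
        rescored.append(new)
    converged = [p for p in rescored if p.converged]
    ranked = sorted(
        converged,
        key=lambda p: (p.score, p.index if p.index is not None else 0),
    )
    out = {
        "poses": rescored,
        "ranked": ranked,
        "conv_fraction": len(converged) / len(rescored) if rescored else 0.0,
    }
    if rescored and not converged:
        out["status"] = "all poses failed to converge"
    return out
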