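"""Redocking metrics and benchmark quality filters.

RMSD is computed over heavy atoms in the receptor frame (no
superposition), minimized over molecular-graph automorphisms that
preserve element and bond order (symmetry-adapted RMSD). A redocking
success is a best-scored converged pose within 1.5 A (inclusive) of the
native pose; a scoring failure is any pose scored better than the
relaxed native pose at RMSD above the cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from qmmdock import constants
from qmmdock.errors import QmmdockError
from qmmdock.molecular_model.types import BenchmarkRecord, MolecularSystem

MAX_AUTOMORPHISMS = 10000


# ----------------------------------------------------------------------
# symmetry-adapted RMSD


def ligand_graph(system: MolecularSystem) -> nx.Graph:
    """Heavy-atom molecular graph of the ligand with element/order labels.

    Node ids are consecutive 0..n-1 in the order of the ligand heavy
    atoms; coordinates compared against this graph must use that order.
    """
    heavy = system.heavy_idx(system.ligand_idx)
    remap = {idx: k for k, idx in enumerate(heavy)}
    g = nx.Graph()
    for idx in heavy:
        g.add_node(remap[idx], element=system.atoms[idx].element.upper())
    for b in system.bonds:
        if b.i in remap and b.j in remap:
            g.add_edge(remap[b.i], remap[b.j], order=b.order)
    return g


def graph_automorphisms(graph: nx.Graph, cap: int = MAX_AUTOMORPHISMS) -> list[dict]:
    """Element- and bond-order-preserving automorphisms (capped)."""
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        graph,
        graph,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    autos = []
    for mapping in matcher.isomorphisms_iter():
        autos.append(mapping)
        if len(autos) >= cap:
            break
    return autos


def symmetry_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    graph: nx.Graph,
    automorphisms: Optional[list[dict]] = None,
) -> float:
    """Minimum heavy-atom RMSD over graph automorphisms, no superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    n = graph.number_of_nodes()
    if a.shape != (n, 3) or b.shape != (n, 3):
        raise QmmdockError(
            f"coordinates ({a.shape}, {b.shape}) do not match graph size {n}"
        )
    if automorphisms is None:
        automorphisms = graph_automorphisms(graph)
    best = np.inf
    order = np.arange(n)
    for mapping in automorphisms:
        perm = np.array([mapping[int(i)] for i in order])
        msd = float(np.mean(np.sum((a - b[perm]) ** 2, axis=1)))
        if msd < best:
            best = msd
    return float(np.sqrt(best))


# ----------------------------------------------------------------------
# success bookkeeping


def judge_success(
    ranked_poses: Sequence,
    native_coords: np.ndarray,
    graph: nx.Graph,
    pose_coords: Sequence[np.ndarray],
    cutoff: float = constants.RMSD_SUCCESS_CUTOFF,
) -> dict:
    """Success iff the best-scored converged pose sits within ``cutoff``.

    ``ranked_poses`` and ``pose_coords`` run in parallel; poses flagged
    non-converged are ignored. With no converged pose the complex drops
    out of the denominator (``status: non-converged``).
    """
    pairs = [
        (p, c) for p, c in zip(ranked_poses, pose_coords) if getattr(p, "converged", True)
    ]
    if not pairs:
        return {"status": "non-converged", "success": None, "best_rmsd": None}
    best_pose, best_coords = min(
        enumerate(pairs), key=lambda kv: (kv[1][0].score, kv[0])
    )[1]
    rmsd = symmetry_rmsd(best_coords, native_coords, graph)
    return {"status": "converged", "success": rmsd <= cutoff, "best_rmsd": rmsd}


def detect_scoring_failure(
    ranked_poses: Sequence,
    pose_coords: Sequence[np.ndarray],
    native_relaxed_score: float,
    native_coords: np.ndarray,
    graph: nx.Graph,
    cutoff: float = constants.RMSD_SUCCESS_CUTOFF,
) -> bool:
    """True iff some non-native pose beats the relaxed native score."""
    autos = graph_automorphisms(graph)
    for pose, coords in zip(ranked_poses, pose_coords):
        if not getattr(pose, "converged", True):
            continue
        if pose.score < native_relaxed_score:
            if symmetry_rmsd(coords, native_coords, graph, autos) > cutoff:
                return True
    return False


def success_rate(results: Sequence[dict]) -> dict:
    """Aggregate per-complex outcomes into Table-style percentages.

    Each outcome carries ``converged`` (bool), ``success`` (bool) and
    optionally ``success_ns`` (ranking without solvation terms).
    Success rates count converged cases only.
    """
    total = len(results)
    converged = [r for r in results if r.get("converged", True)]
    if not converged:
        return {"status": "no converged complexes", "conv": 0.0}
    succ = 100.0 * sum(bool(r.get("success")) for r in converged) / len(converged)
    out = {
        "succ": succ,
        "conv": 100.0 * len(converged) / total if total else 0.0,
    }
    if any("success_ns" in r for r in converged):
        out["succ_ns"] = (
            100.0 * sum(bool(r.get("success_ns")) for r in converged) / len(converged)
        )
    return out


# ----------------------------------------------------------------------
# benchmark curation


@dataclass
class FilterResult:
    passed: bool
    violated: list[str]


#: filter name -> (predicate, human-readable bound)
QUALITY_FILTERS = {
    "resolution": lambda r: r.resolution <= 2.5,
    "dpi": lambda r: r.dpi <= 0.5,
    "b-factor": lambda r: r.ligand_b_factor_avg <= 80.0,
    "ediam": lambda r: r.ediam >= 0.4,
    "mw-range": lambda r: 50.0 <= r.mw <= 500.0,
    "rotatable-bonds": lambda r: r.n_rotatable_bonds < 18,
    "ghose": lambda r: r.ghose_pass_count >= 3,
    "lipinski": lambda r: r.lipinski_pass_count >= 3,
    "missing-atoms": lambda r: not r.has_missing_atoms,
    "altlocs": lambda r: not r.has_altlocs,
    "crystal-contact": lambda r: r.min_crystal_contact >= 4.5,
}


def apply_quality_filters(record: BenchmarkRecord) -> FilterResult:
    """Structure/ligand quality stack; a record passes iff every filter does."""
    violated = []
    for name, predicate in QUALITY_FILTERS.items():
        try:
            ok = predicate(record)
        except (TypeError, AttributeError):
            violated.append(f"{name} (unevaluable)")
            continue
        if ok is None:
            violated.append(f"{name} (unevaluable)")
        elif not ok:
            violated.append(name)
    return FilterResult(passed=not violated, violated=violated)


# ----------------------------------------------------------------------
# drug-likeness pass counts (helper feeding the metadata table)

GHOSE_BOUNDS = {"mw": (160.0, 480.0), "logp": (-0.4, 5.6), "atoms": (20, 70),
                "refractivity": (40.0, 130.0)}
LIPINSKI_BOUNDS = {"mw": 500.0, "logp": 5.0, "hbd": 5, "hba": 10}


def rule_pass_counts(mol) -> tuple[int, int]:
    """(Ghose, Lipinski) pass counts for an RDKit molecule.

    The logP estimator (Crippen) is configuration, not a physics claim.
    """
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    mr = Crippen.MolMR(mol)
    n_atoms = mol.GetNumAtoms()
    ghose = sum(
        [
            GHOSE_BOUNDS["mw"][0] <= mw <= GHOSE_BOUNDS["mw"][1],
            GHOSE_BOUNDS["logp"][0] <= logp <= GHOSE_BOUNDS["logp"][1],
            GHOSE_BOUNDS["atoms"][0] <= n_atoms <= GHOSE_BOUNDS["atoms"][1],
            GHOSE_BOUNDS["refractivity"][0] <= mr <= GHOSE_BOUNDS["refractivity"][1],
        ]
    )
    lip = sum(
        [
            mw <= LIPINSKI_BOUNDS["mw"],
            logp <= LIPINSKI_BOUNDS["logp"],
            Lipinski.NumHDonors(mol) <= LIPINSKI_BOUNDS["hbd"],
            Lipinski.NumHAcceptors(mol) <= LIPINSKI_BOUNDS["hba"],
        ]
    )
    return ghose, lip
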