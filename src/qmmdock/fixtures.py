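"""Deterministic synthetic-complex generator.

Builds small parameterized ligand/pocket complexes (optionally with a
divalent metal site, a covalent anchor, or one explicit water) whose
native pose is a verified local minimum of the classical score. All
randomness flows from one seeded generator; identical seeds give
bit-identical output.

Pseudo-residues are 5-atom rigid groups (N, CA, C, O, CB) with tunable
charges and LJ parameters, not real amino acids; this keeps parameter
tables tiny and fully self-contained.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from qmmdock import constants
from qmmdock.errors import ConfigError, QmmdockError
from qmmdock.molecular_model import (
    Atom,
    BenchmarkRecord,
    BondTerm,
    MolecularSystem,
    assign_parameters,
    plain_rmsd,
)
from qmmdock.partitioning import make_partition
from qmmdock.pipeline import Pose, apply_pose, make_pose, optimize_pose, score_classical
from qmmdock.qm_engines import QMEngineSpec

_LJ = {
    "C": {"epsilon": 0.10, "rmin_half": 2.00},
    "H": {"epsilon": 0.03, "rmin_half": 1.10},
    "N": {"epsilon": 0.17, "rmin_half": 1.85},
    "O": {"epsilon": 0.15, "rmin_half": 1.70},
    "ZN": {"epsilon": 0.25, "rmin_half": 1.09},
}

_BONDED = {
    "bonds": {
        "C-C": {"k": 300.0, "r0": 1.53},
        "C-H": {"k": 340.0, "r0": 1.09},
        "C-N": {"k": 320.0, "r0": 1.45},
        "C-O": {"k": 350.0, "r0": 1.30},
        "H-O": {"k": 450.0, "r0": 0.96},
    },
    "angles": {
        "C-C-C": {"k": 55.0, "theta0": 111.0},
        "C-C-H": {"k": 35.0, "theta0": 109.5},
        "H-C-H": {"k": 30.0, "theta0": 107.0},
        "C-C-N": {"k": 55.0, "theta0": 110.0},
        "C-C-O": {"k": 60.0, "theta0": 115.0},
        "N-C-C": {"k": 55.0, "theta0": 110.0},
        "H-O-H": {"k": 45.0, "theta0": 104.5},
    },
    "torsions": {
        "C-C-C-C": {"k": 0.20, "n": 3, "delta": 0.0},
        "H-C-C-H": {"k": 0.15, "n": 3, "delta": 0.0},
        "C-C-C-H": {"k": 0.15, "n": 3, "delta": 0.0},
    },
}


@dataclass
class ToyComplex:
    """Fixture bundle: parameterized complex, verified native pose, table."""

    system: MolecularSystem
    native: Pose
    params: dict
    seed: int
    options: dict

    def __iter__(self):
        return iter((self.system, self.native, self.params))


# ----------------------------------------------------------------------
# construction


def make_toy_complex(
    seed: int,
    n_pocket_residues: int = 5,
    with_metal: bool = False,
    with_covalent: bool = False,
    with_water: bool = False,
    ligand_size: int = 3,
) -> ToyComplex:
    """Build a pocket/ligand complex with a verified native minimum."""
    if n_pocket_residues < 1:
        raise ConfigError("n_pocket_residues must be >= 1")
    if ligand_size < 2:
        raise ConfigError("ligand_size must be >= 2")
    if with_covalent and ligand_size < 2:
        raise ConfigError("covalent anchor needs a multi-atom ligand")
    if with_covalent and n_pocket_residues < 1:
        raise ConfigError("covalent anchor needs a pocket residue")
    tc = _build_cached(
        seed, n_pocket_residues, with_metal, with_covalent, with_water, ligand_size
    )
    # hand out copies so callers can mutate freely
    return ToyComplex(
        system=tc.system.copy(),
        native=tc.native.copy(),
        params=tc.params,
        seed=tc.seed,
        options=dict(tc.options),
    )


@functools.lru_cache(maxsize=32)
def _build_cached(seed, n_pocket, with_metal, with_covalent, with_water, ligand_size):
    rng = np.random.default_rng(seed)
    system = MolecularSystem()
    table: dict = {"atoms": {}, **{k: dict(v) for k, v in _BONDED.items()}}

    _add_pocket(system, table, rng, n_pocket, ligand_size)
    if with_metal:
        _add_metal(system, table, rng)
    if with_water:
        _add_water(system, table, rng)
    lig_first = system.n_atoms
    _add_ligand(system, table, rng, ligand_size)
    if with_covalent:
        cb = next(
            i for i in range(lig_first)
            if system.atoms[i].atom_name == "CB" and system.atoms[i].residue_id == "A:1"
        )
        system.covalent_link = (lig_first, cb)
        system.bonds.append(BondTerm(i=lig_first, j=cb))
        # pull the anchor side chain toward the ligand head atom
        head = system.atoms[lig_first].coords
        shift = head + 1.8 * _unit(system.atoms[cb].coords - head) - system.atoms[cb].coords
        for i in system.residue_atoms("A:1"):
            system.atoms[i].coords = system.atoms[i].coords + shift

    assign_parameters(system, table)
    system.validate(check_charges=True)

    native = _settle_native(system)
    options = {
        "n_pocket_residues": n_pocket,
        "with_metal": with_metal,
        "with_covalent": with_covalent,
        "with_water": with_water,
        "ligand_size": ligand_size,
    }
    return ToyComplex(system=system, native=native, params=table, seed=seed,
                      options=options)


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise QmmdockError("zero-length direction")
    return v / n


def _pocket_layout(n: int, half_len: float, rng) -> list[tuple[np.ndarray, float]]:
    """(CB tip position, CB charge) per residue.

    The first two residues anchor the ligand ends along +-x with strong
    complementary charges; the third pins the roll angle from +z; the
    rest cage the ligand from the remaining directions with weak
    charges. This makes the classical score funnel-shaped around a
    unique orientation.
    """
    ax = half_len + 3.0
    layout: list[tuple[np.ndarray, float]] = [
        (np.array([-ax, 0.0, 0.0]), +0.80),
        (np.array([+ax, 0.0, 0.0]), -0.80),
        (np.array([0.0, 0.0, 3.8]), -0.45),
    ]
    ring = [
        np.array([0.0, 3.9, -1.2]),
        np.array([0.0, -3.9, -1.2]),
        np.array([0.0, 2.6, -3.2]),
        np.array([0.0, -2.6, -3.2]),
        np.array([2.9, 0.0, -3.4]),
        np.array([-2.9, 0.0, -3.4]),
    ]
    # the two lateral residues carry +-0.25 e to break the chain-kink
    # degeneracy; the positive one sits on the +y side so no pocket
    # corner accumulates only negative charge (that would trap the
    # positive ligand end off-site). The rest are weakly charged filler.
    ring_charges = [0.25, -0.25, 0.05, -0.05, 0.05, -0.05]
    k = 0
    while len(layout) < n:
        if k < len(ring):
            pos = ring[k]
            charge = ring_charges[k]
        else:  # arbitrary extra shell positions, seeded
            pos = 6.0 * _unit(rng.normal(size=3))
            charge = 0.05 if k % 2 == 0 else -0.05
        layout.append((pos, charge))
        k += 1
    layout = layout[:n]
    # seeded jitter so distinct seeds give distinct (but equally
    # funnel-shaped) pockets
    return [(pos + rng.normal(scale=0.12, size=3), q) for pos, q in layout]


def _add_pocket(system, table, rng, n_pocket, ligand_size) -> None:
    half_len = 0.65 * (ligand_size - 1)
    layout = _pocket_layout(n_pocket, half_len, rng)
    for k, (tip, cb_charge) in enumerate(layout):
        d = _unit(tip + np.array([0.0, 0.0, 1e-9]))
        ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        t1 = _unit(np.cross(d, ref))
        t2 = np.cross(d, t1)
        variant = f"P{chr(ord('A') + k)}"  # one residue type per pocket slot
        rid = f"A:{k + 1}"
        ca = tip + 1.53 * d
        positions = {
            "CB": tip,
            "CA": ca,
            "N": ca + 1.45 * t1,
            "C": ca + 1.52 * t2,
            "O": ca + 1.52 * t2 + 1.30 * d,
        }
        for name in ("N", "CA", "C", "O", "CB"):
            system.atoms.append(
                Atom(
                    index=len(system.atoms),
                    element=name[0],
                    coords=positions[name],
                    atom_name=name,
                    residue_name=variant,
                    residue_id=rid,
                    b_factor=10.0,
                )
            )
        base = len(system.atoms) - 5
        n_, ca_i, c, o, cb = base, base + 1, base + 2, base + 3, base + 4
        system.bonds.extend(
            [
                BondTerm(i=n_, j=ca_i),
                BondTerm(i=ca_i, j=c),
                BondTerm(i=c, j=o),
                BondTerm(i=ca_i, j=cb),
            ]
        )
        block = {
            "N": {"charge": -0.10, **_LJ["N"]},
            "CA": {"charge": 0.10, **_LJ["C"]},
            "C": {"charge": 0.20, **_LJ["C"]},
            "O": {"charge": -0.20, **_LJ["O"]},
            "CB": {"charge": round(float(cb_charge), 6), **_LJ["C"]},
        }
        total = sum(v["charge"] for v in block.values())
        block["O"]["charge"] = round(block["O"]["charge"] - total, 6)  # neutral residue
        table["atoms"][variant] = block


def _add_metal(system, table, rng) -> None:
    """Divalent ion near the ligand with two coordinating residues."""
    n_pocket = len(system.residues())
    pos = np.array([0.0, -3.3, -1.6])
    idx = len(system.atoms)
    system.atoms.append(
        Atom(
            index=idx,
            element="Zn",
            coords=pos,
            atom_name="ZN",
            residue_name="ZNM",
            residue_id="M:1",
            b_factor=10.0,
        )
    )
    system.metals.add(idx)
    table["atoms"]["ZNM"] = {"ZN": {"charge": 2.0, **_LJ["ZN"]}}
    # drag two cage side-chain tips into the first shell and give them
    # compensating negative charges (each pocket slot has its own type)
    hosts = [n_pocket - 2, n_pocket - 1] if n_pocket >= 4 else [0, min(1, n_pocket - 1)]
    for k in dict.fromkeys(hosts):
        rid = f"A:{k + 1}"
        cb = system.residue_atoms(rid)[4]
        tip = system.atoms[cb]
        tip.coords = pos + 2.1 * _unit(tip.coords - pos)
        variant = tip.residue_name
        block = table["atoms"][variant]
        block["CB"]["charge"] = -0.45
        total = sum(v["charge"] for v in block.values())
        block["O"]["charge"] = round(block["O"]["charge"] - total, 6)


def _add_water(system, table, rng) -> None:
    d = _unit(rng.normal(size=3))
    origin = 4.6 * d
    idx = len(system.atoms)
    rid = "W:1"
    coords = {
        "O": origin,
        "H1": origin + np.array([0.76, 0.59, 0.0]),
        "H2": origin + np.array([-0.76, 0.59, 0.0]),
    }
    for name, xyz in coords.items():
        system.atoms.append(
            Atom(
                index=len(system.atoms),
                element=name[0],
                coords=xyz,
                atom_name=name,
                residue_name="HOH",
                residue_id=rid,
                b_factor=15.0,
            )
        )
    system.bonds.extend([BondTerm(i=idx, j=idx + 1), BondTerm(i=idx, j=idx + 2)])
    table["atoms"]["HOH"] = {
        "O": {"charge": -0.834, **_LJ["O"]},
        "H1": {"charge": 0.417, **_LJ["H"]},
        "H2": {"charge": 0.417, **_LJ["H"]},
    }


def _add_ligand(system, table, rng, ligand_size) -> None:
    first = len(system.atoms)
    lig_block: dict = {}
    heavy_pos = []
    for k in range(ligand_size):
        heavy_pos.append(np.array([1.30 * k, 0.40 * (-1) ** k, 0.0]))
    heavy_pos = np.array(heavy_pos)
    heavy_pos -= heavy_pos.mean(axis=0)

    # end charges pair with the x-axis anchors; a middle C-H dipole
    # pairs with the +z anchor and pins the roll angle
    charges = np.zeros(ligand_size)
    charges[0] = -0.80
    charges[-1] = +0.80
    mid = (ligand_size - 1) // 2
    h_charges = np.zeros(ligand_size)
    if 0 < mid < ligand_size - 1:
        charges[mid] -= 0.45
        h_charges[mid] = +0.45

    for k in range(ligand_size):
        name = f"C{k + 1}"
        system.atoms.append(
            Atom(
                index=len(system.atoms),
                element="C",
                coords=heavy_pos[k],
                atom_name=name,
                residue_name="LIG",
                residue_id="L:1",
                is_ligand=True,
                b_factor=20.0,
            )
        )
        lig_block[name] = {"charge": round(float(charges[k]), 6), **_LJ["C"]}
    for k in range(ligand_size - 1):
        system.bonds.append(BondTerm(i=first + k, j=first + k + 1))
    # one hydrogen per heavy atom, all tilted toward +z
    for k in range(ligand_size):
        name = f"H{k + 1}"
        up = np.array([0.0, -0.25 * (-1) ** k, 1.0])
        system.atoms.append(
            Atom(
                index=len(system.atoms),
                element="H",
                coords=heavy_pos[k] + 1.09 * _unit(up),
                atom_name=name,
                residue_name="LIG",
                residue_id="L:1",
                is_ligand=True,
                b_factor=20.0,
            )
        )
        system.bonds.append(
            BondTerm(i=first + k, j=first + ligand_size + k)
        )
        lig_block[name] = {"charge": round(float(h_charges[k]), 6), **_LJ["H"]}
    table["atoms"]["LIG"] = lig_block
    # net charge is set by assign_parameters from the table sum


# ----------------------------------------------------------------------
# native pose settling


def _settle_native(system: MolecularSystem, max_rounds: int = 10,
                   n_starts: int = 10) -> Pose:
    """Find the deepest accessible minimum of the classical score.

    Multistart local optimization (the mirror-engine hybrid objective is
    identical to the classical score here), then verify with the
    single-atom perturbation scan.
    """
    partition = make_partition(system, mode="lig", scale=1.0)
    spec = QMEngineSpec(method="mirror-mm", ps_charge=partition.ps_net_charge)
    start = make_pose(system, provenance="native")
    candidates = [start]
    # deterministic mirror/flip starts reach kink- and orientation-flipped
    # basins that random perturbations visit only rarely
    centroid = start.coords.mean(axis=0)
    for diag in ((1, -1, 1), (1, 1, -1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        flipped = start.copy()
        flipped.coords = centroid + (start.coords - centroid) * np.array(diag, float)
        candidates.append(flipped)
    magnitudes = (0.7, 1.3, 2.0, 2.6)
    for k in range(n_starts - 1):
        candidates.append(
            perturb_pose(start, seed=90_000 + k, magnitude=magnitudes[k % 4],
                         system=system)
        )
    pose = None
    for cand in candidates:
        opt = optimize_pose(system, partition, cand, spec=spec,
                            conv=1e-5, max_steps=500)
        if pose is None or opt.score_qmmm < pose.score_qmmm:
            pose = opt
    for _ in range(max_rounds):
        better = _perturbation_scan(system, pose)
        if better is None:
            native = Pose(
                coords=pose.coords.copy(),
                movable=pose.movable,
                provenance="native",
                score_class=pose.score_qmmm,  # identical by the mirror identity
            )
            apply_pose(system, native)
            return native
        pose = optimize_pose(system, partition, better, spec=spec,
                             conv=1e-5, max_steps=400)
    raise QmmdockError(
        "fixture generator could not settle the native pose into a verified "
        "local minimum"
    )


def _perturbation_scan(system: MolecularSystem, pose: Pose, delta: float = 0.2):
    """Return an improved pose if any +-delta single-atom move lowers the
    classical score, else None."""
    base_score, _ = score_classical(system, pose)
    best = None
    best_score = base_score - 1e-7
    for row in range(len(pose.coords)):
        for axis in range(3):
            for sign in (+1.0, -1.0):
                coords = pose.coords.copy()
                coords[row, axis] += sign * delta
                trial = Pose(coords=coords, movable=pose.movable)
                s, _ = score_classical(system, trial)
                if s < best_score:
                    best_score = s
                    best = trial
    return best


# ----------------------------------------------------------------------
# pose perturbation


def perturb_pose(
    pose: Pose,
    seed: int,
    magnitude: float,
    system: Optional[MolecularSystem] = None,
) -> Pose:
    """Rigid-body displacement plus torsional noise at a target RMSD.

    The raw perturbation is rescaled linearly so the (plain) RMSD to the
    input pose equals ``magnitude`` exactly, which satisfies the
    contract RMSD in [0.5*magnitude, 2*magnitude]. ``magnitude = 0``
    returns the input pose.
    """
    if magnitude < 0:
        raise ConfigError("perturbation magnitude must be >= 0")
    out = pose.copy()
    out.provenance = "sampled"
    out.score_class = out.score_qmmm = None
    out.breakdown = None
    if magnitude == 0:
        return out
    rng = np.random.default_rng(seed)
    x = pose.coords.copy()
    centroid = x.mean(axis=0)

    angle = min(0.25 * magnitude, 0.5)  # radians
    rot = Rotation.from_rotvec(angle * _unit(rng.normal(size=3)))
    x_new = (x - centroid) @ rot.as_matrix().T + centroid
    x_new = x_new + magnitude * _unit(rng.normal(size=3))

    if system is not None:
        x_new = _torsion_twist(x_new, pose, system, rng, magnitude)

    delta = x_new - x
    raw = plain_rmsd(x_new, x)
    if raw < 1e-12:
        return out
    out.coords = x + (magnitude / raw) * delta
    return out


def _torsion_twist(coords, pose, system, rng, magnitude):
    """Rotate one side of a random internal heavy-atom bond."""
    import networkx as nx

    movable = list(pose.movable)
    pos_of = {idx: k for k, idx in enumerate(movable)}
    g = system.bond_graph().subgraph(movable)
    heavy = set(system.heavy_idx(movable))
    internal = [
        (i, j)
        for i, j in g.edges
        if i in heavy and j in heavy and g.degree(i) > 1 and g.degree(j) > 1
    ]
    if not internal:
        return coords
    i, j = internal[rng.integers(len(internal))]
    h = g.copy()
    h.remove_edge(i, j)
    side = nx.node_connected_component(h, j) - {j}
    if not side:
        return coords
    axis = _unit(coords[pos_of[j]] - coords[pos_of[i]])
    angle = rng.uniform(-0.5, 0.5) * min(magnitude, 2.0)
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    pivot = coords[pos_of[j]]
    for atom in side:
        k = pos_of[atom]
        coords[k] = (coords[k] - pivot) @ rot.T + pivot
    return coords


# ----------------------------------------------------------------------
# benchmark metadata battery


_PASS_RANGES = {
    "resolution": (1.2, 2.5),
    "dpi": (0.1, 0.5),
    "ligand_b_factor_avg": (10.0, 80.0),
    "ediam": (0.4, 1.0),
    "mw": (150.0, 480.0),
    "n_rotatable_bonds": (0, 17),
    "min_crystal_contact": (4.5, 9.0),
}

_VIOLATIONS = [
    ("resolution", {"resolution": 3.1}),
    ("dpi", {"dpi": 0.85}),
    ("b-factor", {"ligand_b_factor_avg": 95.0}),
    ("ediam", {"ediam": 0.2}),
    ("mw-range", {"mw": 45.0}),
    ("rotatable-bonds", {"n_rotatable_bonds": 18}),
    ("ghose", {"ghose_pass_count": 2}),
    ("lipinski", {"lipinski_pass_count": 1}),
    ("missing-atoms", {"has_missing_atoms": True}),
    ("altlocs", {"has_altlocs": True}),
    ("crystal-contact", {"min_crystal_contact": 3.0}),
]


def make_benchmark_records(
    seed: int, n: int, planted_pass_count: int
) -> list[BenchmarkRecord]:
    """Battery of metadata records: exactly ``planted_pass_count`` pass
    every quality filter; every other record violates exactly one named
    filter (cycled deterministically)."""
    if not 0 <= planted_pass_count <= n:
        raise ConfigError("planted_pass_count must be in [0, n]")
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        fields = {
            "complex_id": f"TOY{k:03d}",
            "ghose_pass_count": int(rng.integers(3, 5)),
            "lipinski_pass_count": int(rng.integers(3, 5)),
            "has_missing_atoms": False,
            "has_altlocs": False,
        }
        for name, (lo, hi) in _PASS_RANGES.items():
            if isinstance(lo, int):
                fields[name] = int(rng.integers(lo, hi + 1))
            else:
                fields[name] = round(float(rng.uniform(lo, hi)), 3)
        if k >= planted_pass_count:
            _, override = _VIOLATIONS[(k - planted_pass_count) % len(_VIOLATIONS)]
            fields.update(override)
        records.append(BenchmarkRecord(**fields))
    return records


def planted_violation_name(k: int, planted_pass_count: int) -> str:
    """Which filter record k (>= planted_pass_count) was built to violate."""
    return _VIOLATIONS[(k - planted_pass_count) % len(_VIOLATIONS)][0]


# ----------------------------------------------------------------------
# file emission (same dialects molecular_model reads)


def write_toy_complex(tc: ToyComplex, out_dir) -> dict[str, Path]:
    """Write receptor.pdb / ligand.sdf / complex.pdb / params.yaml."""
    from qmmdock.molecular_model import save_parameter_table, write_pdb, write_sdf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    system = tc.system.copy()
    apply_pose(system, tc.native)

    receptor = system.copy()
    lig_set = set(receptor.ligand_idx)
    keep = [i for i in range(receptor.n_atoms) if i not in lig_set]
    remap = {old: new for new, old in enumerate(keep)}
    receptor.atoms = [receptor.atoms[i] for i in keep]
    for new, atom in enumerate(receptor.atoms):
        atom.index = new
    receptor.bonds = [
        BondTerm(i=remap[b.i], j=remap[b.j], order=b.order)
        for b in receptor.bonds
        if b.i in remap and b.j in remap
    ]
    receptor.angles, receptor.torsions = [], []
    receptor.metals = {remap[m] for m in receptor.metals}
    receptor.covalent_link = None
    receptor.net_charge = None

    paths = {
        "receptor": out / "receptor.pdb",
        "ligand": out / "ligand.sdf",
        "complex": out / "complex.pdb",
        "params": out / "params.yaml",
    }
    write_pdb(receptor, paths["receptor"])
    write_pdb(system, paths["complex"])
    write_sdf(system, paths["ligand"], subset=system.ligand_idx)
    save_parameter_table(tc.params, paths["params"])
    return paths
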