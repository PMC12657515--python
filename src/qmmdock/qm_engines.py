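"""Pluggable QM backend contract with two built-in engines.

``mirror-mm``
    Oracle engine: returns exactly the MM energy of the capped PS and
    the exact Coulomb energy between PS force-field charges and the
    embedding charges. Used to validate the whole subtractive pipeline
    term by term.
``eem``
    Electronegativity-equalization engine: solves the charge-
    equilibration linear system (electronegativity + hardness + Coulomb
    coupling, total-charge constrained) in the embedding field and adds
    the PS's own LJ/bonded terms. Produces QM-like polarized charges.
``mirror-mm-hf``
    The mirror engine with HF/DFT-like bookkeeping: the engine energy
    additionally contains the electrostatic self-repulsion of the
    embedding charges and declares ``includes_ss_self_energy``, so the
    scoring layer must subtract that term a posteriori.

No interface to external QM programs is implemented; the
:class:`FileExchangeAdapter` contract documents how one plugs in
(basis/multiplicity are pass-through metadata for built-in engines).
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from qmmdock import constants
from qmmdock.energetics import coulomb_point_sets, mm_gradient, mm_terms, ss_self_repulsion
from qmmdock.errors import ConfigError, ConvergenceError, ParameterError
from qmmdock.partitioning import PSGeometry


@dataclass
class QMEngineSpec:
    method: str = "mirror-mm"
    basis: str = "none"
    multiplicity: int = 1
    ps_charge: int = 0
    includes_ss_self_energy: bool = False
    max_scf_or_solver_iters: int = 200

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ConfigError("multiplicity must be >= 1")


@dataclass
class QMResult:
    e_qm_ps: float
    e_qm_elec_ps_ss: float
    qm_charges: np.ndarray
    gradient: Optional[np.ndarray] = None  # per PS atom (incl. links), kcal/mol/A
    converged: bool = True

    def __post_init__(self) -> None:
        self.qm_charges = np.asarray(self.qm_charges, dtype=float)
        if self.converged and not (
            np.isfinite(self.e_qm_ps) and np.isfinite(self.e_qm_elec_ps_ss)
        ):
            raise ConvergenceError("converged result with non-finite energy")


class QMEngine(abc.ABC):
    """Engine contract: deterministic energies for a capped PS in an
    embedding field."""

    name: str = "abstract"
    provides_gradient: bool = False

    @abc.abstractmethod
    def compute(
        self,
        ps_geometry: PSGeometry,
        embedding: tuple[np.ndarray, np.ndarray],
        spec: QMEngineSpec,
    ) -> QMResult:
        """``embedding`` is an (positions (m,3), charges (m,)) pair."""


# ----------------------------------------------------------------------


class MirrorMMEngine(QMEngine):
    """Returns the MM answer through the QM interface (oracle engine)."""

    name = "mirror-mm"
    provides_gradient = True

    def compute(self, ps_geometry, embedding, spec) -> QMResult:
        sub = ps_geometry.subsystem
        terms = mm_terms(sub, cutoff=constants.NB_CUTOFF)
        pos, q = embedding
        ff_charges = sub.charges  # link atoms carry 0
        e_elec = coulomb_point_sets(sub.coords, ff_charges, pos, q) if len(q) else 0.0
        return QMResult(
            e_qm_ps=terms.total,
            e_qm_elec_ps_ss=e_elec,
            qm_charges=ff_charges,
            gradient=None,  # cheap to rebuild on demand; see gradient()
            converged=True,
        )

    def gradient(self, ps_geometry, embedding, spec) -> np.ndarray:
        """Analytic gradient of e_qm_ps + e_qm_elec_ps_ss (PS atoms)."""
        sub = ps_geometry.subsystem
        pos, q = embedding
        grad = mm_gradient(sub, cutoff=constants.NB_CUTOFF)
        if len(q):
            grad = grad + _point_field_gradient(sub.coords, sub.charges, pos, q)
        return grad


def _point_field_gradient(coords, charges, emb_pos, emb_q) -> np.ndarray:
    """Gradient of the PS<->embedding Coulomb term w.r.t. PS coordinates."""
    d = coords[:, None, :] - emb_pos[None, :, :]
    r = np.sqrt(np.sum(d * d, axis=-1))
    coef = -constants.COULOMB_KCAL * charges[:, None] * emb_q[None, :] / r**3
    return np.sum(coef[..., None] * d, axis=1)


class MirrorMMWithSSSelfEnergy(MirrorMMEngine):
    """Mirror engine mimicking a non-parametrized (HF/DFT-like) code that
    folds the embedding self-repulsion into its reported energy."""

    name = "mirror-mm-hf"

    def compute(self, ps_geometry, embedding, spec) -> QMResult:
        res = super().compute(ps_geometry, embedding, spec)
        pos, q = embedding
        if len(q):
            res.e_qm_ps += ss_self_repulsion(pos, q)
        return res


# ----------------------------------------------------------------------


#: electronegativity chi (eV-like, used as kcal/mol/e here) and hardness
#: eta (kcal/mol/e^2) per element. Configuration values, not physics claims.
EEM_TABLE: dict[str, tuple[float, float]] = {
    "H": (20.02, 160.0),
    "C": (35.12, 140.0),
    "N": (46.71, 150.0),
    "O": (56.06, 160.0),
    "S": (47.0, 120.0),
    "P": (40.0, 110.0),
    "FE": (45.0, 100.0),
    "ZN": (40.0, 110.0),
}


class EEMEngine(QMEngine):
    """Toy electronegativity-equalization backend.

    Minimizes ``sum_i chi_i q_i + eta_i q_i^2 + sum_{i<j} k q_i q_j/r_ij
    + sum_i q_i V_i`` subject to ``sum q_i = Q``, where ``V_i`` is the
    potential of the embedding charges at atom i. The engine energy is
    that electrostatic minimum plus the PS's own LJ and bonded terms so
    short-range repulsion is retained.
    """

    name = "eem"
    provides_gradient = False

    def __init__(self, table: Optional[dict] = None) -> None:
        self.table = dict(EEM_TABLE if table is None else table)

    def compute(self, ps_geometry, embedding, spec) -> QMResult:
        sub = ps_geometry.subsystem
        coords = sub.coords
        n = sub.n_atoms
        chi = np.empty(n)
        eta = np.empty(n)
        for i, atom in enumerate(sub.atoms):
            key = atom.element.upper()
            if key not in self.table:
                raise ParameterError(f"element {key!r} missing from the EEM table")
            chi[i], eta[i] = self.table[key]

        d = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=-1))
        if np.any((r < 1e-6) & ~np.eye(n, dtype=bool)):
            return QMResult(
                e_qm_ps=np.nan,
                e_qm_elec_ps_ss=np.nan,
                qm_charges=np.zeros(n),
                converged=False,
            )
        with np.errstate(divide="ignore"):
            J = np.where(np.eye(n, dtype=bool), 0.0, constants.COULOMB_KCAL / r)

        pos, emb_q = embedding
        if len(emb_q):
            dv = coords[:, None, :] - pos[None, :, :]
            rv = np.sqrt(np.sum(dv * dv, axis=-1))
            V = constants.COULOMB_KCAL * np.sum(emb_q[None, :] / rv, axis=1)
        else:
            V = np.zeros(n)

        # KKT system: (2 eta diag + J) q + lambda * 1 = -(chi + V); 1.q = Q
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = J + np.diag(2.0 * eta)
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        b = np.zeros(n + 1)
        b[:n] = -(chi + V)
        b[n] = float(spec.ps_charge)
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return QMResult(
                e_qm_ps=np.nan,
                e_qm_elec_ps_ss=np.nan,
                qm_charges=np.zeros(n),
                converged=False,
            )
        q = sol[:n]

        e_elec_ps = float(np.dot(chi, q) + np.dot(eta, q * q) + 0.5 * q @ J @ q)
        e_elec_ps_ss = float(np.dot(q, V))
        terms = mm_terms(sub, cutoff=constants.NB_CUTOFF)
        e_short = terms.bond + terms.angle + terms.torsion + terms.lj
        return QMResult(
            e_qm_ps=e_elec_ps + e_short,
            e_qm_elec_ps_ss=e_elec_ps_ss,
            qm_charges=q,
            converged=True,
        )


# ----------------------------------------------------------------------


class FileExchangeAdapter(QMEngine):
    """Contract for external engines (Gaussian-like, via file exchange).

    Subclasses implement :meth:`run_external`, which receives the paths
    of an exchange file (written here: elements, coordinates, embedding
    charges, charge/multiplicity/method/basis) and of the expected
    result file, launches the external program, and returns when the
    result file exists. The result file is ``key = value`` lines with
    keys ``energy_ps``, ``energy_ps_ss``, ``charges`` (comma separated)
    and optional ``gradient`` (row-major, comma separated).

    Not instantiated by the built-in pipeline; provided so real engines
    can be plugged in without touching the scoring code.
    """

    name = "external"

    def write_exchange(self, path, ps_geometry, embedding, spec) -> None:
        pos, q = embedding
        sub = ps_geometry.subsystem
        lines = [
            f"method {spec.method}",
            f"basis {spec.basis}",
            f"charge {spec.ps_charge}",
            f"multiplicity {spec.multiplicity}",
            "atoms",
        ]
        for a in sub.atoms:
            lines.append(
                f"{a.element} {a.coords[0]:.8f} {a.coords[1]:.8f} {a.coords[2]:.8f}"
            )
        lines.append("embedding")
        for p, c in zip(pos, q):
            lines.append(f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f} {c:.8f}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def read_result(self, path) -> QMResult:
        data: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if "=" in line:
                    key, value = line.split("=", 1)
                    data[key.strip()] = value.strip()
        charges = np.array([float(x) for x in data["charges"].split(",")])
        gradient = None
        if "gradient" in data:
            flat = np.array([float(x) for x in data["gradient"].split(",")])
            gradient = flat.reshape(-1, 3)
        return QMResult(
            e_qm_ps=float(data["energy_ps"]),
            e_qm_elec_ps_ss=float(data["energy_ps_ss"]),
            qm_charges=charges,
            gradient=gradient,
            converged=data.get("converged", "true").lower() == "true",
        )

    @abc.abstractmethod
    def run_external(self, exchange_path, result_path) -> None: ...

    def compute(self, ps_geometry, embedding, spec) -> QMResult:
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            exchange = Path(tmp) / "ps.inp"
            result = Path(tmp) / "ps.out"
            self.write_exchange(exchange, ps_geometry, embedding, spec)
            self.run_external(exchange, result)
            return self.read_result(result)


# ----------------------------------------------------------------------
# registry and numerical gradient

_REGISTRY: dict[str, type[QMEngine]] = {}


def register_engine(name: str, cls: type[QMEngine]) -> None:
    _REGISTRY[name] = cls


def get_engine(name: str) -> QMEngine:
    if name not in _REGISTRY:
        raise ConfigError(
            f"unknown QM engine {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]()


def registered_engines() -> list[str]:
    return sorted(_REGISTRY)


register_engine("mirror-mm", MirrorMMEngine)
register_engine("mirror-mm-hf", MirrorMMWithSSSelfEnergy)
register_engine("eem", EEMEngine)


def compute_qm(
    ps_geometry: PSGeometry,
    embedding: tuple[np.ndarray, np.ndarray],
    spec: QMEngineSpec,
    engine: Optional[QMEngine] = None,
) -> QMResult:
    """Dispatch one QM evaluation through the registry."""
    if engine is None:
        engine = get_engine(spec.method)
    return engine.compute(ps_geometry, embedding, spec)


def numerical_gradient(
    engine: QMEngine,
    ps_geometry: PSGeometry,
    embedding: tuple[np.ndarray, np.ndarray],
    spec: QMEngineSpec,
    h: float = 1e-4,
) -> np.ndarray:
    """Central finite differences of ``e_qm_ps + e_qm_elec_ps_ss`` with
    respect to the PS atom coordinates (link atoms held fixed)."""
    if h <= 0:
        raise ConfigError("finite-difference step h must be > 0")
    sub = ps_geometry.subsystem
    base = sub.coords
    grad = np.zeros_like(base)
    for i in range(sub.n_atoms):
        for axis in range(3):
            for sign, slot in ((+1, 0), (-1, 1)):
                coords = base.copy()
                coords[i, axis] += sign * h
                sub.set_coords(coords)
                res = engine.compute(ps_geometry, embedding, spec)
                if not res.converged:
                    sub.set_coords(base)
                    raise ConvergenceError(
                        f"engine failed at displaced point (atom {i}, axis {axis})"
                    )
                if slot == 0:
                    e_plus = res.e_qm_ps + res.e_qm_elec_ps_ss
                else:
                    e_minus = res.e_qm_ps + res.e_qm_elec_ps_ss
            grad[i, axis] = (e_plus - e_minus) / (2.0 * h)
    sub.set_coords(base)
    return grad
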