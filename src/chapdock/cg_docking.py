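"""Rigid-body two-body energy model and replica-exchange Monte Carlo sampler.

Two binding partners are represented as rigid Cα-bead bodies in a periodic
cubic box.  The interaction energy is a sum over inter-body bead pairs of a
short-range contact potential and long-range Debye–Hückel screened
electrostatics.  A replica-exchange Monte Carlo (parallel tempering) sampler
draws equilibrium poses of one body relative to the other; the bound
sub-ensemble is extracted with a distance + energy criterion and the
dissociation constant follows from the bound fraction measured across box
volumes.

Units: energies in kcal/mol, distances in Å, temperatures in K.  Bound-state
energy thresholds are quoted in units of k_B·T at a reference temperature
(300 K by default).
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Avogadro

from .structures import RigidBodyStructure

__all__ = [
    "KB_KCAL",
    "COULOMB_KCAL",
    "EnergyModel",
    "ContactTableModel",
    "SquareWellModel",
    "load_default_contact_model",
    "Pose",
    "ComplexEnsemble",
    "KdEstimate",
    "pair_energy",
    "total_energy",
    "remc_sample",
    "extract_bound",
    "estimate_kd",
]

#: Boltzmann constant, kcal/(mol·K)
KB_KCAL = 0.0019872041
#: Coulomb prefactor e²/(4πε₀), kcal·Å/(mol·e²)
COULOMB_KCAL = 332.0637


# ---------------------------------------------------------------------------
# Energy models
# ---------------------------------------------------------------------------

class EnergyModel:
    """Interface: vectorized inter-body pair energies as a function of distance.

    Concrete models implement :meth:`pair_tables`, which precomputes per-pair
    parameter matrices for a fixed (A, B) body pair, and
    :meth:`energy_from_distances`, which maps an (n_A, n_B) distance matrix to
    per-pair energies.  ``cutoff`` truncates all interactions (plain
    truncation, not shifted).
    """

    cutoff: float = 30.0

    def bind(self, a: RigidBodyStructure, b: RigidBodyStructure) -> "_BoundEvaluator":
        return _BoundEvaluator(self, a, b)

    def energy_from_distances(self, r: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _BoundEvaluator:
    """Energy of a fixed body pair, parameters precomputed."""

    def __init__(self, model: EnergyModel, a: RigidBodyStructure, b: RigidBodyStructure):
        self.model = model
        self.a = a
        self.b = b
        model._prepare(a, b)

    def total(self, r: np.ndarray) -> float:
        e = self.model.energy_from_distances(r)
        return float(np.sum(e))


@dataclass
class SquareWellModel(EnergyModel):
    """Hard core + square well, the analytically solvable reference model.

    ``well_depth_kt`` is the well depth in units of k_B·T at ``t_ref``; the
    conversion to kcal/mol happens once so the sampler runs at any ladder
    temperature with a fixed Hamiltonian.
    """

    core_radius: float = 3.0
    well_radius: float = 8.0
    well_depth_kt: float = 3.0
    t_ref: float = 300.0
    cutoff: float = 30.0

    @property
    def well_depth_kcal(self) -> float:
        return self.well_depth_kt * KB_KCAL * self.t_ref

    def _prepare(self, a, b) -> None:
        pass

    def energy_from_distances(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        e = np.zeros_like(r)
        e[r < self.well_radius] = -self.well_depth_kcal
        e[r < self.core_radius] = np.inf
        e[r > self.cutoff] = 0.0
        return e

    def energy_scalar(self, r: float) -> float:
        if r < self.core_radius:
            return math.inf
        if r < self.well_radius and r <= self.cutoff:
            return -self.well_depth_kcal
        return 0.0


@dataclass
class ContactTableModel(EnergyModel):
    """Residue-level contact potential plus Debye–Hückel electrostatics.

    Attractive pairs (ε_ij < 0) interact through a Lennard-Jones-like well of
    depth |ε_ij| with minimum at σ_ij; repulsive pairs (ε_ij > 0) through a
    barrier form that is positive at short range and decays to zero.  The
    screened Coulomb term is q_i·q_j·C·exp(−r/λ_D)/(ε_r·r).  All interactions
    are plainly truncated at ``cutoff``.
    """

    epsilon: dict[tuple[str, str], float] = field(default_factory=dict)  # kcal/mol
    sigma: dict[str, float] = field(default_factory=dict)                # Å (per-residue diameter)
    dielectric: float = 80.0
    debye_length: float = 10.0
    cutoff: float = 30.0

    def __post_init__(self) -> None:
        # symmetrize the epsilon lookup
        for (i, j), v in list(self.epsilon.items()):
            self.epsilon[(j, i)] = v

    def _pair_eps(self, ti: str, tj: str) -> float:
        try:
            return self.epsilon[(ti, tj)]
        except KeyError:
            raise KeyError(f"no contact parameter for residue pair ({ti}, {tj})")

    def _pair_sigma(self, ti: str, tj: str) -> float:
        try:
            return 0.5 * (self.sigma[ti] + self.sigma[tj])
        except KeyError:
            raise KeyError(f"no bead diameter for residue type {ti!r} or {tj!r}")

    def _prepare(self, a: RigidBodyStructure, b: RigidBodyStructure) -> None:
        ta, tb = a.residue_types, b.residue_types
        self._eps = np.array(
            [[self._pair_eps(ti, tj) for tj in tb] for ti in ta]
        )
        self._sig = np.array(
            [[self._pair_sigma(ti, tj) for tj in tb] for ti in ta]
        )
        self._qq = np.outer(a.charges, b.charges) * COULOMB_KCAL / self.dielectric

    def energy_from_distances(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        sr6 = (self._sig / r) ** 6
        lj = sr6 * sr6 - 2.0 * sr6              # min of −1 at r == σ
        eps = self._eps
        att = eps < 0
        rep = ~att
        e = np.zeros_like(r)
        e[att] = np.abs(eps[att]) * lj[att]
        # barrier form for repulsive pairs: +|ε|(LJ+2) inside σ, −|ε|·LJ outside
        inside = rep & (r <= self._sig)
        outside = rep & (r > self._sig)
        e[inside] = np.abs(eps[inside]) * (lj[inside] + 2.0)
        e[outside] = -np.abs(eps[outside]) * lj[outside]
        e += self._qq * np.exp(-r / self.debye_length) / r
        e[r > self.cutoff] = 0.0
        return e


def load_default_contact_model(
    scale: float = 1.0, offset: float = 0.0, **kwargs
) -> ContactTableModel:
    """Load the synthetic default contact-parameter table shipped with the
    package (``data/synthetic_contact_params.tsv``).

    The table is a hydrophobicity-derived stand-in constructed for this
    package (ε_ij = −λ·h_i·h_j + e₀ on normalized hydrophobicities), not a
    published statistical potential; users reproducing published systems
    should load their own ε table.  ``scale`` multiplies all ε values and
    ``offset`` (kcal/mol) is added to them, mirroring the usual λ/e₀ knobs of
    statistical contact potentials.
    """
    ref = importlib.resources.files("chapdock") / "data" / "synthetic_contact_params.tsv"
    text = ref.read_text()
    hyd: dict[str, float] = {}
    sig: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, h, s = line.split("\t")
        hyd[aa] = float(h)
        sig[aa] = float(s)
    eps = {
        (i, j): scale * (-0.6 * hyd[i] * hyd[j] + 0.2) + offset
        for i in hyd for j in hyd
    }
    return ContactTableModel(epsilon=eps, sigma=sig, **kwargs)


# ---------------------------------------------------------------------------
# Poses and ensembles
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    """One rigid-body placement of the mobile body.

    ``translation`` is the position of the mobile body's centroid in the box;
    ``rotation`` is a unit quaternion in (x, y, z, w) ordering applied about
    the centroid.
    """

    translation: np.ndarray
    rotation: np.ndarray
    energy: float = 0.0
    temperature_index: int = 0

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        norm = np.linalg.norm(self.rotation)
        if abs(norm - 1.0) > 1e-10:
            if norm == 0:
                raise ValueError("zero quaternion")
            self.rotation = self.rotation / norm
        if not np.isfinite(self.energy):
            raise ValueError("pose energy must be finite")


@dataclass
class ComplexEnsemble:
    """Sampled poses of a two-body system, per replica.

    Arrays are indexed ``[replica, sample]``; ``ladder`` holds the replica
    temperatures.  ``bound_mask`` is populated by :func:`extract_bound`.
    """

    translations: np.ndarray         # (R, S, 3)
    quaternions: np.ndarray          # (R, S, 4)
    energies: np.ndarray             # (R, S) kcal/mol
    ladder: np.ndarray               # (R,) K
    box_edge: float
    record_stride: int
    body_a: RigidBodyStructure | None = None
    body_b: RigidBodyStructure | None = None
    bound_mask: np.ndarray | None = None
    acceptance: dict | None = None

    @property
    def n_replicas(self) -> int:
        return len(self.ladder)

    @property
    def n_samples(self) -> int:
        return self.translations.shape[1]

    def replica_nearest(self, temperature: float) -> int:
        """Index of the ladder temperature closest to ``temperature``."""
        return int(np.argmin(np.abs(np.asarray(self.ladder) - temperature)))

    def pose(self, replica: int, sample: int) -> Pose:
        return Pose(
            self.translations[replica, sample],
            self.quaternions[replica, sample],
            float(self.energies[replica, sample]),
            temperature_index=replica,
        )

    def ligand_coords(self, replica: int, sample: int) -> np.ndarray:
        """Mobile-body Cα coordinates of one pose (no periodic wrapping)."""
        bc = self.body_b.coords - self.body_b.coords.mean(axis=0)
        rot = _quat_to_mat(self.quaternions[replica, sample])
        return bc @ rot.T + self.translations[replica, sample]

    def bound_fraction(self, replica: int | None = None,
                       temperature: float = 300.0) -> float:
        if self.bound_mask is None:
            raise ValueError("bound_mask not computed; call extract_bound first")
        if replica is None:
            replica = self.replica_nearest(temperature)
        return float(self.bound_mask[replica].mean())


@dataclass
class KdEstimate:
    """Dissociation constant in molar units with its uncertainty."""

    kd: float
    uncertainty: float
    per_box: list[tuple[float, float]]   # (volume Å³, bound fraction)
    per_box_kd: np.ndarray = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if len(self.per_box) < 1:
            raise ValueError("per_box needs at least one entry")


# ---------------------------------------------------------------------------
# Quaternion helpers (x, y, z, w ordering)
# ---------------------------------------------------------------------------

def _quat_to_mat(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _quat_mul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    x1, y1, z1, w1 = q1
    x2, y2, z2, w2 = q2
    return np.array([
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
    ])


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _axis_angle_quat(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    s = math.sin(angle / 2.0)
    return np.array([axis[0] * s, axis[1] * s, axis[2] * s, math.cos(angle / 2.0)])


# ---------------------------------------------------------------------------
# Energy evaluation
# ---------------------------------------------------------------------------

def _min_image_distances(a_coords: np.ndarray, b_coords: np.ndarray,
                         box_edge: float) -> np.ndarray:
    disp = b_coords[None, :, :] - a_coords[:, None, :]
    disp -= box_edge * np.round(disp / box_edge)
    return np.sqrt(np.sum(disp * disp, axis=-1))


def pair_energy(model: EnergyModel, type_i: str, type_j: str,
                q_i: float, q_j: float, r: float) -> float:
    """Energy of a single bead pair at separation ``r`` (Å), in kcal/mol."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    a = RigidBodyStructure([1], [type_i], [[0.0, 0.0, 0.0]], [q_i])
    b = RigidBodyStructure([1], [type_j], [[0.0, 0.0, 0.0]], [q_j])
    ev = model.bind(a, b)
    return ev.total(np.array([[r]]))


def total_energy(model: EnergyModel, a: RigidBodyStructure,
                 b: RigidBodyStructure, pose: Pose, box_edge: float) -> float:
    """Total inter-body energy of a pose under the minimum-image convention."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both bodies must be nonempty")
    if box_edge < 2 * model.cutoff:
        raise ValueError(
            f"box edge {box_edge} smaller than twice the cutoff {model.cutoff}"
        )
    ev = model.bind(a, b)
    bc = b.coords - b.coords.mean(axis=0)
    rot = _quat_to_mat(pose.rotation)
    b_pos = bc @ rot.T + pose.translation
    r = _min_image_distances(a.coords, b_pos, box_edge)
    return ev.total(r)


# ---------------------------------------------------------------------------
# Replica-exchange Monte Carlo
# ---------------------------------------------------------------------------

def geometric_ladder(t_min: float = 200.0, t_max: float = 395.0,
                     n: int = 20) -> np.ndarray:
    """Geometrically spaced replica temperatures between the endpoints."""
    if n == 1:
        return np.array([t_min])
    return t_min * (t_max / t_min) ** (np.arange(n) / (n - 1))


def remc_sample(
    model: EnergyModel,
    a: RigidBodyStructure,
    b: RigidBodyStructure,
    box_edge: float,
    ladder: np.ndarray,
    n_steps: int,
    record_stride: int = 100,
    move_params: dict | None = None,
    seed: int = 0,
    exchange_interval: int = 100,
    n_adapt: int | None = None,
) -> ComplexEnsemble:
    """Sample rigid-body poses of ``b`` relative to the fixed body ``a``.

    Each MC step applies to every replica one Metropolis move of the mobile
    body: a rigid translation (uniform in a sphere) or a rotation (quaternion
    perturbation), chosen with equal probability.  Every
    ``exchange_interval`` steps a randomly chosen neighbor pair attempts a
    configuration swap with the standard parallel-tempering criterion.  Move
    magnitudes adapt toward ~30% acceptance during the first ``n_adapt``
    steps (these adaptation steps are discarded, keeping the production run
    a fixed-parameter Markov chain) and are frozen afterwards.

    Reproducible given ``seed``.  Per-replica acceptance statistics are
    attached to the returned ensemble.
    """
    ladder = np.asarray(ladder, dtype=float)
    if np.any(np.diff(ladder) <= 0) and len(ladder) > 1:
        raise ValueError("temperature ladder must be strictly increasing")
    if n_steps < record_stride:
        raise ValueError("n_steps must be at least record_stride")
    if box_edge < 2 * model.cutoff:
        raise ValueError("box edge must be at least twice the interaction cutoff")

    params = {"translation_step": 8.0, "rotation_step": 0.6, "adaptive": True}
    if move_params:
        params.update(move_params)
    if n_adapt is None:
        n_adapt = min(n_steps // 10, 5000) if params["adaptive"] else 0

    rng = np.random.default_rng(seed)
    n_rep = len(ladder)
    betas = 1.0 / (KB_KCAL * ladder)
    ev = model.bind(a, b)
    a_coords = a.coords
    bc = b.coords - b.coords.mean(axis=0)

    # fast path for single-bead bodies: scalar minimum-image distance and a
    # scalar energy; rotations of a point bead never change the energy
    point_bodies = (len(a) == 1 and len(b) == 1
                    and hasattr(model, "energy_scalar"))
    if point_bodies:
        ax, ay, az = (float(v) for v in a_coords[0])

        def energy_of(pos: np.ndarray) -> float:
            dx = pos[0, 0] - ax
            dy = pos[0, 1] - ay
            dz = pos[0, 2] - az
            dx -= box_edge * round(dx / box_edge)
            dy -= box_edge * round(dy / box_edge)
            dz -= box_edge * round(dz / box_edge)
            return model.energy_scalar(math.sqrt(dx * dx + dy * dy + dz * dz))
    else:
        def energy_of(pos: np.ndarray) -> float:
            return ev.total(_min_image_distances(a_coords, pos, box_edge))

    # per-replica state
    trans = np.empty((n_rep, 3))
    quats = np.empty((n_rep, 4))
    b_rot = np.empty((n_rep,) + bc.shape)
    energies = np.empty(n_rep)
    for k in range(n_rep):
        while True:
            t = rng.uniform(0, box_edge, size=3)
            q = _random_quat(rng)
            rot = _quat_to_mat(q)
            pos = bc @ rot.T + t
            e = energy_of(pos)
            if np.isfinite(e):
                break
        trans[k], quats[k], b_rot[k], energies[k] = t, q, pos - t, e

    dt = np.full(n_rep, params["translation_step"])
    dr = np.full(n_rep, params["rotation_step"])
    acc = np.zeros(n_rep)
    att = np.zeros(n_rep)
    acc_win = np.zeros(n_rep)
    att_win = np.zeros(n_rep)
    n_exch_acc = 0
    n_exch_att = 0

    n_records = n_steps // record_stride
    out_t = np.empty((n_rep, n_records, 3))
    out_q = np.empty((n_rep, n_records, 4))
    out_e = np.empty((n_rep, n_records))
    rec = 0

    total_steps = n_adapt + n_steps
    for step in range(total_steps):
        production = step >= n_adapt
        for k in range(n_rep):
            att[k] += 1
            att_win[k] += 1
            if rng.random() < 0.5:
                # translation: uniform in a sphere of radius dt[k]
                while True:
                    v = rng.uniform(-1.0, 1.0, size=3)
                    n2 = v @ v
                    if n2 <= 1.0:
                        break
                new_t = (trans[k] + dt[k] * v) % box_edge
                pos = b_rot[k] + new_t
                e = energy_of(pos)
                de = e - energies[k]
                if de <= 0 or (np.isfinite(de) and
                               rng.random() < math.exp(-betas[k] * de)):
                    trans[k] = new_t
                    energies[k] = e
                    acc[k] += 1
                    acc_win[k] += 1
            else:
                dq = _axis_angle_quat(rng.normal(size=3),
                                      rng.normal(0.0, dr[k]))
                new_q = _quat_mul(dq, quats[k])
                new_q /= np.linalg.norm(new_q)
                if point_bodies:
                    # a point bead has no orientation; the move is a no-op
                    quats[k] = new_q
                    acc[k] += 1
                    acc_win[k] += 1
                    continue
                rot = _quat_to_mat(new_q)
                new_brot = bc @ rot.T
                pos = new_brot + trans[k]
                e = energy_of(pos)
                de = e - energies[k]
                if de <= 0 or (np.isfinite(de) and
                               rng.random() < math.exp(-betas[k] * de)):
                    quats[k] = new_q
                    b_rot[k] = new_brot
                    energies[k] = e
                    acc[k] += 1
                    acc_win[k] += 1

        if not production and params["adaptive"] and (step + 1) % 200 == 0:
            for k in range(n_rep):
                if att_win[k] == 0:
                    continue
                rate = acc_win[k] / att_win[k]
                f = 1.1 if rate > 0.3 else 1 / 1.1
                dt[k] = min(dt[k] * f, box_edge / 2)
                dr[k] = min(dr[k] * f, math.pi)
            acc_win[:] = 0
            att_win[:] = 0

        if n_rep > 1 and (step + 1) % exchange_interval == 0:
            i = int(rng.integers(0, n_rep - 1))
            j = i + 1
            n_exch_att += 1
            delta = (betas[i] - betas[j]) * (energies[i] - energies[j])
            if delta >= 0 or rng.random() < math.exp(delta):
                for arr in (trans, quats, b_rot, energies):
                    arr[[i, j]] = arr[[j, i]]
                n_exch_acc += 1

        if production and (step - n_adapt + 1) % record_stride == 0:
            out_t[:, rec] = trans
            out_q[:, rec] = quats
            out_e[:, rec] = energies
            rec += 1

    return ComplexEnsemble(
        translations=out_t[:, :rec],
        quaternions=out_q[:, :rec],
        energies=out_e[:, :rec],
        ladder=ladder,
        box_edge=box_edge,
        record_stride=record_stride,
        body_a=a,
        body_b=b,
        acceptance={
            "move_rate": (acc / np.maximum(att, 1)).tolist(),
            "exchange_rate": n_exch_acc / max(n_exch_att, 1),
            "translation_step": dt.tolist(),
            "rotation_step": dr.tolist(),
        },
    )


def extract_bound(
    ensemble: ComplexEnsemble,
    distance_cut: float = 8.0,
    energy_cut: float = -2.0,
    t_ref: float = 300.0,
) -> ComplexEnsemble:
    """Mark bound poses: minimum inter-body bead distance ≤ ``distance_cut``
    (Å) and total energy ≤ ``energy_cut`` (in k_B·T at ``t_ref``).

    The mask is computed for every replica and stored on the ensemble, which
    is returned for chaining.
    """
    if ensemble.body_a is None or ensemble.body_b is None:
        raise ValueError("ensemble is missing its body structures")
    e_thresh = energy_cut * KB_KCAL * t_ref
    a_coords = ensemble.body_a.coords
    bc = ensemble.body_b.coords - ensemble.body_b.coords.mean(axis=0)
    mask = np.zeros(ensemble.energies.shape, dtype=bool)
    for k in range(ensemble.n_replicas):
        for s in range(ensemble.n_samples):
            if ensemble.energies[k, s] > e_thresh:
                continue
            rot = _quat_to_mat(ensemble.quaternions[k, s])
            pos = bc @ rot.T + ensemble.translations[k, s]
            r = _min_image_distances(a_coords, pos, ensemble.box_edge)
            mask[k, s] = r.min() <= distance_cut
    ensemble.bound_mask = mask
    return ensemble


def estimate_kd(per_box: list[tuple[float, float]],
                temperature: float = 300.0) -> KdEstimate:
    """Dissociation constant from bound fractions measured over box volumes.

    For one copy of each partner in volume V (Å³),
    ``Kd = (1 − P_b)² / (P_b · N_A · V)`` with V converted to liters.  The
    estimate is the mean over boxes; the uncertainty is the standard error
    over boxes (0 for a single box).  A consistency warning is raised if the
    per-box values spread by more than three standard errors.
    """
    kds = []
    for volume, p_b in per_box:
        if not (0.0 < p_b < 1.0):
            raise ValueError(
                f"bound fraction {p_b} at volume {volume} is 0 or 1; "
                "affinity unresolvable at this box size"
            )
        v_liters = volume * 1e-27
        kds.append((1.0 - p_b) ** 2 / (p_b * Avogadro * v_liters))
    kds = np.array(kds)
    kd = float(kds.mean())
    se = float(kds.std(ddof=1) / math.sqrt(len(kds))) if len(kds) > 1 else 0.0
    if len(kds) > 1 and se > 0 and (kds.max() - kds.min()) > 3 * se * math.sqrt(len(kds)):
        warnings.warn(
            "per-box Kd values are not volume-consistent (spread > 3×SE); "
            "check box sizes and sampling"
        )
    return KdEstimate(kd=kd, uncertainty=se, per_box=list(per_box), per_box_kd=kds)
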