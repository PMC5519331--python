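"""Generators and analytic oracles for end-to-end testing of the pipeline.

Every stage of the package can be exercised without external downloads:

* a hard-core/square-well two-body toy whose bound fraction and dissociation
  constant have closed forms, as the exact reference for the REMC sampler and
  the Kd estimator;
* small rigid bead bodies with an engineered complementary charged patch, so
  the docking pipeline has a known dominant binding mode;
* paired alignments Gibbs-sampled from a Potts model with planted
  inter-segment couplings and per-organism paralog multiplicity, emulating
  the inputs of the stochastic paralog-matching pipeline;
* two-state rigid-body trajectories with known dRMS and angular deviation.

All generators are reproducible from their seed, and each returns a truth
record sufficient to score any downstream prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Avogadro

from .cg_docking import KB_KCAL, SquareWellModel
from .geometry import inertia_frame
from .structures import FamilyMSA, RigidBodyStructure
from .trajectory import TwoBodyTrajectory

__all__ = [
    "SquareWellToy",
    "analytic_kd",
    "ToyComplexSpec",
    "generate_toy_complex",
    "PlantedPottsSpec",
    "generate_paired_msa",
    "gibbs_sample_potts",
    "generate_two_state_trajectory",
]


# ---------------------------------------------------------------------------
# Square-well toy with closed-form thermodynamics
# ---------------------------------------------------------------------------

@dataclass
class SquareWellToy:
    """Hard core + square well between two single-bead bodies in a periodic
    box.  ``well_depth`` is in units of k_B·T at ``t_ref``."""

    core_radius: float = 3.0
    well_radius: float = 8.0
    well_depth: float = 3.0
    box_edge: float = 100.0
    t_ref: float = 300.0

    def __post_init__(self) -> None:
        if not (0 < self.core_radius < self.well_radius < self.box_edge / 2):
            raise ValueError("need core_radius < well_radius < box_edge/2")

    def model(self, cutoff: float | None = None) -> SquareWellModel:
        return SquareWellModel(
            core_radius=self.core_radius,
            well_radius=self.well_radius,
            well_depth_kt=self.well_depth,
            t_ref=self.t_ref,
            cutoff=cutoff if cutoff is not None else self.well_radius + 2.0,
        )

    def bodies(self) -> tuple[RigidBodyStructure, RigidBodyStructure]:
        a = RigidBodyStructure([1], ["G"], [[0.0, 0.0, 0.0]], [0.0], label="toy A")
        b = RigidBodyStructure([1], ["G"], [[0.0, 0.0, 0.0]], [0.0], label="toy B")
        return a, b


def analytic_kd(toy: SquareWellToy,
                temperature: float = 300.0) -> tuple[float, float]:
    """Exact bound fraction and dissociation constant of the square-well toy.

    The configurational integral over the relative position splits into the
    bound shell V_b = (4π/3)(r_well³ − r_core³) with Boltzmann factor
    e^{βε}, and the free volume V_free = V_box − (4π/3)r_well³ (the hard
    core is excluded).  P_b = V_b·e^{βε}/(V_b·e^{βε} + V_free); Kd follows
    from the same one-pair-in-a-box relation the estimator uses,
    Kd = (1 − P_b)²/(P_b·N_A·V).  Returns ``(P_b, Kd)`` with Kd in molar.
    """
    eps_kcal = toy.well_depth * KB_KCAL * toy.t_ref
    beta_eps = eps_kcal / (KB_KCAL * temperature)
    v_box = toy.box_edge ** 3
    v_well = 4.0 / 3.0 * math.pi * toy.well_radius ** 3
    v_core = 4.0 / 3.0 * math.pi * toy.core_radius ** 3
    v_b = v_well - v_core
    v_free = v_box - v_well
    p_b = v_b * math.exp(beta_eps) / (v_b * math.exp(beta_eps) + v_free)
    kd = (1.0 - p_b) ** 2 / (p_b * Avogadro * v_box * 1e-27)
    return p_b, kd


# ---------------------------------------------------------------------------
# Toy rigid-body complex with an engineered binding patch
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    """Two small bead bodies with one complementary charged patch."""

    n_receptor: int = 12
    n_ligand: int = 8
    patch_size: int = 3
    patch_charge: float = 1.0        # per patch bead; ligand gets the opposite
    spacing: float = 4.0             # Å between consecutive beads
    charged: bool = True


def _bead_chain(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """A mildly kinked bead chain: consecutive beads at fixed spacing with
    small random direction changes (keeps the body non-collinear)."""
    coords = np.zeros((n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        perturb = rng.normal(scale=0.4, size=3)
        direction = direction + perturb
        direction /= np.linalg.norm(direction)
        coords[i] = coords[i - 1] + spacing * direction
    return coords - coords.mean(axis=0)


def generate_toy_complex(
    spec: ToyComplexSpec | None = None, seed: int = 0
) -> tuple[RigidBodyStructure, RigidBodyStructure, dict]:
    """Two rigid bead bodies whose terminal patches carry opposite charges.

    The receptor's patch residues are lysines (+1) and the ligand's are
    aspartates (−1) when ``spec.charged``; all other beads are neutral
    glycines/alanines.  The truth record lists the patch residue ids of both
    bodies, so contact-probability maps and lowest-energy poses can be scored
    against the designed interface.
    """
    if spec is None:
        spec = ToyComplexSpec()
    rng = np.random.default_rng(seed)
    rec_coords = _bead_chain(spec.n_receptor, spec.spacing, rng)
    lig_coords = _bead_chain(spec.n_ligand, spec.spacing, rng)

    rec_types = np.array(["A"] * spec.n_receptor, dtype="U1")
    lig_types = np.array(["G"] * spec.n_ligand, dtype="U1")
    rec_charges = np.zeros(spec.n_receptor)
    lig_charges = np.zeros(spec.n_ligand)
    rec_patch = list(range(spec.n_receptor - spec.patch_size, spec.n_receptor))
    lig_patch = list(range(spec.patch_size))
    if spec.charged:
        rec_types[rec_patch] = "K"
        lig_types[lig_patch] = "D"
        rec_charges[rec_patch] = spec.patch_charge
        lig_charges[lig_patch] = -spec.patch_charge

    rec_ids = np.arange(1, spec.n_receptor + 1)
    lig_ids = np.arange(1, spec.n_ligand + 1)
    receptor = RigidBodyStructure(rec_ids, rec_types, rec_coords, rec_charges,
                                  label="toy receptor")
    ligand = RigidBodyStructure(lig_ids, lig_types, lig_coords, lig_charges,
                                label="toy ligand")
    truth = {
        "receptor_patch_ids": [int(rec_ids[i]) for i in rec_patch],
        "ligand_patch_ids": [int(lig_ids[i]) for i in lig_patch],
        "charged": spec.charged,
    }
    return receptor, ligand, truth


# ---------------------------------------------------------------------------
# Planted-coupling Potts alignments with paralog structure
# ---------------------------------------------------------------------------

@dataclass
class PlantedPottsSpec:
    """Specification of a paired-alignment generator with planted couplings.

    ``planted_pairs`` are inter-segment column pairs ``(i, j)`` with
    ``0 ≤ i < n_a`` and ``0 ≤ j < n_b`` (j indexed within segment B); each
    carries a same-state ferromagnetic coupling of strength ``coupling``.
    ``paralog_distribution`` gives the probability of an organism carrying
    1, 2, ... interacting pairs.
    """

    n_a: int = 20
    n_b: int = 20
    planted_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: [(2, 4), (9, 11), (16, 17)])
    coupling: float = 3.0
    n_organisms: int = 300
    paralog_distribution: tuple[float, ...] = (0.5, 0.3, 0.2)
    alphabet_size: int = 21
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for i, j in self.planted_pairs:
            if not (0 <= i < self.n_a and 0 <= j < self.n_b):
                raise ValueError(f"planted pair ({i}, {j}) out of bounds")
        if self.coupling < 0:
            raise ValueError("coupling must be non-negative")


def gibbs_sample_potts(
    n_chains: int,
    n_sites: int,
    q: int,
    couplings: dict[tuple[int, int], np.ndarray],
    fields: np.ndarray | None,
    n_sweeps: int,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Gibbs-sample ``n_chains`` independent sequences from a Potts model.

    ``couplings`` maps ordered site pairs (i, j), i < j, to q×q matrices
    J_ij(a, b); ``fields`` is (n_sites, q) or None for zero fields.  Each
    sweep resamples every site of every chain from its full conditional.
    Chains are independent, so one sample per chain after burn-in is an
    exact-enough draw for the generator's purposes.
    """
    if fields is None:
        fields = np.zeros((n_sites, q))
    neighbors: dict[int, list[tuple[int, np.ndarray]]] = {
        i: [] for i in range(n_sites)}
    for (i, j), mat in couplings.items():
        if not (0 <= i < j < n_sites):
            raise ValueError(f"coupling pair ({i}, {j}) must satisfy i < j")
        mat = np.asarray(mat, dtype=float)
        neighbors[i].append((j, mat))          # logits_i(a) += J[a, x_j]
        neighbors[j].append((i, mat.T))
    x = (init.copy() if init is not None
         else rng.integers(0, q, size=(n_chains, n_sites)))
    rows = np.arange(n_chains)
    for _ in range(n_sweeps):
        for i in range(n_sites):
            logits = np.broadcast_to(fields[i], (n_chains, q)).copy()
            for j, mat in neighbors[i]:
                logits += mat[:, x[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n_chains)
            x[:, i] = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    return x


def generate_paired_msa(
    spec: PlantedPottsSpec,
) -> tuple[FamilyMSA, FamilyMSA, dict]:
    """Generate two family alignments from the planted Potts model.

    Each organism draws its number of interacting pairs from
    ``paralog_distribution``; every true pair's concatenated sequence is
    Gibbs-sampled from the planted model, then split at the segment boundary
    into the two family MSAs.  The true partner identity is recorded in the
    truth record but not exposed through the family alignments, exactly the
    situation the stochastic matching pipeline faces.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_a + spec.n_b
    q = spec.alphabet_size
    probs = np.asarray(spec.paralog_distribution, dtype=float)
    probs = probs / probs.sum()
    copy_counts = rng.choice(np.arange(1, len(probs) + 1),
                             size=spec.n_organisms, p=probs)
    n_pairs = int(copy_counts.sum())

    couplings = {}
    for i, j in spec.planted_pairs:
        couplings[(i, spec.n_a + j)] = spec.coupling * np.eye(q)
    seqs = gibbs_sample_potts(
        n_chains=n_pairs, n_sites=n_total, q=q, couplings=couplings,
        fields=None, n_sweeps=spec.burn_in, rng=rng)

    org_labels = np.repeat(
        [f"org{k:04d}" for k in range(spec.n_organisms)], copy_counts)
    row_ids = np.arange(n_pairs)
    labels_a = np.array([f"A{r:05d}" for r in row_ids])
    labels_b = np.array([f"B{r:05d}" for r in row_ids])

    # shuffle each family's row order within the whole alignment so the
    # matching pipeline cannot exploit row position
    perm_a = rng.permutation(n_pairs)
    perm_b = rng.permutation(n_pairs)
    fam_a = FamilyMSA(sequences=seqs[perm_a, :spec.n_a].astype(np.int8),
                      organism_ids=org_labels[perm_a],
                      labels=labels_a[perm_a])
    fam_b = FamilyMSA(sequences=seqs[perm_b, spec.n_a:].astype(np.int8),
                      organism_ids=org_labels[perm_b],
                      labels=labels_b[perm_b])
    truth = {
        "planted_pairs": list(spec.planted_pairs),
        "coupling": spec.coupling,
        "true_partners": {str(labels_a[r]): str(labels_b[r]) for r in row_ids},
        "copy_counts": copy_counts.tolist(),
    }
    return fam_a, fam_b, truth


# ---------------------------------------------------------------------------
# Two-state synthetic trajectories
# ---------------------------------------------------------------------------

def generate_two_state_trajectory(
    angle: float = 60.0,
    displacement: float = 10.0,
    populations: tuple[float, float] = (0.8, 0.2),
    noise: float = 0.0,
    n_frames: int = 200,
    seed: int = 0,
    dt_ns: float = 0.1,
) -> tuple[TwoBodyTrajectory, dict]:
    """Trajectory hopping between two rigid poses of a mobile body.

    State 0 is the reference placement; state 1 is rotated by ``angle``
    degrees about an axis perpendicular to the body's principal inertia axis
    (so the exact angular deviation equals ``angle``) and shifted by
    ``displacement`` Å.  Frames are drawn i.i.d. from ``populations``;
    optional isotropic Gaussian ``noise`` (Å per bead) is added.  The truth
    record carries the state sequence and the exact per-state dRMS and θ.
    """
    p0, p1 = populations
    if abs(p0 + p1 - 1.0) > 1e-9:
        raise ValueError("populations must sum to 1")
    rng = np.random.default_rng(seed)

    body_k = _bead_chain(10, 4.0, rng)
    body_j0 = _bead_chain(7, 4.0, rng)
    offset = np.array([25.0, 0.0, 0.0])
    j_state0 = body_j0 + offset

    i1 = inertia_frame(body_j0).axes[0]
    # rotation axis perpendicular to the principal axis
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, i1)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    axis = np.cross(i1, helper)
    axis /= np.linalg.norm(axis)
    theta = math.radians(angle)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + math.sin(theta) * kx + (1 - math.cos(theta)) * kx @ kx
    j_state1 = body_j0 @ rot.T + offset + np.array([0.0, displacement, 0.0])

    states = (rng.random(n_frames) < p1).astype(int)
    states[0] = 0                                # reference frame is state 0
    coords_j = np.empty((n_frames, body_j0.shape[0], 3))
    coords_k = np.empty((n_frames, body_k.shape[0], 3))
    for t in range(n_frames):
        cj = j_state1 if states[t] else j_state0
        coords_j[t] = cj + rng.normal(scale=noise, size=cj.shape) if noise else cj
        coords_k[t] = (body_k + rng.normal(scale=noise, size=body_k.shape)
                       if noise else body_k)

    d0 = np.linalg.norm(j_state0[:, None, :] - body_k[None, :, :], axis=-1)
    d1 = np.linalg.norm(j_state1[:, None, :] - body_k[None, :, :], axis=-1)
    drms_state1 = float(np.sqrt(np.mean((d1 - d0) ** 2)))

    traj = TwoBodyTrajectory(
        coords_j=coords_j,
        coords_k=coords_k,
        time_values=np.arange(n_frames) * dt_ns,
        reference_frame=0,
    )
    truth = {
        "states": states,
        "theta_state1": float(angle),
        "drms_state1": drms_state1,
        "populations": (p0, p1),
    }
    return traj, truth
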