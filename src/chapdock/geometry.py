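"""Orientational analysis of bound ensembles.

The binding geometry of the mobile body (the J-domain in the chaperone
application) relative to the fixed body (the Hsp70 nucleotide-binding domain)
is described in the fixed body's inertia frame: the spherical polar angles of
the mobile body's center of mass locate the binding site, and three Euler
angles built from the two bodies' inertia axes give the relative orientation.
Free-energy surfaces over angle pairs, per-residue contact probabilities and
neighbor-count clustering into binding modes complete the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cg_docking import KB_KCAL, ComplexEnsemble, _min_image_distances, _quat_to_mat
from .structures import RigidBodyStructure

__all__ = [
    "InertiaFrame",
    "AngularCoordinates",
    "FreeEnergySurface",
    "BindingModeClusters",
    "inertia_frame",
    "spherical_coords",
    "euler_angles",
    "euler_to_matrix",
    "free_energy_surface",
    "contact_probability",
    "cluster_bound",
    "mode_free_energy_gap",
]


@dataclass
class InertiaFrame:
    """Center of mass and principal inertia axes, ordered by decreasing moment.

    ``axes[0]`` (I₁) is the axis with the *largest* moment of inertia.  The
    frame is orthonormal and right-handed; each axis is sign-fixed so its
    largest-magnitude component is positive (the third axis may be flipped to
    restore handedness), making frames reproducible across runs.
    """

    origin: np.ndarray
    axes: np.ndarray                 # (3, 3), rows are I₁, I₂, I₃

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("axes are not orthonormal")
        if abs(np.linalg.det(self.axes) - 1.0) > 1e-9:
            raise ValueError("axes are not right-handed")


@dataclass
class AngularCoordinates:
    """Spherical (Φ_com, Ω_com) and Euler (Θ, Ω, Ψ) angles, degrees."""

    phi_com: float
    omega_com: float
    theta: float
    omega: float
    psi: float
    gimbal_flag: bool = False


def inertia_frame(coords: np.ndarray,
                  masses: np.ndarray | None = None) -> InertiaFrame:
    """Principal-axis frame of a point set (equal masses by default).

    Raises on degenerate tensors (two moments equal within 1e-6 relative),
    where the principal directions are not unique.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    x = coords - com
    r2 = np.sum(x * x, axis=1)
    tensor = np.einsum("k,kij->ij",
                       masses,
                       r2[:, None, None] * np.eye(3)[None]
                       - x[:, :, None] * x[:, None, :])
    moments, vecs = np.linalg.eigh(tensor)        # ascending
    order = np.argsort(moments)[::-1]             # descending moment
    moments = moments[order]
    axes = vecs[:, order].T                       # rows
    scale = max(abs(moments[0]), 1e-30)
    for a, b in ((0, 1), (1, 2)):
        if abs(moments[a] - moments[b]) / scale < 1e-6:
            raise ValueError(
                f"degenerate inertia tensor: moments {a + 1} and {b + 1} "
                f"coincide ({moments[a]:.6g} vs {moments[b]:.6g})"
            )
    # sign convention: largest-|component| positive for I1 and I2,
    # I3 then fixed by right-handedness
    for i in range(2):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return InertiaFrame(origin=com, axes=axes)


def spherical_coords(point: np.ndarray, frame: InertiaFrame) -> tuple[float, float]:
    """Spherical polar angles (degrees) of ``point`` in an inertia frame.

    The polar angle Φ is measured from I₁ (0° along I₁, 90° in the I₂–I₃
    plane); the azimuth Ω is atan2 of the I₃ and I₂ components, in
    (−180°, 180°].
    """
    v = np.asarray(point, dtype=float) - frame.origin
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero displacement from the frame origin")
    v = frame.axes @ v / norm                     # components along I1, I2, I3
    phi = math.degrees(math.acos(np.clip(v[0], -1.0, 1.0)))
    omega = math.degrees(math.atan2(v[2], v[1]))
    if omega <= -180.0:
        omega += 360.0
    return phi, omega


def euler_angles(jd_frame: InertiaFrame,
                 nbd_frame: InertiaFrame) -> tuple[float, float, float, bool]:
    """Euler angles (Θ, Ω, Ψ) in degrees of one inertia frame relative to
    another, plus a gimbal-lock flag.

    With I_aᴶ·I_bᴷ the direction cosines between the two frames' axes:
    Θ = asin(I₁ᴶ·I₂ᴷ), Ω = atan2(I₂ᴶ·I₂ᴷ/cosΘ, −I₃ᴶ·I₂ᴷ/cosΘ),
    Ψ = atan2(I₁ᴶ·I₃ᴷ/cosΘ, I₁ᴶ·I₁ᴷ/cosΘ).  At gimbal lock
    (|I₁ᴶ·I₂ᴷ| = 1) only Ω+Ψ is defined; the flag is set and the joint angle
    is returned in Ω with Ψ = 0.
    """
    m = jd_frame.axes @ nbd_frame.axes.T          # m[a, b] = I_aJ · I_bK
    s = np.clip(m[0, 1], -1.0, 1.0)
    theta = math.asin(s)
    c = math.cos(theta)
    if abs(abs(s) - 1.0) < 1e-12 or c < 1e-12:
        # gimbal lock: report the joint angle
        joint = math.degrees(math.atan2(m[1, 2], m[1, 1]))
        return math.degrees(theta), joint, 0.0, True
    omega = math.degrees(math.atan2(m[1, 1] / c, -m[2, 1] / c))
    psi = math.degrees(math.atan2(m[0, 2] / c, m[0, 0] / c))
    # atan2 yields [−180, 180]; the declared range is (−180, 180]
    if omega <= -180.0:
        omega = 180.0
    if psi <= -180.0:
        psi = 180.0
    return math.degrees(theta), omega, psi, False


def euler_to_matrix(theta: float, omega: float, psi: float) -> np.ndarray:
    """Direction-cosine matrix m[a, b] = I_aᴶ·I_bᴷ reconstructed from the
    Euler angles (degrees); the inverse of :func:`euler_angles` away from
    gimbal lock."""
    th, om, ps = map(math.radians, (theta, omega, psi))
    ct, st = math.cos(th), math.sin(th)
    i1 = np.array([ct * math.cos(ps), st, ct * math.sin(ps)])
    # orthonormal basis perpendicular to i1 in which Ω places I2
    e_a = np.array([-st * math.cos(ps), ct, -st * math.sin(ps)])
    e_b = np.array([-math.sin(ps), 0.0, math.cos(ps)])
    i2 = math.sin(om) * e_a + math.cos(om) * e_b
    i3 = np.cross(i1, i2)
    return np.vstack([i1, i2, i3])


@dataclass
class FreeEnergySurface:
    """−k_B·T·ln of a normalized 2-D histogram, min-shifted to zero.

    Empty bins carry NaN in ``values`` (no data, not +∞); ``counts`` holds the
    raw histogram.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray               # k_B·T units unless kcal requested
    counts: np.ndarray
    temperature: float


def free_energy_surface(samples_x: np.ndarray, samples_y: np.ndarray,
                        bins=None, temperature: float = 300.0,
                        ranges=None, units: str = "kt") -> FreeEnergySurface:
    """Histogram-based free-energy surface over an angle pair.

    Default binning is 5° bins over the data range (or ``ranges`` when
    given).  ``units`` is ``"kt"`` or ``"kcal"``.
    """
    x = np.asarray(samples_x, dtype=float)
    y = np.asarray(samples_y, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sample")
    if bins is None:
        if ranges is None:
            ranges = ((x.min(), x.max() + 1e-9), (y.min(), y.max() + 1e-9))
        bins = (
            max(1, int(math.ceil((ranges[0][1] - ranges[0][0]) / 5.0))),
            max(1, int(math.ceil((ranges[1][1] - ranges[1][0]) / 5.0))),
        )
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=ranges)
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        f = -np.log(p)
    f[counts == 0] = np.nan
    f -= np.nanmin(f)
    if units == "kcal":
        f = f * KB_KCAL * temperature
    return FreeEnergySurface(x_edges=xe, y_edges=ye, values=f,
                             counts=counts, temperature=temperature)


def contact_probability(ensemble: ComplexEnsemble,
                        distance_cut: float = 8.0,
                        replica: int | None = None,
                        temperature: float = 300.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue probability of being in contact with the partner.

    For each residue of either body, the fraction of *bound* poses in which
    at least one partner Cα lies within ``distance_cut`` Å (minimum image).
    Returns ``(p_a, p_b)`` aligned with the two bodies' residue orderings.
    """
    if ensemble.bound_mask is None:
        raise ValueError("bound_mask not computed; call extract_bound first")
    if replica is None:
        replica = ensemble.replica_nearest(temperature)
    idx = np.flatnonzero(ensemble.bound_mask[replica])
    if idx.size == 0:
        raise ValueError("bound ensemble is empty")
    a = ensemble.body_a
    b = ensemble.body_b
    bc = b.coords - b.coords.mean(axis=0)
    n_a, n_b = len(a), len(b)
    hits_a = np.zeros(n_a)
    hits_b = np.zeros(n_b)
    for s in idx:
        rot = _quat_to_mat(ensemble.quaternions[replica, s])
        pos = bc @ rot.T + ensemble.translations[replica, s]
        r = _min_image_distances(a.coords, pos, ensemble.box_edge)
        close = r <= distance_cut
        hits_a += close.any(axis=1)
        hits_b += close.any(axis=0)
    return hits_a / idx.size, hits_b / idx.size


@dataclass
class BindingModeClusters:
    """Binding modes from neighbor-count clustering of bound poses."""

    assignments: np.ndarray          # (n_poses,) cluster id, by descending size
    centers: np.ndarray              # (n_clusters,) pose index of each center
    populations: np.ndarray          # fractional occupancies, non-increasing

    def __post_init__(self) -> None:
        if np.any(np.diff(self.populations) > 1e-12):
            raise ValueError("populations must be non-increasing")


def _pairwise_ligand_rmsd(coords: np.ndarray) -> np.ndarray:
    """Pairwise RMSD between ligand coordinate sets (n_poses, n_beads, 3).

    The receptor is rigid and identically placed in every pose, so no
    superposition is needed: ligand RMSD in the common frame isolates the
    binding-mode geometry.
    """
    n = coords.shape[0]
    flat = coords.reshape(n, -1)
    sq = np.sum(flat * flat, axis=1)
    g = flat @ flat.T
    d2 = (sq[:, None] + sq[None, :] - 2 * g) / coords.shape[1]
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def cluster_bound(ensemble: ComplexEnsemble,
                  cutoff: float = 5.0,
                  replica: int | None = None,
                  temperature: float = 300.0,
                  max_poses: int | None = None,
                  seed: int = 0) -> BindingModeClusters:
    """Neighbor-count (Daura-style) clustering of the bound poses.

    The pose with the most neighbors within ``cutoff`` Å ligand-Cα RMSD
    becomes a cluster center; it and its neighbors are removed and the step
    repeats.  Ties break toward the lowest pose index, making the result
    deterministic given the pose ordering.  ``max_poses`` optionally
    subsamples large ensembles (seeded) before the O(n²) RMSD matrix.
    """
    if ensemble.bound_mask is None:
        raise ValueError("bound_mask not computed; call extract_bound first")
    if replica is None:
        replica = ensemble.replica_nearest(temperature)
    idx = np.flatnonzero(ensemble.bound_mask[replica])
    if idx.size == 0:
        raise ValueError("no bound poses to cluster")
    if max_poses is not None and idx.size > max_poses:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_poses, replace=False))
    coords = np.array([ensemble.ligand_coords(replica, s) for s in idx])
    rmsd = _pairwise_ligand_rmsd(coords)
    return cluster_rmsd_matrix(rmsd, cutoff)


def cluster_rmsd_matrix(rmsd: np.ndarray, cutoff: float) -> BindingModeClusters:
    """Neighbor-count clustering of a precomputed pairwise RMSD matrix."""
    n = rmsd.shape[0]
    adj = rmsd <= cutoff
    np.fill_diagonal(adj, True)
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centers, sizes = [], []
    cid = 0
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))          # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & remaining)
        assignments[members] = cid
        centers.append(center)
        sizes.append(len(members))
        remaining[members] = False
        cid += 1
    sizes = np.asarray(sizes, dtype=float)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(len(order), dtype=int)
    relabel[order] = np.arange(len(order))
    return BindingModeClusters(
        assignments=relabel[assignments],
        centers=np.asarray(centers)[order],
        populations=sizes[order] / n,
    )


def mode_free_energy_gap(clusters: BindingModeClusters,
                         temperature: float = 300.0) -> float:
    """Free-energy gap −k_B·T·ln(p₂/p₁) between the two largest binding
    modes, in kcal/mol (positive when the first mode dominates)."""
    if len(clusters.populations) < 2:
        raise ValueError("need at least two clusters")
    p1, p2 = clusters.populations[:2]
    return -KB_KCAL * temperature * math.log(p2 / p1)
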