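"""Frame-wise stability metrics for two-body trajectories.

Given time-ordered Cα coordinates of a mobile body J and a reference body K,
the module computes the inter-protein distance-matrix RMS deviation (dRMS)
from a reference frame, the angular deviation θ of J's principal inertia
axis, and named inter-residue distance traces.  These are generic trajectory
metrics: the frames can come from molecular dynamics, from the CG sampler, or
from the synthetic two-state generator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import inertia_frame

__all__ = [
    "TwoBodyTrajectory",
    "drms",
    "angular_deviation",
    "contact_distance_traces",
]


@dataclass
class TwoBodyTrajectory:
    """Time-ordered Cα coordinates of two bodies.

    ``coords_j``/``coords_k`` have shape (n_frames, n_residues, 3); optional
    ``time_values`` are in ns.  ``residue_ids_*`` resolve named residue pairs
    for distance traces.
    """

    coords_j: np.ndarray
    coords_k: np.ndarray
    time_values: np.ndarray | None = None
    reference_frame: int = 0
    residue_ids_j: np.ndarray | None = None
    residue_ids_k: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords_j = np.asarray(self.coords_j, dtype=float)
        self.coords_k = np.asarray(self.coords_k, dtype=float)
        if self.coords_j.ndim != 3 or self.coords_k.ndim != 3:
            raise ValueError("coordinates must be (frames, residues, 3)")
        if self.coords_j.shape[0] != self.coords_k.shape[0]:
            raise ValueError("bodies must have the same number of frames")
        if self.coords_j.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.time_values is not None:
            self.time_values = np.asarray(self.time_values, dtype=float)
            if len(self.time_values) != self.n_frames:
                raise ValueError("time_values length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords_j.shape[0]

    def _index_j(self, residue_id) -> int:
        if self.residue_ids_j is None:
            return int(residue_id)
        hit = np.flatnonzero(self.residue_ids_j == residue_id)
        if hit.size == 0:
            raise KeyError(f"residue {residue_id} not in body J")
        return int(hit[0])

    def _index_k(self, residue_id) -> int:
        if self.residue_ids_k is None:
            return int(residue_id)
        hit = np.flatnonzero(self.residue_ids_k == residue_id)
        if hit.size == 0:
            raise KeyError(f"residue {residue_id} not in body K")
        return int(hit[0])


def _window_slice(traj: TwoBodyTrajectory, window: float | None) -> slice:
    """Trailing window: last ``window`` ns when time metadata exists (default
    10 ns), else the last third of the frames."""
    if traj.time_values is not None:
        w = 10.0 if window is None else window
        t_end = traj.time_values[-1]
        start = int(np.searchsorted(traj.time_values, t_end - w))
        return slice(min(start, traj.n_frames - 1), traj.n_frames)
    if window is not None:
        warnings.warn("window given but trajectory has no time metadata; "
                      "using the last third of frames")
    return slice(max(0, traj.n_frames - max(1, traj.n_frames // 3)),
                 traj.n_frames)


def _distance_matrices(traj: TwoBodyTrajectory) -> np.ndarray:
    disp = traj.coords_j[:, :, None, :] - traj.coords_k[:, None, :, :]
    return np.sqrt(np.sum(disp * disp, axis=-1))


def drms(traj: TwoBodyTrajectory,
         window: float | None = None) -> tuple[np.ndarray, float]:
    """Inter-body distance-matrix RMS deviation per frame, and its trailing
    window average.

    For each frame t, dRMS(t) = sqrt(mean over all inter-body residue pairs
    of (d_ij(t) − d_ij(t₀))²) with t₀ the reference frame.  Invariant under
    any rigid transformation of a whole frame.
    """
    d = _distance_matrices(traj)
    d0 = d[traj.reference_frame]
    per_frame = np.sqrt(np.mean((d - d0[None]) ** 2, axis=(1, 2)))
    win = _window_slice(traj, window)
    return per_frame, float(per_frame[win].mean())


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares superposition: rotation R and translation t with
    R @ q_i + t ≈ p_i."""
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, pc - r @ qc


def angular_deviation(traj: TwoBodyTrajectory,
                      align: bool = True,
                      window: float | None = None
                      ) -> tuple[np.ndarray, float]:
    """Angle (degrees) between body J's largest-moment inertia axis at each
    frame and at the reference frame.

    With ``align`` (default), each frame is first rigid-body superposed so
    that body K matches its reference coordinates (the transform is applied
    to both bodies), which removes global tumbling.  The axis sign is kept
    continuous between consecutive frames (positive dot product with the
    previous frame's axis) to avoid spurious 180° jumps.  Returns per-frame θ
    in [0, 180] and the trailing-window average.
    """
    ref = traj.reference_frame
    k_ref = traj.coords_k[ref]
    axes = np.empty((traj.n_frames, 3))
    prev = None
    for t in range(traj.n_frames):
        cj = traj.coords_j[t]
        if align:
            r, trans = _kabsch(k_ref, traj.coords_k[t])
            cj = cj @ r.T + trans
        ax = inertia_frame(cj).axes[0]
        if prev is not None and np.dot(ax, prev) < 0:
            ax = -ax
        axes[t] = ax
        prev = ax
    ref_axis = axes[ref]
    cosang = np.clip(axes @ ref_axis, -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    win = _window_slice(traj, window)
    return theta, float(theta[win].mean())


def contact_distance_traces(traj: TwoBodyTrajectory,
                            pairs: list[tuple],
                            bins: int = 50) -> pd.DataFrame:
    """Cα–Cα distance per frame for named (residue_j, residue_k) pairs.

    Returns a DataFrame with one column per pair (named ``"J<id>-K<id>"``)
    plus the time axis when present.  Pooled histograms are available via
    ``numpy.histogram`` on the columns; ``bins`` is kept for the convenience
    attribute ``df.attrs["histograms"]``.
    """
    data = {}
    for rj, rk in pairs:
        ij = traj._index_j(rj)
        ik = traj._index_k(rk)
        d = np.linalg.norm(traj.coords_j[:, ij] - traj.coords_k[:, ik], axis=1)
        data[f"J{rj}-K{rk}"] = d
    df = pd.DataFrame(data)
    if traj.time_values is not None:
        df.insert(0, "time_ns", traj.time_values)
    hists = {
        name: np.histogram(df[name].to_numpy(), bins=bins)
        for name in data
    }
    df.attrs["histograms"] = hists
    return df
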