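"""Representative-structure extraction via density-peak clustering.

The pairwise RMSD matrix of the core active site (key residues, iron-oxo
centre and substrate, superposed per pair) is clustered with the
density-peak algorithm: each frame gets a local density rho and a separation
delta (distance to the nearest frame of higher density); cluster centres are
the frames with anomalously large gamma = rho * delta, and each remaining
frame joins the cluster of its nearest higher-density neighbour.  The centre
of the most populated cluster is the representative structure of a binding
mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, GeometryError, InsufficientDataError
from .modeclass import FrameLabel, Mode, frames_in_mode
from .structio import SelectionSpec, Topology, Trajectory, select_atoms


@dataclass
class RMSDMatrix:
    """Symmetric pairwise superposed-RMSD matrix (Å) over trajectory frames."""

    values: np.ndarray
    selection: SelectionSpec | None = None
    frame_indices: np.ndarray | None = None  # original frame ids of the rows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD matrix must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("RMSD matrix diagonal must be zero")
        if self.frame_indices is None:
            self.frame_indices = np.arange(n)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class DPCParams:
    """Density-peak hyperparameters.

    ``d_c`` "auto" uses the 2nd percentile of the off-diagonal distance
    distribution (the usual neighbourhood heuristic).  ``n_centers`` "auto"
    picks the split with the largest relative gap in the sorted gamma values.
    """

    d_c: float | str = "auto"
    kernel: str = "gaussian"  # or "hard"
    n_centers: int | str = "auto"

    def __post_init__(self) -> None:
        if isinstance(self.d_c, (int, float)) and self.d_c <= 0:
            raise ValueError("d_c must be > 0 when numeric")
        if self.kernel not in ("gaussian", "hard"):
            raise ValueError(f"Unknown kernel {self.kernel!r}")


@dataclass
class DPCResult:
    rho: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    centers: list[int]
    assignment: np.ndarray
    nearest_higher: np.ndarray
    d_c: float


def pairwise_rmsd_matrix(traj: Trajectory, top: Topology,
                         selection: SelectionSpec,
                         frames: list[int] | None = None) -> RMSDMatrix:
    """Entry (i, j) = Kabsch-superposed RMSD of the selected atoms between
    frames i and j.  ``frames`` restricts (and indexes) the rows."""
    idx = select_atoms(top, selection)
    if len(idx) < 3:
        raise GeometryError(f"RMSD selection must contain >= 3 atoms, got {len(idx)}")
    frame_list = list(range(traj.n_frames)) if frames is None else list(frames)
    coords = traj.coords[np.asarray(frame_list)][:, idx, :]  # (n, N, 3)
    n = len(frame_list)
    # centre once; pairwise superposed RMSD via per-pair SVD of the 3x3 cross-covariance
    centred = coords - coords.mean(axis=1, keepdims=True)
    values = np.zeros((n, n))
    for i in range(n):
        Pi = centred[i]
        for j in range(i + 1, n):
            Qj = centred[j]
            H = Pi.T @ Qj
            U, S, Vt = np.linalg.svd(H)
            if np.linalg.det(Vt.T @ U.T) < 0:
                S = S.copy()
                S[-1] = -S[-1]
            msd = ((Pi ** 2).sum() + (Qj ** 2).sum() - 2.0 * S.sum()) / Pi.shape[0]
            values[i, j] = values[j, i] = np.sqrt(max(msd, 0.0))
    return RMSDMatrix(values=values, selection=selection,
                      frame_indices=np.asarray(frame_list))


def _auto_dc(values: np.ndarray) -> float:
    """Neighbourhood heuristic: d_c at the 2nd percentile of the
    off-diagonal distances, clamped so each point keeps on the order of two
    neighbours within d_c on small matrices."""
    n = values.shape[0]
    off = values[~np.eye(n, dtype=bool)]
    pct = max(2.0, 200.0 / n)
    d_c = float(np.percentile(off, pct))
    if d_c <= 0:
        positive = off[off > 0]
        d_c = float(positive.min()) if positive.size else 0.0
    return d_c


def _auto_n_centers(gamma_sorted: np.ndarray) -> int:
    """Largest relative gap in the descending normalized gamma sequence,
    searched only where the leading gamma is still substantial (>= 10% of
    the maximum) so that noise in the tail cannot spawn centres."""
    n = gamma_sorted.size
    if n == 1 or gamma_sorted[0] <= 0:
        return 1
    g = gamma_sorted / gamma_sorted[0]
    eps = 0.01  # damping floor: keeps near-zero tails from exploding ratios
    best_k, best_ratio = 1, -np.inf
    for k in range(1, min(n - 1, 10) + 1):
        if g[k - 1] < 0.1:
            break
        ratio = (g[k - 1] + eps) / (g[k] + eps)
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    return best_k


def dpc_cluster(matrix: RMSDMatrix, params: DPCParams | None = None) -> DPCResult:
    """Density-peak clustering of a distance matrix.

    rho_i = sum_j exp(-(d_ij/d_c)^2) for the gaussian kernel (count of
    neighbours within d_c for "hard"); delta_i = distance to the nearest
    point of strictly higher density (index order breaks rho ties), with the
    global density maximum assigned delta = max_j d_ij.  Non-centres join
    the cluster of their nearest higher-density neighbour, processed in
    descending-rho order.
    """
    params = params or DPCParams()
    D = matrix.values
    n = matrix.n
    if n < 2:
        raise InsufficientDataError("Need >= 2 points to cluster")
    if np.allclose(D, 0.0):
        raise DegenerateInputError("All pairwise distances are zero")

    d_c = _auto_dc(D) if params.d_c == "auto" else float(params.d_c)
    if d_c <= 0:
        raise DegenerateInputError("d_c collapsed to zero on this matrix")

    if params.kernel == "gaussian":
        K = np.exp(-((D / d_c) ** 2))
        np.fill_diagonal(K, 0.0)
        rho = K.sum(axis=1)
    else:
        rho = ((D <= d_c).sum(axis=1) - 1).astype(float)

    # rho ties broken by index order: j is "higher" than i iff rho_j > rho_i,
    # or rho_j == rho_i and j < i.  This yields a strict total order, so
    # exactly one point (the global maximum) has no higher neighbour.
    order = np.lexsort((np.arange(n), -rho))  # descending rho, ascending index
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    delta = np.empty(n)
    nearest_higher = np.full(n, -1, dtype=int)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = D[i].max()
            continue
        higher = order[:pos]
        d_to_higher = D[i, higher]
        best = int(np.argmin(d_to_higher))
        delta[i] = float(d_to_higher[best])
        nearest_higher[i] = int(higher[best])

    gamma = rho * delta
    gamma_order = np.lexsort((np.arange(n), -gamma))
    gamma_sorted = gamma[gamma_order]
    k = _auto_n_centers(gamma_sorted) if params.n_centers == "auto" else int(params.n_centers)
    k = max(1, min(k, n))
    centers = sorted(int(i) for i in gamma_order[:k])

    assignment = np.full(n, -1, dtype=int)
    for cid, c in enumerate(centers):
        assignment[c] = cid
    for i in order:  # descending rho: the nearest-higher is already assigned
        if assignment[i] == -1:
            if nearest_higher[i] >= 0:
                assignment[i] = assignment[nearest_higher[i]]
            else:  # density maximum not chosen as a centre: join nearest centre
                assignment[i] = int(np.argmin([D[i, c] for c in centers]))

    return DPCResult(rho=rho, delta=delta, gamma=gamma, centers=centers,
                     assignment=assignment, nearest_higher=nearest_higher, d_c=d_c)


@dataclass
class RepresentativeResult:
    """Per-mode representative frame indices; modes that could not be
    clustered carry an error message instead."""

    frames: dict[Mode, int] = field(default_factory=dict)
    errors: dict[Mode, str] = field(default_factory=dict)


def representative_frames(traj: Trajectory, top: Topology,
                          labels: list[FrameLabel], selection: SelectionSpec,
                          params: DPCParams | None = None,
                          modes: tuple[Mode, ...] = (Mode.MODE1, Mode.MODE2),
                          ) -> RepresentativeResult:
    """Representative frame of each requested mode: cluster the mode's frames
    by active-site RMSD and return the centre of the most populated cluster
    (ties: lowest frame index)."""
    result = RepresentativeResult()
    for mode in modes:
        frame_idx = frames_in_mode(labels, mode)
        if len(frame_idx) < 2:
            result.errors[mode] = (
                f"{mode.value}: need >= 2 frames to extract a representative, "
                f"got {len(frame_idx)}"
            )
            continue
        sub = pairwise_rmsd_matrix(traj, top, selection, frames=frame_idx)
        try:
            dpc = dpc_cluster(sub, params)
        except DegenerateInputError:
            # all mode frames identical: any frame represents the mode
            result.frames[mode] = int(min(frame_idx))
            continue
        sizes = np.bincount(dpc.assignment, minlength=len(dpc.centers))
        best_cluster = int(np.argmax(sizes))  # argmax takes the lowest id on ties
        center_local = dpc.centers[best_cluster]
        result.frames[mode] = int(sub.frame_indices[center_local])
    return result
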