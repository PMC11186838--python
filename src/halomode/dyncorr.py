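"""Dynamic cross-correlation analysis (DCCA) of atomic motions.

After superposing every frame onto an iteratively refined mean structure,
the displacement of atom i at frame t is dr_i(t) = r_i(t) - <r_i>, and the
correlation between atoms i and j is

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

with entries in [-1, 1] and unit diagonal.  Positive values mean concerted
motion (e.g. a second-sphere residue moving with the substrate), negative
values anti-correlated motion.  Correlation against a multi-atom group (a
whole ligand, a phosphate group) is computed on the group's geometric-centre
displacement.

A principal-component decomposition of the displacement covariance is
exposed as a secondary diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, InsufficientDataError
from .structio import SelectionSpec, Topology, Trajectory, select_atoms


@dataclass
class DCCAMatrix:
    """Correlation matrix over selected atoms/groups.

    Rows of atoms with zero displacement variance are undefined: their
    entries are NaN markers and their positions are listed in ``undefined``
    (the diagonal of such rows is still reported NaN, never propagated into
    other rows).
    """

    values: np.ndarray
    labels: list[str]
    undefined: list[int] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _batch_fit(coords: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Kabsch-superpose every frame of ``coords`` (T, N, 3) onto ``mean``
    (N, 3) in one batched SVD (reflections excluded)."""
    centroid = mean.mean(axis=0)
    Qc = mean - centroid
    Pc = coords - coords.mean(axis=1, keepdims=True)
    H = np.einsum("tni,nj->tij", Pc, Qc)
    U, _S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("tji,tkj->tik", Vt, U))  # det(V @ U^T)
    scale = np.ones((coords.shape[0], 1, 3))
    scale[:, 0, 2] = np.sign(det)
    R = (Vt.transpose(0, 2, 1) * scale) @ U.transpose(0, 2, 1)
    return np.einsum("tni,tji->tnj", Pc, R) + centroid


def _superposed_selection(traj: Trajectory, idx: list[int]) -> np.ndarray:
    """(T, N, 3) coordinates of the selection, each frame Kabsch-superposed
    onto the iterated mean structure."""
    coords = traj.coords[:, idx, :].astype(float)
    mean = coords[0].copy()
    for _ in range(10):
        fitted = _batch_fit(coords, mean)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if shift < 1e-6:
            break
    return _batch_fit(coords, mean)


def mean_structure(traj: Trajectory, top: Topology, selection: SelectionSpec) -> np.ndarray:
    """Iterated mean: superpose all frames on the current mean, re-average,
    until the mean shifts < 1e-6 Å RMSD (at most 10 iterations)."""
    if traj.n_frames < 2:
        raise InsufficientDataError("mean_structure needs >= 2 frames")
    idx = select_atoms(top, selection)
    if len(idx) < 3:
        raise GeometryError("mean_structure needs >= 3 selected atoms")
    return _superposed_selection(traj, idx).mean(axis=0)


def dcca_matrix(traj: Trajectory, top: Topology, selection: SelectionSpec,
                groups: dict[str, SelectionSpec] | None = None) -> DCCAMatrix:
    """Normalized displacement cross-correlations over a selection.

    ``groups`` appends extra rows computed on geometric-centre displacements
    of multi-atom selections (superposed in the same shared frame as the
    primary selection so ligand-vs-residue couplings are meaningful).
    """
    if traj.n_frames < 3:
        raise InsufficientDataError("dcca_matrix needs >= 3 frames")
    idx = select_atoms(top, selection)
    if len(idx) < 3:
        raise GeometryError("dcca_matrix needs >= 3 selected atoms")

    group_items = list((groups or {}).items())
    group_idx = [select_atoms(top, spec) for _, spec in group_items]
    # superpose on the union so every tracked atom shares one frame of reference
    union = sorted(set(idx).union(*[set(g) for g in group_idx]) if group_idx else set(idx))
    pos_in_union = {a: k for k, a in enumerate(union)}
    fitted = _superposed_selection(traj, union)

    series = [fitted[:, pos_in_union[a], :] for a in idx]
    for g in group_idx:
        series.append(fitted[:, [pos_in_union[a] for a in g], :].mean(axis=1))
    X = np.stack(series, axis=0)  # (n, T, 3)
    disp = X - X.mean(axis=1, keepdims=True)

    inner = np.einsum("itk,jtk->ij", disp, disp) / disp.shape[1]
    var = np.diag(inner).copy()
    # sub-1e-10 Å displacements are numerically indistinguishable from a
    # static atom after superposition round-off
    undefined = [i for i in range(len(series)) if var[i] <= 1e-20]
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = inner / denom
    for i in range(len(series)):
        if i not in undefined:
            C[i, i] = 1.0
    for i in undefined:
        C[i, :] = np.nan
        C[:, i] = np.nan
    C = np.clip(C, -1.0, 1.0, out=C, where=~np.isnan(C))

    labels = []
    for a in idx:
        atom = top.atoms[a]
        labels.append(f"{atom.res_name}{atom.res_id}:{atom.name}")
    labels.extend(name for name, _ in group_items)
    return DCCAMatrix(values=C, labels=labels, undefined=undefined)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    modes: np.ndarray  # (3N, k) top eigenvectors
    explained_fraction: np.ndarray


def displacement_pca(traj: Trajectory, top: Topology, selection: SelectionSpec,
                     n_modes: int = 3) -> PCAResult:
    """Principal components of the superposed displacement covariance
    (secondary diagnostic; eigenvalues in Å^2)."""
    idx = select_atoms(top, selection)
    if len(idx) < 3:
        raise GeometryError("displacement_pca needs >= 3 selected atoms")
    fitted = _superposed_selection(traj, idx)
    T = fitted.shape[0]
    flat = fitted.reshape(T, -1)
    flat = flat - flat.mean(axis=0, keepdims=True)
    cov = flat.T @ flat / (T - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    k = min(n_modes, evals.size)
    total = float(evals.sum()) or 1.0
    return PCAResult(eigenvalues=evals, modes=evecs[:, :k],
                     explained_fraction=evals[:k] / total)


def plot_dcca_heatmap(matrix: DCCAMatrix, path: str) -> None:
    """Optional heatmap of the correlation matrix (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.labels)))
    ax.set_yticks(range(len(matrix.labels)))
    ax.set_xticklabels(matrix.labels, rotation=90, fontsize=6)
    ax.set_yticklabels(matrix.labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
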