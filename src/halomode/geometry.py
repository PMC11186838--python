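"""Core geometric operators: distances, hydrogen bonds, Kabsch superposition, RMSD.

Hydrogen bonds are detected by the heavy-atom criterion used throughout the
analysis: donor N/O to acceptor O distance of at most 3.2 Å (inclusive).  An
optional donor–H–acceptor angle gate is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, GeometryError
from .structio import Topology, Trajectory

HBOND_CUTOFF_DEFAULT = 3.2  # Å, heavy atom to heavy atom


@dataclass(frozen=True)
class HBond:
    """One donor–acceptor contact; distance is heavy atom to heavy atom (Å)."""

    donor_atom: int
    acceptor_atom: int
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.angle is not None and not 0.0 <= self.angle <= 180.0:
            raise ValueError("angle must be in [0, 180] degrees")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation/translation mapping P onto Q, with the residual RMSD."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float

    def apply(self, P: np.ndarray) -> np.ndarray:
        return np.asarray(P, dtype=float) @ self.rotation.T + self.translation


def pair_distance(traj: Trajectory, frame: int, i: int, j: int) -> float:
    """Euclidean distance (Å) between atoms i and j in one frame."""
    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {traj.n_frames})")
    for idx in (i, j):
        if not 0 <= idx < traj.n_atoms:
            raise IndexError(f"atom index {idx} out of range [0, {traj.n_atoms})")
    return float(np.linalg.norm(traj.coords[frame, i] - traj.coords[frame, j]))


def min_pair_distance(traj: Trajectory, frame: int,
                      group_a: list[int], group_b: list[int]) -> float:
    """Minimum distance between two atom groups in one frame (Å)."""
    A = traj.coords[frame, group_a]  # (na, 3)
    B = traj.coords[frame, group_b]  # (nb, 3)
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return float(d.min())


def _resolve_hydrogens(traj: Trajectory, frame: int, top: Topology,
                       donor: int, bond_max: float = 1.3) -> list[int]:
    """Hydrogens covalently attached to a donor: same residue, name starts with
    H, within ``bond_max`` Å in this frame."""
    d_atom = top.atoms[donor]
    out = []
    for atom in top.atoms:
        if atom.res_id != d_atom.res_id or atom.chain != d_atom.chain:
            continue
        if not atom.name.startswith("H"):
            continue
        if np.linalg.norm(traj.coords[frame, atom.index] - traj.coords[frame, donor]) <= bond_max:
            out.append(atom.index)
    return out


def detect_hbonds(traj: Trajectory, frame: int, top: Topology,
                  donors: list[int], acceptors: list[int],
                  cutoff: float = HBOND_CUTOFF_DEFAULT,
                  angle_min: float | None = None) -> list[HBond]:
    """All donor–acceptor pairs within the distance cutoff (inclusive).

    Self-pairs are skipped.  When ``angle_min`` is set, the donor–H–acceptor
    angle of some attached hydrogen must additionally reach ``angle_min``
    degrees; a donor with no resolvable hydrogen is then a configuration
    error.  Results are sorted by distance ascending (ties by index).
    """
    coords = traj.coords[frame]
    out: list[HBond] = []
    for d in donors:
        for a in acceptors:
            if d == a:
                continue
            dist = float(np.linalg.norm(coords[d] - coords[a]))
            if dist > cutoff:
                continue
            angle = None
            if angle_min is not None:
                hydrogens = _resolve_hydrogens(traj, frame, top, d)
                if not hydrogens:
                    raise ConfigError(
                        f"angle_min set but no hydrogen resolvable for donor atom {d} "
                        f"({top.atoms[d].name}/{top.atoms[d].res_name}{top.atoms[d].res_id})"
                    )
                best = 0.0
                for h in hydrogens:
                    v1 = coords[d] - coords[h]
                    v2 = coords[a] - coords[h]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    best = max(best, float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
                if best < angle_min:
                    continue
                angle = best
            out.append(HBond(donor_atom=d, acceptor_atom=a, distance=dist, angle=angle))
    out.sort(key=lambda h: (h.distance, h.donor_atom, h.acceptor_atom))
    return out


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation + translation minimizing RMSD of P onto Q.

    Reflections are excluded (det(R) = +1), so a mirrored point set keeps a
    positive residual.  Collinear or too-small point sets are rejected: with
    fewer than two independent directions the rotation is not determined.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(f"P and Q must both be (N, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"Need at least 3 points, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise GeometryError("Degenerate (collinear or coincident) point set")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    diff = Pc @ R.T - Qc
    val = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=val)


def rmsd(P: np.ndarray, Q: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation (Å); optionally after Kabsch superposition."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError(f"Shape mismatch: {P.shape} vs {Q.shape}")
    if superpose:
        return kabsch_superpose(P, Q).rmsd
    return float(np.sqrt(((P - Q) ** 2).sum(axis=1).mean()))
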