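"""Multi-frame structure I/O and atom selection.

Frames are the MODEL records of a single PDB file (a file without MODEL
records is read as one frame).  Coordinates are stored in a ``T x A x 3``
float array in Angstrom, with the atom order of the first model defining the
order of every frame.  ``res_id`` follows the 1-based PDB convention; atom
indices are 0-based everywhere inside the package.

Only the plain ATOM/HETATM/MODEL/ENDMDL subset is supported: no altlocs,
insertion codes or unit cells.  Inputs are assumed imaged/whole — there is no
periodic-boundary handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, PDBFormatError, SelectionError

# Heavy-atom names treated as hydrogen-bond donors/acceptors by default.
# Protein side-chain/backbone N and O donors plus nucleotide hydroxyls;
# acceptors cover carbonyl/carboxylate O, phosphate O and the ferryl oxo.
DEFAULT_DONOR_NAMES = frozenset(
    {"N", "NE", "NH1", "NH2", "NZ", "ND1", "NE2", "ND2", "OG", "OG1", "OH",
     "O3'", "O5'", "N1", "N2", "N6"}
)
DEFAULT_ACCEPTOR_NAMES = frozenset(
    {"O", "OD1", "OD2", "OE1", "OE2", "O1P", "O2P", "O3P", "OP1", "OP2",
     "OP3", "O3'", "O4'", "O5'", "O1", "OH"}
)


@dataclass(frozen=True)
class Atom:
    """Metadata for one atom; ``index`` is its 0-based position in the topology."""

    index: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str

    def __post_init__(self) -> None:
        if self.res_id < 1:
            raise ValueError(f"res_id must be >= 1 (PDB convention), got {self.res_id}")


@dataclass
class Topology:
    """Ordered atom list; the order is the coordinate order of every frame."""

    atoms: list[Atom]
    donor_names: frozenset[str] = DEFAULT_DONOR_NAMES
    acceptor_names: frozenset[str] = DEFAULT_ACCEPTOR_NAMES

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Topology must contain at least one atom")
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("Atom indices must be 0..A-1 in order")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def donor_indices(self, subset: Iterable[int] | None = None) -> list[int]:
        """Indices of atoms whose name is in ``donor_names`` (optionally within a subset)."""
        pool = self.atoms if subset is None else [self.atoms[i] for i in subset]
        return [a.index for a in pool if a.name in self.donor_names]

    def acceptor_indices(self, subset: Iterable[int] | None = None) -> list[int]:
        pool = self.atoms if subset is None else [self.atoms[i] for i in subset]
        return [a.index for a in pool if a.name in self.acceptor_names]


@dataclass
class Trajectory:
    """Coordinate frames in Angstrom, shape ``(n_frames, n_atoms, 3)``."""

    coords: np.ndarray
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (T, A, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.coords.shape[0])
        else:
            self.frame_ids = np.asarray(self.frame_ids, dtype=int)
            if self.frame_ids.shape[0] != self.coords.shape[0]:
                raise ValueError("frame_ids length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class ResidueTerm:
    """One residue selector: res_id (1-based), optional chain, optional atom names."""

    res_id: int
    chain: str | None = None
    names: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SelectionSpec:
    """Union of residue terms and/or explicit 0-based atom indices."""

    residues: tuple[ResidueTerm, ...] = ()
    indices: tuple[int, ...] = ()

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionSpec":
        """Build from the config dialect, e.g.
        ``{"residues": [{"res_id": 178, "names": ["NH1","NH2","NE"]}]}`` or
        ``{"indices": [3, 4, 5]}``."""
        residues = []
        for term in d.get("residues", []):
            names = term.get("names")
            residues.append(
                ResidueTerm(
                    res_id=int(term["res_id"]),
                    chain=term.get("chain"),
                    names=tuple(names) if names is not None else None,
                )
            )
        return cls(residues=tuple(residues), indices=tuple(d.get("indices", ())))

    def describe(self) -> str:
        parts = []
        for t in self.residues:
            s = f"res {t.res_id}"
            if t.chain:
                s += f"/{t.chain}"
            if t.names:
                s += f" [{','.join(t.names)}]"
            parts.append(s)
        if self.indices:
            parts.append(f"indices {list(self.indices)}")
        return "; ".join(parts) if parts else "<empty spec>"


def select_atoms(top: Topology, spec: SelectionSpec) -> list[int]:
    """Resolve a SelectionSpec to a sorted, duplicate-free 0-based index list.

    Raises :class:`SelectionError` if nothing matches or an explicit index is
    out of range.  The result is independent of the order of spec terms.
    """
    hits: set[int] = set()
    for term in spec.residues:
        for atom in top.atoms:
            if atom.res_id != term.res_id:
                continue
            if term.chain is not None and atom.chain != term.chain:
                continue
            if term.names is not None and atom.name not in term.names:
                continue
            hits.add(atom.index)
    for idx in spec.indices:
        if not 0 <= idx < top.n_atoms:
            raise SelectionError(
                f"Explicit atom index {idx} out of range for topology of "
                f"{top.n_atoms} atoms ({spec.describe()})"
            )
        hits.add(idx)
    if not hits:
        raise SelectionError(f"Selection matched no atoms: {spec.describe()}")
    return sorted(hits)


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, tuple[float, float, float]]:
    try:
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or " "
        res_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            # fall back to first alphabetic character of the atom name
            element = next((c for c in name if c.isalpha()), "X")
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"Unparseable ATOM/HETATM record at line {lineno}: {exc}") from exc
    # Atom.index is assigned by the caller, use a placeholder here.
    return Atom(0, name, element, res_name, res_id, chain), (x, y, z)


def read_pdb_models(path: str | Path) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-model) PDB file into a Topology + Trajectory.

    Every model must contain the same atoms in the same order; a mismatch is a
    :class:`PDBFormatError` naming the offending model.  A file without MODEL
    records is returned as a single frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    frames: list[list[tuple[float, float, float]]] = []
    metas: list[list[tuple[str, str, int, str]]] = []
    current_xyz: list[tuple[float, float, float]] | None = None
    current_meta: list[tuple[str, str, int, str]] | None = None
    atoms: list[Atom] = []
    model_numbers: list[int] = []
    saw_model = False

    def _flush() -> None:
        nonlocal current_xyz, current_meta
        if current_xyz is not None:
            frames.append(current_xyz)
            metas.append(current_meta or [])
        current_xyz, current_meta = None, None

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model = True
                _flush()
                try:
                    model_numbers.append(int(line.split()[1]))
                except (IndexError, ValueError):
                    model_numbers.append(len(frames) + 1)
                current_xyz, current_meta = [], []
            elif record == "ENDMDL":
                _flush()
            elif record in ("ATOM", "HETATM"):
                if current_xyz is None:
                    current_xyz, current_meta = [], []
                    if saw_model:
                        model_numbers.append(len(frames) + 1)
                atom, xyz = _parse_atom_record(line, lineno)
                if not frames:  # still in the first model: collect topology
                    atoms.append(
                        Atom(len(atoms), atom.name, atom.element,
                             atom.res_name, atom.res_id, atom.chain)
                    )
                current_xyz.append(xyz)
                current_meta.append((atom.name, atom.res_name, atom.res_id, atom.chain))
        _flush()

    if not frames:
        raise PDBFormatError(f"No ATOM/HETATM records found in {path}")
    if not model_numbers:
        model_numbers = [1]

    ref_meta = metas[0]
    for k, meta in enumerate(metas[1:], start=2):
        model_no = model_numbers[k - 1] if k - 1 < len(model_numbers) else k
        if len(meta) != len(ref_meta):
            raise PDBFormatError(
                f"Model {model_no} of {path.name} has {len(meta)} atoms; "
                f"model {model_numbers[0]} has {len(ref_meta)}"
            )
        for i, (a, b) in enumerate(zip(meta, ref_meta)):
            if a != b:
                raise PDBFormatError(
                    f"Model {model_no} of {path.name}: atom {i} is "
                    f"{a[0]}/{a[1]}{a[2]}, expected {b[0]}/{b[1]}{b[2]}"
                )

    top = Topology(atoms=atoms)
    coords = np.array(frames, dtype=float)
    return top, Trajectory(coords=coords)


_PDB_ATOM_FMT = (
    "{record:<6s}{serial:>5d} {name:<4s}{res_name:>4s} {chain:1s}"
    "{res_id:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)

_HET_RES_NAMES = {"FEO", "CLA", "HOH", "NUC", "SUB"}


def _format_atom_line(atom: Atom, xyz: np.ndarray, serial: int) -> str:
    # PDB column rules: 4-char names start in column 13, shorter names in 14.
    name = atom.name if len(atom.name) >= 4 else f" {atom.name}"
    record = "HETATM" if atom.res_name in _HET_RES_NAMES else "ATOM"
    return _PDB_ATOM_FMT.format(
        record=record, serial=serial, name=f"{name:<4s}", res_name=atom.res_name,
        chain=atom.chain, res_id=atom.res_id, x=xyz[0], y=xyz[1], z=xyz[2],
        occ=1.00, b=0.00, element=atom.element[:2],
    )


def write_frame_pdb(top: Topology, traj: Trajectory, frame: int, path: str | Path) -> None:
    """Write one frame as a single-model PDB (coordinates to 3 decimals)."""
    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {traj.n_frames})")
    if traj.n_atoms != top.n_atoms:
        raise GeometryError("Topology/Trajectory atom counts differ")
    with Path(path).open("w") as fh:
        for atom in top.atoms:
            fh.write(_format_atom_line(atom, traj.coords[frame, atom.index], atom.index + 1))
        fh.write("END\n")


def write_models_pdb(top: Topology, traj: Trajectory, path: str | Path,
                     frames: Sequence[int] | None = None) -> None:
    """Write several frames as MODEL/ENDMDL records of one PDB file."""
    frame_list = range(traj.n_frames) if frames is None else frames
    with Path(path).open("w") as fh:
        for model_no, frame in enumerate(frame_list, start=1):
            if not 0 <= frame < traj.n_frames:
                raise IndexError(f"frame {frame} out of range [0, {traj.n_frames})")
            fh.write(f"MODEL     {model_no:>4d}\n")
            for atom in top.atoms:
                fh.write(_format_atom_line(atom, traj.coords[frame, atom.index], atom.index + 1))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_xyz_frames(path: str | Path, top: Topology) -> Trajectory:
    """Plain-text XYZ multi-frame reader behind the same Trajectory contract.

    Standard XYZ blocks: atom count, comment line, then ``name x y z`` rows.
    Atom names must match the topology order in every frame.
    """
    path = Path(path)
    frames: list[list[list[float]]] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise PDBFormatError(f"Bad XYZ atom count at line {pos + 1}") from exc
        if n != top.n_atoms:
            raise PDBFormatError(
                f"XYZ frame {len(frames) + 1} has {n} atoms; topology has {top.n_atoms}"
            )
        block = lines[pos + 2: pos + 2 + n]
        if len(block) < n:
            raise PDBFormatError(f"Truncated XYZ frame starting at line {pos + 1}")
        frame = []
        for i, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise PDBFormatError(f"Bad XYZ row at line {pos + 3 + i}")
            frame.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(frame)
        pos += 2 + n
    if not frames:
        raise PDBFormatError(f"No frames found in {path}")
    return Trajectory(coords=np.array(frames, dtype=float))
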