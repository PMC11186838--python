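"""Sequence triage: pairwise global alignment, percent identity, facial-triad calls.

Fe(II)/alpha-ketoglutarate oxygenases bind iron through a 2-His facial triad:
hydroxylases carry a 2-His-1-carboxylate motif (HXD/E), while halogenases
replace the carboxylate with a small residue (HXG/A), opening a halide
coordination site.  Candidate sequences are therefore triaged by the residue
at the third triad position, located by alignment against a curated
reference rather than a bare motif scan (the pattern "HX[GA]" alone matches
promiscuously; a regex scanner is provided only as a labelled heuristic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

IDENTITY_CONVENTIONS = ("aligned_columns", "shorter_seq", "full_alignment")


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence; 20 standard residues plus X, uppercase."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        seq = self.sequence.upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in VALID_AA:
                raise ValueError(f"{self.id}: illegal character {ch!r} at position {pos}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment as two equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float
    denominator_convention: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("Gapped strings must have equal length")


@dataclass(frozen=True)
class TriadCall:
    """Facial-triad classification of a query sequence.

    Positions are 1-based in the query; any of them is None when the
    corresponding reference position maps to a gap.
    """

    his1_pos: int | None
    x_pos: int | None
    third_pos: int | None
    third_residue: str | None
    call: str  # HXD_E_hydroxylase_like | HXG_A_halogenase_like | unclassified


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return [SeqRecord(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def _build_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(a: SeqRecord, b: SeqRecord, matrix: str = "BLOSUM62",
                 gap_open: float = -10.0, gap_extend: float = -0.5,
                 convention: str = "aligned_columns") -> AlignmentResult:
    """Optimal global alignment under affine gap penalties (Gotoh).

    The first alignment in the aligner's deterministic traceback order is
    reported when optima tie.  Identity is computed under ``convention``
    (see :func:`percent_identity`) and recorded with the result.
    """
    aligner = _build_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(a.sequence, b.sequence)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    result = AlignmentResult(
        aligned_a=aligned_a, aligned_b=aligned_b, score=float(alignment.score),
        identity_percent=0.0, denominator_convention=convention,
    )
    identity = percent_identity(result, convention)
    return AlignmentResult(
        aligned_a=aligned_a, aligned_b=aligned_b, score=float(alignment.score),
        identity_percent=identity, denominator_convention=convention,
    )


def percent_identity(aln: AlignmentResult, convention: str = "aligned_columns") -> float:
    """100 * identical columns / denominator.

    Conventions: ``aligned_columns`` counts only gap-free columns in the
    denominator (default); ``shorter_seq`` divides by the shorter input
    length; ``full_alignment`` divides by the alignment length.
    """
    if convention not in IDENTITY_CONVENTIONS:
        raise ValueError(f"Unknown identity convention {convention!r}")
    matches = 0
    gapfree = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            gapfree += 1
            if x == y:
                matches += 1
    if convention == "aligned_columns":
        denom = gapfree
    elif convention == "shorter_seq":
        denom = min(len(aln.aligned_a.replace("-", "")), len(aln.aligned_b.replace("-", "")))
    else:
        denom = len(aln.aligned_a)
    if denom == 0:
        raise ValueError("Zero-length denominator for percent identity")
    return 100.0 * matches / denom


def _map_positions_through(aligned_ref: str, aligned_query: str,
                           ref_positions: tuple[int, ...]) -> list[tuple[int | None, str | None]]:
    """Map 1-based reference positions through an alignment; returns
    (query_position, query_residue) per reference position, None on gaps."""
    wanted = set(ref_positions)
    found: dict[int, tuple[int | None, str | None]] = {}
    ref_pos = 0
    query_pos = 0
    for rc, qc in zip(aligned_ref, aligned_query):
        if rc != "-":
            ref_pos += 1
        if qc != "-":
            query_pos += 1
        if rc != "-" and ref_pos in wanted:
            found[ref_pos] = (query_pos, qc) if qc != "-" else (None, None)
    return [found.get(p, (None, None)) for p in ref_positions]


def call_facial_triad(query: SeqRecord, reference: SeqRecord,
                      ref_triad_positions: tuple[int, int, int],
                      matrix: str = "BLOSUM62", gap_open: float = -10.0,
                      gap_extend: float = -0.5) -> TriadCall:
    """Classify the query's facial triad by alignment against a reference.

    The reference triad positions (1-based) must read H, any, D/E/G/A in the
    reference itself.  The query is aligned globally; the call follows the
    query residue at the mapped third position: D/E -> hydroxylase-like,
    G/A -> halogenase-like; a non-His first position, a gap, or any other
    residue leaves the query unclassified.
    """
    p1, p2, p3 = ref_triad_positions
    if not (1 <= p1 < p2 < p3 <= len(reference)):
        raise ValueError(
            f"Reference triad positions {ref_triad_positions} out of range or "
            f"not strictly increasing for sequence of length {len(reference)}"
        )
    if reference.sequence[p1 - 1] != "H":
        raise ValueError(f"Reference position {p1} is {reference.sequence[p1 - 1]}, expected H")
    third_ref = reference.sequence[p3 - 1]
    if third_ref not in "DEGA":
        raise ValueError(f"Reference position {p3} is {third_ref}, expected D/E/G/A")

    aln = global_align(reference, query, matrix=matrix,
                       gap_open=gap_open, gap_extend=gap_extend)
    mapped = _map_positions_through(aln.aligned_a, aln.aligned_b, (p1, p2, p3))
    (h_pos, h_res), (x_pos, _x_res), (t_pos, t_res) = mapped

    call = "unclassified"
    if h_res == "H" and t_res is not None:
        if t_res in "DE":
            call = "HXD_E_hydroxylase_like"
        elif t_res in "GA":
            call = "HXG_A_halogenase_like"
    return TriadCall(his1_pos=h_pos, x_pos=x_pos, third_pos=t_pos,
                     third_residue=t_res, call=call)


def scan_triad_candidates(seq: SeqRecord) -> list[tuple[int, str, str]]:
    """Heuristic regex scan for H-X-[GADE] windows (1-based start position,
    matched triplet, coarse class).  Promiscuous by construction — use
    :func:`call_facial_triad` for actual triage."""
    out = []
    for m in re.finditer(r"(?=(H.[GADE]))", seq.sequence):
        triplet = m.group(1)
        cls = ("HXG_A_halogenase_like" if triplet[2] in "GA"
               else "HXD_E_hydroxylase_like")
        out.append((m.start() + 1, triplet, cls))
    return out
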