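"""Synthetic active-site trajectories with known ground truth.

The generator emulates the statistical structure of a halogenase active
site in which the nucleotide's 5'-phosphate stochastically switches between
hydrogen-bonding two arginine anchors (binding modes 1 and 2) or neither
("other"), and within each mode the reacting-atom distances fall inside or
outside the catalytic-competence cutoffs with a per-mode probability.  It
is a statistical emulation, not physics: distances are drawn directly from
(truncated) normal distributions and atoms are placed along fixed
directions to realize them, so the classifier's inputs carry exactly the
drawn geometry plus isotropic jitter on the unconstrained atoms.

Mode switching is a saturated Markov chain with a persistence knob:
P(m -> m) = rho + (1 - rho) * pi_m and P(m -> m') = (1 - rho) * pi_m', so the
stationary distribution is pi for every rho and rho = 0 reduces to i.i.d.
sampling (keeping binomial error formulas exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import SpecError
from .modeclass import (CriteriaConfig, D_CCL_MAX_DEFAULT, D_OH_MAX_DEFAULT,
                        Mode)
from .geometry import HBOND_CUTOFF_DEFAULT
from .structio import Atom, ResidueTerm, SelectionSpec, Topology, Trajectory


@dataclass(frozen=True)
class DistSpec:
    """Truncated normal distribution for one distance (Å)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SpecError("sd must be >= 0")
        if not self.lower < self.upper:
            raise SpecError(f"Empty truncation bounds [{self.lower}, {self.upper}]")
        if self.sd == 0 and not self.lower <= self.mean <= self.upper:
            raise SpecError("Constant distance outside its truncation bounds")

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.sd == 0:
            return np.full(size, self.mean) if size else self.mean
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=size, random_state=rng)


@dataclass(frozen=True)
class ModeGeometry:
    """Per-mode geometry template.

    ``anchor`` is "A" (mode-1 arginine), "B" (mode-2 arginine) or None (no
    anchor contact).  When the marginal distributions are set, d_O-H and
    d_C2'-Cl are drawn from them for every frame of the mode and the
    productive flag is DERIVED from the cutoffs; otherwise the flag is drawn
    Bernoulli(q_m) first and the distances come from the in/out-of-cutoff
    distributions accordingly.
    """

    anchor: str | None
    anchor_dist: DistSpec = DistSpec(2.9, 0.1, 2.4, HBOND_CUTOFF_DEFAULT)
    d_OH_in: DistSpec = DistSpec(2.8, 0.2, 2.2, D_OH_MAX_DEFAULT)
    d_CCl_in: DistSpec = DistSpec(4.2, 0.2, 3.5, D_CCL_MAX_DEFAULT)
    d_OH_out: DistSpec = DistSpec(4.3, 0.2, D_OH_MAX_DEFAULT + 0.2, 5.5)
    d_CCl_out: DistSpec = DistSpec(5.7, 0.2, D_CCL_MAX_DEFAULT + 0.2, 7.0)
    d_OH_marginal: DistSpec | None = None
    d_CCl_marginal: DistSpec | None = None

    def __post_init__(self) -> None:
        if self.anchor not in (None, "A", "B"):
            raise SpecError(f"anchor must be 'A', 'B' or None, got {self.anchor!r}")
        if self.anchor is not None and self.anchor_dist.upper > HBOND_CUTOFF_DEFAULT:
            raise SpecError("anchor_dist truncation must lie within the H-bond cutoff")
        if self.d_OH_in.upper > D_OH_MAX_DEFAULT or self.d_OH_in.lower < 0:
            raise SpecError("d_OH_in bounds must lie within [0, d_OH_max]")
        if self.d_CCl_in.upper > D_CCL_MAX_DEFAULT or self.d_CCl_in.lower < 0:
            raise SpecError("d_CCl_in bounds must lie within [0, d_CCl_max]")
        if self.d_OH_out.lower <= D_OH_MAX_DEFAULT:
            raise SpecError("d_OH_out bounds must lie above d_OH_max")
        if self.d_CCl_out.lower <= D_CCL_MAX_DEFAULT:
            raise SpecError("d_CCl_out bounds must lie above d_CCl_max")


_MODES = (Mode.MODE1, Mode.MODE2, Mode.OTHER)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic study condition."""

    n_frames: int
    occupancies: tuple[float, float, float]  # (pi_M1, pi_M2, pi_other)
    productive_prob: dict[Mode, float] = field(
        default_factory=lambda: {Mode.MODE1: 0.5, Mode.MODE2: 0.5, Mode.OTHER: 0.0})
    geometry: dict[Mode, ModeGeometry] = field(default_factory=lambda: {
        Mode.MODE1: ModeGeometry(anchor="A"),
        Mode.MODE2: ModeGeometry(anchor="B"),
        Mode.OTHER: ModeGeometry(anchor=None),
    })
    persistence: float = 0.0
    jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SpecError("n_frames must be >= 1")
        if abs(sum(self.occupancies) - 1.0) > 1e-12:
            raise SpecError(f"Occupancies must sum to 1, got {sum(self.occupancies)}")
        if any(p < 0 for p in self.occupancies):
            raise SpecError("Occupancies must be non-negative")
        if not 0.0 <= self.persistence < 1.0:
            raise SpecError("persistence must be in [0, 1)")
        for m in _MODES:
            q = self.productive_prob.get(m, 0.0)
            if not 0.0 <= q <= 1.0:
                raise SpecError(f"productive_prob[{m.value}] must be in [0, 1]")
        if self.jitter_sd < 0:
            raise SpecError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame labels as drawn by the generator."""

    modes: tuple[Mode, ...]
    productive: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.modes) != len(self.productive):
            raise SpecError("GroundTruth arrays must have equal length")


# ---------------------------------------------------------------------------
# Template topology: a ~30-atom toy active site with two arginine anchors,
# an iron-oxo/chloride centre and a phosphorylated substrate.

SUBSTRATE_RES_ID = 401
FEO_RES_ID = 301
ANCHOR_A_RES_ID = 178  # mode-1 arginine (CtNTH numbering)
ANCHOR_B_RES_ID = 238  # mode-2 arginine
LYS_RES_ID = 108

# Sites: anchor guanidinium groups 18 Å apart along x, iron centre below the
# substrate site, "other"-mode phosphate parked at +y away from both anchors.
_ANCHOR_A_NH1 = np.array([-9.0, 0.0, 0.0])
_ANCHOR_B_NH1 = np.array([9.0, 0.0, 0.0])
_OTHER_SITE = np.array([0.0, 8.0, 0.0])
_APPROACH = {"A": np.array([1.0, 0.0, 0.0]),
             "B": np.array([-1.0, 0.0, 0.0]),
             None: np.array([0.0, 1.0, 0.0])}

_FE = np.array([0.0, -4.0, 2.0])
_OXO = _FE + np.array([0.0, 0.8, 1.4])     # ferryl oxygen
_CL = _FE + np.array([2.3, 0.0, 0.0])      # chloride ligand
_OH_DIR = np.array([0.0, 0.6, 0.8])        # unit: oxo -> substrate H
_CCL_DIR = np.array([0.0, 0.6, 0.8])       # unit: Cl -> substrate C2'

_TEMPLATE = [
    # (name, element, res_name, res_id, chain, xyz, constrained)
    ("CA", "C", "ARG", ANCHOR_A_RES_ID, "A", (-12.0, 0.0, 0.0), False),
    ("CZ", "C", "ARG", ANCHOR_A_RES_ID, "A", (-9.8, 0.0, 0.0), False),
    ("NE", "N", "ARG", ANCHOR_A_RES_ID, "A", (-10.2, 0.8, 0.0), True),
    ("NH1", "N", "ARG", ANCHOR_A_RES_ID, "A", tuple(_ANCHOR_A_NH1), True),
    ("NH2", "N", "ARG", ANCHOR_A_RES_ID, "A", (-10.2, -0.8, 0.0), True),
    ("CA", "C", "ARG", ANCHOR_B_RES_ID, "A", (12.0, 0.0, 0.0), False),
    ("CZ", "C", "ARG", ANCHOR_B_RES_ID, "A", (9.8, 0.0, 0.0), False),
    ("NE", "N", "ARG", ANCHOR_B_RES_ID, "A", (10.2, 0.8, 0.0), True),
    ("NH1", "N", "ARG", ANCHOR_B_RES_ID, "A", tuple(_ANCHOR_B_NH1), True),
    ("NH2", "N", "ARG", ANCHOR_B_RES_ID, "A", (10.2, -0.8, 0.0), True),
    ("CA", "C", "LYS", LYS_RES_ID, "A", (-5.0, 5.5, 0.0), False),
    ("NZ", "N", "LYS", LYS_RES_ID, "A", (-6.0, 2.8, 0.0), False),
    ("FE", "FE", "FEO", FEO_RES_ID, "A", tuple(_FE), False),
    ("O1", "O", "FEO", FEO_RES_ID, "A", tuple(_OXO), True),
    ("CL", "CL", "FEO", FEO_RES_ID, "A", tuple(_CL), True),
    ("P", "P", "NUC", SUBSTRATE_RES_ID, "A", (0.0, 0.0, 0.0), True),
    ("O1P", "O", "NUC", SUBSTRATE_RES_ID, "A", (0.0, 0.0, 0.0), True),
    ("O2P", "O", "NUC", SUBSTRATE_RES_ID, "A", (0.0, 0.0, 0.0), True),
    ("O3P", "O", "NUC", SUBSTRATE_RES_ID, "A", (0.0, 0.0, 0.0), True),
    ("O5'", "O", "NUC", SUBSTRATE_RES_ID, "A", (3.6, 2.5, 7.0), False),
    ("C5'", "C", "NUC", SUBSTRATE_RES_ID, "A", (4.5, 1.8, 6.5), False),
    ("C4'", "C", "NUC", SUBSTRATE_RES_ID, "A", (4.8, 0.5, 5.8), False),
    ("O4'", "O", "NUC", SUBSTRATE_RES_ID, "A", (4.0, 1.2, 5.0), False),
    ("C3'", "C", "NUC", SUBSTRATE_RES_ID, "A", (4.5, -1.0, 5.0), False),
    ("O3'", "O", "NUC", SUBSTRATE_RES_ID, "A", (5.5, -1.5, 5.5), False),
    ("C2'", "C", "NUC", SUBSTRATE_RES_ID, "A", (0.0, 0.0, 0.0), True),
    ("H2'", "H", "NUC", SUBSTRATE_RES_ID, "A", (0.0, 0.0, 0.0), True),
    ("C1'", "C", "NUC", SUBSTRATE_RES_ID, "A", (3.5, 0.0, 5.0), False),
    ("N9", "N", "NUC", SUBSTRATE_RES_ID, "A", (3.0, 0.5, 3.8), False),
]


def build_template_topology() -> Topology:
    """Fixed toy active-site topology (two Arg anchors, Fe-oxo-Cl centre,
    phosphorylated substrate).  The anchor separation (18 Å) guarantees that
    a phosphate H-bonded to one anchor is far outside the cutoff of the
    other, so both-anchor frames have probability ~ 0 under default jitter."""
    atoms = [
        Atom(i, name, element, res_name, res_id, chain)
        for i, (name, element, res_name, res_id, chain, _, _) in enumerate(_TEMPLATE)
    ]
    return Topology(atoms=atoms)


def _template_coords() -> np.ndarray:
    return np.array([xyz for (_, _, _, _, _, xyz, _) in _TEMPLATE], dtype=float)


def _atom_index(name: str, res_id: int) -> int:
    for i, (n, _, _, rid, _, _, _) in enumerate(_TEMPLATE):
        if n == name and rid == res_id:
            return i
    raise KeyError((name, res_id))


_IDX = {
    "O1P": _atom_index("O1P", SUBSTRATE_RES_ID),
    "O2P": _atom_index("O2P", SUBSTRATE_RES_ID),
    "O3P": _atom_index("O3P", SUBSTRATE_RES_ID),
    "P": _atom_index("P", SUBSTRATE_RES_ID),
    "C2'": _atom_index("C2'", SUBSTRATE_RES_ID),
    "H2'": _atom_index("H2'", SUBSTRATE_RES_ID),
    "O1": _atom_index("O1", FEO_RES_ID),
    "CL": _atom_index("CL", FEO_RES_ID),
}

_JITTER_IDX = np.array([i for i, (_, _, _, _, _, _, constrained)
                        in enumerate(_TEMPLATE) if not constrained])


def default_criteria() -> CriteriaConfig:
    """CriteriaConfig wired to the template topology (the stated cutoffs
    3.2 / 3.2 / 4.5 Å are the defaults of :class:`CriteriaConfig`)."""
    arg_names = ("NE", "NH1", "NH2")
    return CriteriaConfig(
        mode1_anchor=SelectionSpec(residues=(ResidueTerm(ANCHOR_A_RES_ID, names=arg_names),)),
        mode2_anchor=SelectionSpec(residues=(ResidueTerm(ANCHOR_B_RES_ID, names=arg_names),)),
        phosphate_acceptors=SelectionSpec(
            residues=(ResidueTerm(SUBSTRATE_RES_ID, names=("O1P", "O2P", "O3P")),)),
        reactive_pair_OH=(
            SelectionSpec(residues=(ResidueTerm(FEO_RES_ID, names=("O1",)),)),
            SelectionSpec(residues=(ResidueTerm(SUBSTRATE_RES_ID, names=("H2'",)),)),
        ),
        reactive_pair_CCl=(
            SelectionSpec(residues=(ResidueTerm(SUBSTRATE_RES_ID, names=("C2'",)),)),
            SelectionSpec(residues=(ResidueTerm(FEO_RES_ID, names=("CL",)),)),
        ),
    )


def substrate_selection() -> SelectionSpec:
    return SelectionSpec(residues=(ResidueTerm(SUBSTRATE_RES_ID),))


def active_site_selection() -> SelectionSpec:
    """Anchors + iron centre + substrate: the 'core active site' used for
    RMSD clustering on the template."""
    return SelectionSpec(residues=(
        ResidueTerm(ANCHOR_A_RES_ID), ResidueTerm(ANCHOR_B_RES_ID),
        ResidueTerm(LYS_RES_ID), ResidueTerm(FEO_RES_ID),
        ResidueTerm(SUBSTRATE_RES_ID),
    ))


# ---------------------------------------------------------------------------
# Sampling


def sample_mode_sequence(spec: SyntheticSpec,
                         rng: np.random.Generator | None = None) -> list[Mode]:
    """Markov mode sequence with stationary distribution = occupancies."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    pi = np.asarray(spec.occupancies, dtype=float)
    rho = spec.persistence
    seq: list[Mode] = []
    current = int(rng.choice(3, p=pi))
    seq.append(_MODES[current])
    for _ in range(spec.n_frames - 1):
        if rho > 0 and rng.random() < rho:
            pass  # stay
        else:
            current = int(rng.choice(3, p=pi))
        seq.append(_MODES[current])
    return seq


def _place_phosphate(coords: np.ndarray, anchor: str | None, dist: float) -> None:
    """Place the phosphate group: the nearest O at the drawn distance from
    the anchor's NH1, the rest of the group strictly farther away."""
    if anchor == "A":
        site, u = _ANCHOR_A_NH1, _APPROACH["A"]
    elif anchor == "B":
        site, u = _ANCHOR_B_NH1, _APPROACH["B"]
    else:
        site, u = _OTHER_SITE, _APPROACH[None]
        dist = 0.0
    perp = np.array([u[1], -u[0], 0.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    o1p = site + dist * u
    p = o1p + 1.5 * u
    coords[_IDX["O1P"]] = o1p
    coords[_IDX["P"]] = p
    coords[_IDX["O2P"]] = p + 1.5 * perp
    coords[_IDX["O3P"]] = p - 1.5 * perp


def sample_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Draw a full synthetic trajectory with its ground-truth labels.

    Deterministic under ``spec.seed``: the same spec yields bit-identical
    coordinates and labels.
    """
    rng = np.random.default_rng(spec.seed)
    modes = sample_mode_sequence(spec, rng)
    template = _template_coords()
    T = spec.n_frames
    coords = np.empty((T, template.shape[0], 3))
    productive: list[bool] = []

    oh_dir = _OH_DIR / np.linalg.norm(_OH_DIR)
    ccl_dir = _CCL_DIR / np.linalg.norm(_CCL_DIR)

    for t, mode in enumerate(modes):
        g = spec.geometry[mode]
        frame = template.copy()

        anchor_d = float(g.anchor_dist.sample(rng)) if g.anchor is not None else 0.0
        _place_phosphate(frame, g.anchor, anchor_d)

        if g.d_OH_marginal is not None or g.d_CCl_marginal is not None:
            if g.d_OH_marginal is None or g.d_CCl_marginal is None:
                raise SpecError("Marginal distance specs must be set for both pairs")
            d_oh = float(g.d_OH_marginal.sample(rng))
            d_ccl = float(g.d_CCl_marginal.sample(rng))
            prod = d_oh <= D_OH_MAX_DEFAULT and d_ccl <= D_CCL_MAX_DEFAULT
        else:
            prod = rng.random() < spec.productive_prob.get(mode, 0.0)
            if prod:
                d_oh = float(g.d_OH_in.sample(rng))
                d_ccl = float(g.d_CCl_in.sample(rng))
            else:
                d_oh = float(g.d_OH_out.sample(rng))
                d_ccl = float(g.d_CCl_out.sample(rng))
        frame[_IDX["H2'"]] = _OXO + d_oh * oh_dir
        frame[_IDX["C2'"]] = _CL + d_ccl * ccl_dir
        productive.append(bool(prod))

        if spec.jitter_sd > 0:
            frame[_JITTER_IDX] += rng.normal(0.0, spec.jitter_sd,
                                             size=(_JITTER_IDX.size, 3))
        coords[t] = frame

    truth = GroundTruth(modes=tuple(modes), productive=tuple(productive))
    return Trajectory(coords=coords), truth


# ---------------------------------------------------------------------------
# Sequence fixtures

_BASE_SEQ = "MKTAYVDLHAGWQERNPFSTCILKDVGHMEWARQSYLNTP"  # triad H9-A10-G11... see below


def make_sequence_fixtures(seed: int = 0) -> list["SeqRecord"]:
    """Deterministic sequence fixtures for the triage layer.

    Returns an HXG-triad reference, HXA and HXD point variants, a variant
    with the triad window deleted, and a pair differing at exactly k of n
    positions so the expected gap-free identity is 100 * (n - k) / n
    (k/n = 10/40 here, i.e. 75%).
    """
    from .seqmotif import SeqRecord  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    base = _BASE_SEQ
    triad_start = base.index("HAG")  # 0-based; triad positions are +1..+3
    p1 = triad_start + 1

    ref = SeqRecord("ref_hxg", base)
    var_hxa = SeqRecord("var_hxa", base[:triad_start + 2] + "A" + base[triad_start + 3:])
    var_hxd = SeqRecord("var_hxd", base[:triad_start + 2] + "D" + base[triad_start + 3:])
    deleted = SeqRecord("var_triad_deleted",
                        base[:triad_start - 1] + base[triad_start + 4:])

    n, k = len(base), 10
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    positions = rng.choice(n, size=k, replace=False)
    mutated = list(base)
    for pos in sorted(positions):
        choices = [c for c in alphabet if c != base[pos]]
        mutated[pos] = choices[int(rng.integers(len(choices)))]
    pair_base = SeqRecord("pair_base", base)
    pair_mut = SeqRecord("pair_mutated", "".join(mutated))
    return [ref, var_hxa, var_hxd, deleted, pair_base, pair_mut]


def triad_positions_of_reference() -> tuple[int, int, int]:
    """1-based positions of the H-X-G triad in the fixture reference."""
    start = _BASE_SEQ.index("HAG")
    return (start + 1, start + 2, start + 3)
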