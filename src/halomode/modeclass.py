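"""Binding-mode classification and productive-conformation statistics.

Each trajectory frame is assigned one substrate binding mode from the
orientation of the nucleotide's 5'-phosphate group:

* ``MODE1`` — the phosphate forms at least one hydrogen bond (heavy-atom
  distance <= cutoff, default 3.2 Å) with the mode-1 arginine anchor
  (Arg178 in CtNTH, Arg177 in AdaV);
* ``MODE2`` — at least one hydrogen bond with the mode-2 anchor
  (Arg238 / Arg237);
* ``OTHER`` — no hydrogen bond with either anchor.

A frame is *productive* (catalytically competent) when the reacting-atom
distances satisfy d_O-H <= 3.2 Å and d_C2'-Cl <= 4.5 Å: the ferryl oxo close
enough to abstract the substrate hydrogen, and the chloride close enough to
the carbon radical for transfer.

P1(m) is the percentage of total frames in mode m; P2(m) is the percentage
of total frames that are in mode m AND productive (so P2 <= P1 and the P1
values partition 100%).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError, SelectionError
from .geometry import HBOND_CUTOFF_DEFAULT, min_pair_distance
from .structio import SelectionSpec, Topology, Trajectory, select_atoms

D_OH_MAX_DEFAULT = 3.2   # Å, oxo O to abstractable substrate H
D_CCL_MAX_DEFAULT = 4.5  # Å, substrate C2' to chloride


class Mode(enum.Enum):
    MODE1 = "mode1"
    MODE2 = "mode2"
    OTHER = "other"


class TieBreak(enum.Enum):
    """Policy for frames hydrogen-bonded to BOTH anchors."""

    SHORTER_DISTANCE = "shorter_distance"  # assign to the closer anchor
    AMBIGUOUS_BUCKET = "ambiguous_bucket"  # assign to OTHER, count separately


@dataclass
class CriteriaConfig:
    """Geometric criteria for mode classification and catalytic competence.

    ``reactive_pair_OH`` selects the ferryl oxo O and the abstractable
    substrate hydrogen; ``reactive_pair_CCl`` the substrate C2' and the
    chloride ligand.  Whether d_O-H points at the C2' hydrogen or the 3'-OH
    hydrogen is a configuration choice — both readings are chemically
    sensible and example configs for each are shipped.
    """

    mode1_anchor: SelectionSpec
    mode2_anchor: SelectionSpec
    phosphate_acceptors: SelectionSpec
    reactive_pair_OH: tuple[SelectionSpec, SelectionSpec]
    reactive_pair_CCl: tuple[SelectionSpec, SelectionSpec]
    hbond_cutoff: float = HBOND_CUTOFF_DEFAULT
    d_OH_max: float = D_OH_MAX_DEFAULT
    d_CCl_max: float = D_CCL_MAX_DEFAULT
    tie_break: TieBreak = TieBreak.SHORTER_DISTANCE

    def __post_init__(self) -> None:
        if isinstance(self.tie_break, str):
            self.tie_break = TieBreak(self.tie_break)
        for name in ("hbond_cutoff", "d_OH_max", "d_CCl_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


@dataclass(frozen=True)
class FrameLabel:
    """Per-frame classification result."""

    frame: int
    mode: Mode
    productive: bool
    d_OH: float
    d_CCl: float
    both_anchors: bool = False


def _resolve_or_raise(top: Topology, spec: SelectionSpec, what: str) -> list[int]:
    try:
        return select_atoms(top, spec)
    except SelectionError as exc:
        raise ConfigError(f"Criteria selection '{what}' did not resolve: {exc}") from exc


def classify_frames(traj: Trajectory, top: Topology, cfg: CriteriaConfig) -> list[FrameLabel]:
    """Assign every frame a binding mode and a productive flag.

    All selections are resolved before any frame is processed so that a bad
    config fails fast.  Anchor contact uses the minimum phosphate-O to
    anchor-atom distance against ``hbond_cutoff`` (inclusive).
    """
    m1 = _resolve_or_raise(top, cfg.mode1_anchor, "mode1_anchor")
    m2 = _resolve_or_raise(top, cfg.mode2_anchor, "mode2_anchor")
    if set(m1) & set(m2):
        raise ConfigError("mode1_anchor and mode2_anchor selections overlap")
    phos = _resolve_or_raise(top, cfg.phosphate_acceptors, "phosphate_acceptors")
    oxo = _resolve_or_raise(top, cfg.reactive_pair_OH[0], "reactive_pair_OH[0]")
    sub_h = _resolve_or_raise(top, cfg.reactive_pair_OH[1], "reactive_pair_OH[1]")
    c2 = _resolve_or_raise(top, cfg.reactive_pair_CCl[0], "reactive_pair_CCl[0]")
    cl = _resolve_or_raise(top, cfg.reactive_pair_CCl[1], "reactive_pair_CCl[1]")

    labels: list[FrameLabel] = []
    for f in range(traj.n_frames):
        d1 = min_pair_distance(traj, f, phos, m1)
        d2 = min_pair_distance(traj, f, phos, m2)
        in1 = d1 <= cfg.hbond_cutoff
        in2 = d2 <= cfg.hbond_cutoff
        both = in1 and in2
        if both:
            if cfg.tie_break is TieBreak.SHORTER_DISTANCE:
                mode = Mode.MODE1 if d1 <= d2 else Mode.MODE2
            else:
                mode = Mode.OTHER
        elif in1:
            mode = Mode.MODE1
        elif in2:
            mode = Mode.MODE2
        else:
            mode = Mode.OTHER
        d_oh = min_pair_distance(traj, f, oxo, sub_h)
        d_ccl = min_pair_distance(traj, f, c2, cl)
        productive = d_oh <= cfg.d_OH_max and d_ccl <= cfg.d_CCl_max
        labels.append(FrameLabel(frame=f, mode=mode, productive=productive,
                                 d_OH=d_oh, d_CCl=d_ccl, both_anchors=both))
    return labels


@dataclass
class ModeStats:
    """Aggregated per-mode statistics over a labelled trajectory.

    ``p1[m]`` and ``p2[m]`` are percentages of TOTAL frames.  The conditional
    productive fraction P2/P1 is exposed separately and never replaces P2.
    Distance means/sds use the sample (n-1) denominator over frames of that
    mode only, and are None where fewer than two frames are available.
    """

    total_frames: int
    counts: dict[Mode, int]
    p1: dict[Mode, float]
    p2: dict[Mode, float]
    mean_d_OH: dict[Mode, float | None]
    sd_d_OH: dict[Mode, float | None]
    mean_d_CCl: dict[Mode, float | None]
    sd_d_CCl: dict[Mode, float | None]
    ambiguous_count: int = 0

    def conditional_productive_fraction(self, mode: Mode) -> float | None:
        if self.p1[mode] == 0:
            return None
        return self.p2[mode] / self.p1[mode]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m in Mode:
            rows.append({
                "mode": m.value, "count": self.counts[m],
                "P1": self.p1[m], "P2": self.p2[m],
                "mean_dOH": self.mean_d_OH[m], "sd_dOH": self.sd_d_OH[m],
                "mean_dCCl": self.mean_d_CCl[m], "sd_dCCl": self.sd_d_CCl[m],
            })
        return pd.DataFrame(rows)


def mode_statistics(labels: list[FrameLabel]) -> ModeStats:
    """P1/P2 percentages and per-mode distance statistics from frame labels."""
    if not labels:
        raise InsufficientDataError("Empty label list")
    total = len(labels)
    counts = {m: 0 for m in Mode}
    prod_counts = {m: 0 for m in Mode}
    ambiguous = 0
    for lab in labels:
        counts[lab.mode] += 1
        if lab.productive:
            prod_counts[lab.mode] += 1
        if lab.both_anchors:
            ambiguous += 1
    p1 = {m: 100.0 * counts[m] / total for m in Mode}
    p2 = {m: 100.0 * prod_counts[m] / total for m in Mode}
    mean_oh: dict[Mode, float | None] = {}
    sd_oh: dict[Mode, float | None] = {}
    mean_ccl: dict[Mode, float | None] = {}
    sd_ccl: dict[Mode, float | None] = {}
    for m in Mode:
        if counts[m] >= 2:
            moh, soh, mccl, sccl = distance_statistics(labels, m)
            mean_oh[m], sd_oh[m], mean_ccl[m], sd_ccl[m] = moh, soh, mccl, sccl
        else:
            mean_oh[m] = sd_oh[m] = mean_ccl[m] = sd_ccl[m] = None
    return ModeStats(total_frames=total, counts=counts, p1=p1, p2=p2,
                     mean_d_OH=mean_oh, sd_d_OH=sd_oh,
                     mean_d_CCl=mean_ccl, sd_d_CCl=sd_ccl,
                     ambiguous_count=ambiguous)


def distance_statistics(labels: list[FrameLabel], mode: Mode
                        ) -> tuple[float, float, float, float]:
    """Sample mean and sd (n-1) of d_O-H and d_C2'-Cl over frames of one mode."""
    d_oh = np.array([lab.d_OH for lab in labels if lab.mode is mode])
    d_ccl = np.array([lab.d_CCl for lab in labels if lab.mode is mode])
    if d_oh.size < 2:
        raise InsufficientDataError(
            f"Need >= 2 frames in {mode.value} for distance statistics, got {d_oh.size}"
        )
    return (float(d_oh.mean()), float(d_oh.std(ddof=1)),
            float(d_ccl.mean()), float(d_ccl.std(ddof=1)))


def frames_in_mode(labels: list[FrameLabel], mode: Mode | None) -> list[int]:
    """Frame indices of a mode, or all frames when mode is None."""
    if mode is None:
        return [lab.frame for lab in labels]
    return [lab.frame for lab in labels if lab.mode is mode]


def hbond_occupancy(traj: Trajectory, top: Topology, cfg: CriteriaConfig,
                    residues: list[SelectionSpec], substrate: SelectionSpec,
                    frames: list[int], subset_name: str = "all") -> pd.DataFrame:
    """Per-residue hydrogen-bond occupancy against the substrate.

    A residue is "occupied" in a frame when at least one donor/acceptor pair
    between its atoms and the substrate's is within ``cfg.hbond_cutoff``;
    multiple simultaneous hydrogen bonds still count that frame once.
    Occupancy is reported as a percentage of the frame subset (by default the
    frames of the mode under study).

    Returns a DataFrame with columns res_id, res_name, occupancy_percent,
    subset.
    """
    if not frames:
        raise InsufficientDataError("Empty frame subset for occupancy")
    sub_idx = _resolve_or_raise(top, substrate, "substrate")
    sub_donors = top.donor_indices(sub_idx)
    sub_acceptors = top.acceptor_indices(sub_idx)
    rows = []
    for spec in residues:
        res_idx = _resolve_or_raise(top, spec, spec.describe())
        res_donors = top.donor_indices(res_idx)
        res_acceptors = top.acceptor_indices(res_idx)
        hit_frames = 0
        for f in frames:
            hit = False
            if res_donors and sub_acceptors:
                hit = min_pair_distance(traj, f, res_donors, sub_acceptors) <= cfg.hbond_cutoff
            if not hit and res_acceptors and sub_donors:
                hit = min_pair_distance(traj, f, res_acceptors, sub_donors) <= cfg.hbond_cutoff
            if hit:
                hit_frames += 1
        first = top.atoms[res_idx[0]]
        rows.append({
            "res_id": first.res_id,
            "res_name": first.res_name,
            "occupancy_percent": 100.0 * hit_frames / len(frames),
            "subset": subset_name,
        })
    return pd.DataFrame(rows)


def labels_to_dataframe(labels: list[FrameLabel]) -> pd.DataFrame:
    return pd.DataFrame({
        "frame": [lab.frame for lab in labels],
        "mode": [lab.mode.value for lab in labels],
        "productive": [lab.productive for lab in labels],
        "d_OH": [lab.d_OH for lab in labels],
        "d_CCl": [lab.d_CCl for lab in labels],
        "both_anchors": [lab.both_anchors for lab in labels],
    })


def binomial_se_percent(p_percent: float, n: int) -> float:
    """Standard error (in percentage points) of a binomial proportion."""
    p = p_percent / 100.0
    return 100.0 * math.sqrt(p * (1.0 - p) / n)
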