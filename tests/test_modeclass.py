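"""Mode classification, P1/P2 statistics, distance statistics, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from halomode.errors import ConfigError, InsufficientDataError
from halomode.modeclass import (CriteriaConfig, FrameLabel, Mode, TieBreak,
                                binomial_se_percent, classify_frames,
                                distance_statistics, hbond_occupancy,
                                mode_statistics)
from halomode.structio import ResidueTerm, SelectionSpec

from conftest import make_trajectory


def _criteria(**overrides):
    base = dict(
        mode1_anchor=SelectionSpec(residues=(ResidueTerm(178),)),
        mode2_anchor=SelectionSpec(residues=(ResidueTerm(238),)),
        phosphate_acceptors=SelectionSpec(
            residues=(ResidueTerm(401, names=("O1P", "O2P")),)),
        reactive_pair_OH=(SelectionSpec(residues=(ResidueTerm(301, names=("O1",)),)),
                          SelectionSpec(residues=(ResidueTerm(401, names=("H2'",)),))),
        reactive_pair_CCl=(SelectionSpec(residues=(ResidueTerm(401, names=("C2'",)),)),
                           SelectionSpec(residues=(ResidueTerm(301, names=("CL",)),))),
    )
    base.update(overrides)
    return CriteriaConfig(**base)


def _frame(phos=(20.0, 0, 0), d_oh=3.0, d_ccl=4.4):
    """One 12-atom frame for arg_pair_topology with controllable geometry.

    Anchor 178 spans x in [0, 1]; anchor 238 sits at x = 40; the oxo O is at
    (0, 20, 0) with the substrate H d_oh away, Cl at (20, 20, 0) with C2'
    d_ccl away.
    """
    return [
        [0, 0, 0], [1, 0, 0], [0.5, 1, 0],          # ARG 178
        [40, 0, 0], [41, 0, 0], [40.5, 1, 0],       # ARG 238
        [phos[0], phos[1], phos[2]],                 # O1P
        [phos[0] + 1.3, phos[1], phos[2]],           # O2P
        [0, 20, 0],                                  # oxo O1
        [d_oh, 20, 0],                               # H2'
        [20 + d_ccl, 20, 0],                         # C2'
        [20, 20, 0],                                 # CL
    ]


class TestClassifyFrames:
    def test_mode_assignment(self, arg_pair_topology):
        traj = make_trajectory([
            _frame(phos=(2.9, 0, 0)),     # 2.9 Å from anchor 178 -> MODE1
            _frame(phos=(37.1, 0, 0)),    # near anchor 238 -> MODE2
            _frame(phos=(20.0, 0, 0)),    # far from both -> OTHER
        ])
        labels = classify_frames(traj, arg_pair_topology, _criteria())
        assert [l.mode for l in labels] == [Mode.MODE1, Mode.MODE2, Mode.OTHER]
        assert not any(l.both_anchors for l in labels)

    @pytest.mark.parametrize("d_oh,d_ccl,expected", [
        (3.0, 4.4, True),
        (3.3, 4.4, False),   # d_O-H above 3.2
        (3.0, 4.6, False),   # d_C2'-Cl above 4.5
        (3.2, 4.5, True),    # both boundaries inclusive
    ])
    def test_productive_flag(self, arg_pair_topology, d_oh, d_ccl, expected):
        traj = make_trajectory([_frame(d_oh=d_oh, d_ccl=d_ccl)])
        (label,) = classify_frames(traj, arg_pair_topology, _criteria())
        assert label.productive is expected
        assert label.d_OH == pytest.approx(d_oh)
        assert label.d_CCl == pytest.approx(d_ccl)

    def test_both_anchor_tie_breaks(self, arg_pair_topology):
        # a phosphate within the cutoff of both anchors (anchors placed at
        # x=1 and x=40... need a closer pair) -> use custom frame where the
        # phosphate O1P is 2.8 Å from 178 and O2P reaches 238
        frame = _frame(phos=(2.8, 0, 0))
        frame[7] = [37.2, 0, 0]  # O2P within 2.8 Å of anchor 238 at x=40
        traj = make_trajectory([frame])
        (shorter,) = classify_frames(traj, arg_pair_topology, _criteria())
        assert shorter.both_anchors
        assert shorter.mode in (Mode.MODE1, Mode.MODE2)

        (bucket,) = classify_frames(
            traj, arg_pair_topology,
            _criteria(tie_break=TieBreak.AMBIGUOUS_BUCKET))
        assert bucket.mode is Mode.OTHER and bucket.both_anchors
        assert mode_statistics([bucket]).ambiguous_count == 1

    def test_unresolvable_selection_fails_before_processing(self, arg_pair_topology):
        cfg = _criteria(mode1_anchor=SelectionSpec(residues=(ResidueTerm(999),)))
        traj = make_trajectory([_frame()])
        with pytest.raises(ConfigError, match="mode1_anchor"):
            classify_frames(traj, arg_pair_topology, cfg)

    def test_overlapping_anchors_rejected(self, arg_pair_topology):
        cfg = _criteria(mode2_anchor=SelectionSpec(residues=(ResidueTerm(178),)))
        with pytest.raises(ConfigError, match="overlap"):
            classify_frames(make_trajectory([_frame()]), arg_pair_topology, cfg)

    def test_raising_cutoffs_is_monotone(self, arg_pair_topology, rng):
        """A larger H-bond cutoff never moves frames into OTHER; larger
        distance cutoffs never unset the productive flag."""
        frames = [_frame(phos=(rng.uniform(2, 8), 0, 0),
                         d_oh=rng.uniform(2.5, 4.0), d_ccl=rng.uniform(4.0, 5.0))
                  for _ in range(40)]
        traj = make_trajectory(frames)
        tight = classify_frames(traj, arg_pair_topology, _criteria())
        loose = classify_frames(
            traj, arg_pair_topology,
            _criteria(hbond_cutoff=4.5, d_OH_max=4.2, d_CCl_max=5.5))
        for a, b in zip(tight, loose):
            if a.mode is not Mode.OTHER:
                assert b.mode is not Mode.OTHER
            if a.productive:
                assert b.productive

    def test_determinism(self, arg_pair_topology, rng):
        frames = [_frame(phos=(rng.uniform(2, 40), 0, 0)) for _ in range(20)]
        traj = make_trajectory(frames)
        assert classify_frames(traj, arg_pair_topology, _criteria()) == \
            classify_frames(traj, arg_pair_topology, _criteria())


def _label(mode, productive=False, d_oh=3.0, d_ccl=4.0, frame=0):
    return FrameLabel(frame=frame, mode=mode, productive=productive,
                      d_OH=d_oh, d_CCl=d_ccl)


class TestModeStatistics:
    def test_p1_example(self):
        labels = [_label(Mode.MODE1), _label(Mode.MODE1),
                  _label(Mode.MODE2), _label(Mode.OTHER)]
        st_ = mode_statistics(labels)
        assert st_.p1[Mode.MODE1] == 50.0
        assert st_.p1[Mode.MODE2] == 25.0
        assert st_.p1[Mode.OTHER] == 25.0

    def test_p2_uses_total_frame_denominator(self):
        labels = [_label(Mode.MODE1, True), _label(Mode.MODE1, False),
                  _label(Mode.MODE2, True), _label(Mode.OTHER, False)]
        st_ = mode_statistics(labels)
        assert st_.p2[Mode.MODE1] == 25.0
        assert st_.p2[Mode.MODE2] == 25.0
        assert st_.conditional_productive_fraction(Mode.MODE1) == pytest.approx(0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(InsufficientDataError):
            mode_statistics([])

    @given(st.lists(st.tuples(st.sampled_from(list(Mode)), st.booleans()),
                    min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_and_bounds(self, drawn):
        """P1 sums to 100 exactly; 0 <= P2(m) <= P1(m) for every mode."""
        labels = [_label(m, p, frame=i) for i, (m, p) in enumerate(drawn)]
        st_ = mode_statistics(labels)
        assert sum(st_.p1.values()) == pytest.approx(100.0, abs=1e-9)
        for m in Mode:
            assert 0.0 <= st_.p2[m] <= st_.p1[m] + 1e-12


class TestDistanceStatistics:
    def test_constant_and_two_point(self):
        labels = [_label(Mode.MODE1, d_oh=2.8, d_ccl=4.0, frame=i) for i in range(3)]
        mean, sd, _, _ = distance_statistics(labels, Mode.MODE1)
        assert mean == pytest.approx(2.8)
        assert sd == pytest.approx(0.0, abs=1e-12)

        labels = [_label(Mode.MODE1, d_oh=2.0, frame=0),
                  _label(Mode.MODE1, d_oh=4.0, frame=1)]
        mean, sd, _, _ = distance_statistics(labels, Mode.MODE1)
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(np.sqrt(2.0))  # n-1 denominator

    def test_insufficient_frames(self):
        with pytest.raises(InsufficientDataError):
            distance_statistics([_label(Mode.MODE1)], Mode.MODE1)

    def test_recovers_normal_parameters(self, rng):
        draws = rng.normal(2.8, 0.4, size=10_000)
        labels = [_label(Mode.MODE1, d_oh=d, frame=i) for i, d in enumerate(draws)]
        mean, sd, _, _ = distance_statistics(labels, Mode.MODE1)
        assert mean == pytest.approx(2.8, abs=0.02)
        assert sd == pytest.approx(0.4, abs=0.02)


class TestOccupancy:
    def test_fraction_of_subset_frames(self, arg_pair_topology):
        # anchor 178 donor NH1 at origin; phosphate alternates near/far
        frames = [_frame(phos=(2.9, 0, 0)), _frame(phos=(2.9, 0, 0)),
                  _frame(phos=(20, 0, 0)), _frame(phos=(20, 0, 0))]
        traj = make_trajectory(frames)
        occ = hbond_occupancy(
            traj, arg_pair_topology, _criteria(),
            residues=[SelectionSpec(residues=(ResidueTerm(178),)),
                      SelectionSpec(residues=(ResidueTerm(238),))],
            substrate=SelectionSpec(residues=(ResidueTerm(401),)),
            frames=[0, 1, 2, 3])
        by_res = dict(zip(occ.res_id, occ.occupancy_percent))
        assert by_res[178] == 50.0
        assert by_res[238] == 0.0

    def test_simultaneous_bonds_count_once(self, arg_pair_topology):
        """Two H-bonds in one frame count one frame; cross-checked against
        an exhaustive per-pair enumeration."""
        frame = _frame(phos=(2.5, 0, 0))  # O1P at 2.5, O2P at 3.8 -> 1 bond
        frame[7] = [0.5, 2.9, 0]          # move O2P within cutoff too
        traj = make_trajectory([frame, _frame(phos=(20, 0, 0))])
        cfg = _criteria()
        res_spec = SelectionSpec(residues=(ResidueTerm(178),))
        sub_spec = SelectionSpec(residues=(ResidueTerm(401),))
        occ = hbond_occupancy(traj, arg_pair_topology, cfg, [res_spec],
                              sub_spec, frames=[0, 1])
        assert occ.occupancy_percent.iloc[0] == 50.0

        # brute force: count pairs within cutoff per frame, collapse to bool
        res_idx = [0, 1, 2]
        sub_acceptors = [6, 7]
        per_frame_pairs = []
        for f in range(2):
            cnt = sum(
                1 for i in res_idx for j in sub_acceptors
                if np.linalg.norm(traj.coords[f, i] - traj.coords[f, j]) <= 3.2)
            per_frame_pairs.append(cnt)
        assert per_frame_pairs[0] >= 2 and per_frame_pairs[1] == 0
        brute_occ = 100.0 * sum(c > 0 for c in per_frame_pairs) / 2
        assert occ.occupancy_percent.iloc[0] == brute_occ

    def test_empty_subset_rejected(self, arg_pair_topology):
        with pytest.raises(InsufficientDataError):
            hbond_occupancy(make_trajectory([_frame()]), arg_pair_topology,
                            _criteria(), [SelectionSpec(residues=(ResidueTerm(178),))],
                            SelectionSpec(residues=(ResidueTerm(401),)), frames=[])


def test_binomial_se_matches_formula():
    assert binomial_se_percent(50.0, 10_000) == pytest.approx(0.5)
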