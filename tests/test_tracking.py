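"""Identity assignment, re-identification and occlusion-gap repair."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movemetrics.core import INFERRED, NOT_TRACKED, TRACKED
from movemetrics.errors import CapacityError
from movemetrics.joints import JOINT_INDEX
from movemetrics.tracking import GapPolicy, assign_identities, interpolate_gaps

from conftest import make_stream, make_track


def continuous_body(slot, center, t0=0.0, duration=5.0, hz=10.0):
    return [(t0 + k / hz, slot, center) for k in range(int(duration * hz))]


class TestAssignIdentities:
    def test_single_continuous_body(self):
        tracks = assign_identities(make_stream(continuous_body(0, (0, 0, 2))))
        assert len(tracks) == 1
        assert tracks[0].persistent_id == 1
        assert len(tracks[0]) == 50
        assert tracks[0].active

    def test_reappearance_near_anchor_keeps_id(self):
        ents = continuous_body(0, (0, 0, 2), 0.0) + continuous_body(3, (0.1, 0, 2), 15.0)
        tracks = assign_identities(make_stream(ents), GapPolicy(reid_radius=0.5))
        assert len(tracks) == 1
        assert len(tracks[0]) == 100

    def test_reappearance_outside_radius_gets_new_id(self):
        ents = continuous_body(0, (0, 0, 2), 0.0) + continuous_body(0, (2.0, 0, 2), 15.0)
        tracks = assign_identities(make_stream(ents), GapPolicy(reid_radius=0.5))
        assert [t.persistent_id for t in tracks] == [1, 2]

    def test_nearest_anchor_wins(self):
        ents = (
            continuous_body(0, (0, 0, 2), 0.0)
            + continuous_body(1, (1, 0, 2), 0.0)
            + continuous_body(2, (0.9, 0, 2), 10.0)
        )
        tracks = assign_identities(make_stream(ents))
        sizes = {t.persistent_id: len(t) for t in tracks}
        assert sizes == {1: 50, 2: 100}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_reid_matches_brute_force_nearest_anchor(self, seed):
        """Randomized anchors; package choice must equal the exhaustive
        nearest-anchor-within-radius oracle."""
        rng = np.random.default_rng(seed)
        anchors = rng.uniform([-2, 0, 2], [2, 0, 4], size=(4, 3))
        ents = []
        for i, a in enumerate(anchors):
            ents += continuous_body(i, tuple(a), 0.0, duration=3.0)
        reapp = anchors[rng.integers(4)] + rng.normal(0, 0.15, 3)
        ents += continuous_body(0, tuple(reapp), 20.0, duration=2.0)
        tracks = assign_identities(make_stream(ents), GapPolicy(reid_radius=0.5))

        track_anchors = {t.persistent_id: anchors[t.persistent_id - 1] for t in tracks if t.persistent_id <= 4}
        dists = {tid: np.linalg.norm(reapp - a) for tid, a in track_anchors.items()}
        expected = min((d, tid) for tid, d in dists.items())
        if expected[0] <= 0.5:
            winner = [t for t in tracks if len(t) == 50][0]
            assert winner.persistent_id == expected[1]
        else:
            assert max(t.persistent_id for t in tracks) == 5

    def test_seventh_identity_raises_capacity_error(self):
        ents = []
        for k in range(7):  # sequential far-apart bodies, never re-identified
            ents += continuous_body(0, (10.0 * k, 0, 2), 20.0 * k, duration=2.0)
        with pytest.raises(CapacityError):
            assign_identities(make_stream(ents), GapPolicy(reid_radius=0.5))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(gaps=st.lists(st.tuples(st.floats(1.0, 5.0), st.floats(1.0, 10.0)), max_size=3))
    def test_identity_stability_single_body(self, gaps):
        """A single subject with any pattern of sub-radius disappearances
        is only ever issued one persistent id."""
        ents = []
        t = 0.0
        rng = np.random.default_rng(42)
        for dur, gap in gaps + [(3.0, 0.0)]:
            jitter = rng.normal(0, 0.05, 3)
            ents += continuous_body(0, tuple(np.array([0, 0, 2.0]) + jitter), t, duration=dur)
            t += dur + gap
        tracks = assign_identities(make_stream(ents), GapPolicy(reid_radius=0.5))
        assert len(tracks) == 1

    def test_slot_permutation_does_not_change_grouping(self):
        """Device slot churn: relabelling the slots of detection runs leaves
        the partition of frames into subjects unchanged."""
        base = (
            continuous_body(0, (0, 0, 2), 0.0)
            + continuous_body(1, (1.5, 0, 2), 0.0)
            + continuous_body(0, (0.05, 0, 2), 10.0)
            + continuous_body(1, (1.55, 0, 2), 10.0)
        )
        churned = (
            continuous_body(0, (0, 0, 2), 0.0)
            + continuous_body(1, (1.5, 0, 2), 0.0)
            + continuous_body(4, (0.05, 0, 2), 10.0)  # same subjects, new slots
            + continuous_body(2, (1.55, 0, 2), 10.0)
        )

        def partition(tracks):
            return sorted(frozenset(zip(t.times, map(tuple, t.positions[:, 0, :]))) for t in tracks)

        assert partition(assign_identities(make_stream(base))) == partition(
            assign_identities(make_stream(churned))
        )


class TestInterpolateGaps:
    def test_midpoint_fill(self):
        track = make_track(
            [0.0, 0.5, 1.0],
            joint="head",
            positions=[(0, 0, 0), (0, 0, 0), (1, 0, 0)],
            states=[TRACKED, NOT_TRACKED, TRACKED],
        )
        out = interpolate_gaps(track, GapPolicy(max_interp_gap=1.5))
        j = JOINT_INDEX["head"]
        np.testing.assert_allclose(out.positions[1, j], (0.5, 0, 0))
        assert out.states[1, j] == INFERRED

    def test_long_gap_left_missing(self):
        times = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        states = [TRACKED] + [NOT_TRACKED] * 5 + [TRACKED]
        track = make_track(times, joint="head", positions=[(k, 0, 0) for k in range(7)], states=states)
        out = interpolate_gaps(track, GapPolicy(max_interp_gap=0.5))
        j = JOINT_INDEX["head"]
        assert np.all(out.states[1:6, j] == NOT_TRACKED)
        assert np.all(np.isnan(out.positions[1:6, j]))

    def test_edge_gaps_never_filled(self):
        track = make_track(
            [0.0, 0.1, 0.2],
            joint="head",
            positions=[(0, 0, 0)] * 3,
            states=[NOT_TRACKED, TRACKED, NOT_TRACKED],
        )
        out = interpolate_gaps(track, GapPolicy())
        j = JOINT_INDEX["head"]
        assert out.states[0, j] == NOT_TRACKED and out.states[2, j] == NOT_TRACKED

    def test_multi_point_gap_equals_per_axis_interp_oracle(self, rng):
        times = np.arange(0, 2.0, 0.1)
        pos = rng.normal(0, 1, (len(times), 3)).cumsum(axis=0)
        states = np.full(len(times), TRACKED)
        states[5:9] = NOT_TRACKED
        track = make_track(times, joint="neck", positions=pos, states=states)
        out = interpolate_gaps(track, GapPolicy(max_interp_gap=1.0))
        j = JOINT_INDEX["neck"]
        for axis in range(3):
            expected = np.interp(times[5:9], [times[4], times[9]], [pos[4, axis], pos[9, axis]])
            np.testing.assert_allclose(out.positions[5:9, j, axis], expected, atol=1e-12)

    def test_exact_for_linear_motion(self):
        """Linear true trajectory: filled positions equal truth to 1e-9."""
        times = np.arange(0, 3.0, 0.05)
        velocity = np.array([0.2, -0.1, 0.05])
        pos = times[:, None] * velocity[None, :]
        states = np.full(len(times), TRACKED)
        states[10:18] = NOT_TRACKED
        track = make_track(times, joint="head", positions=pos, states=states)
        out = interpolate_gaps(track, GapPolicy(max_interp_gap=1.0))
        j = JOINT_INDEX["head"]
        np.testing.assert_allclose(out.positions[:, j, :], pos, atol=1e-9)

    def test_input_track_unmodified(self):
        track = make_track(
            [0.0, 0.5, 1.0],
            joint="head",
            positions=[(0, 0, 0), (0, 0, 0), (1, 0, 0)],
            states=[TRACKED, NOT_TRACKED, TRACKED],
        )
        before = track.states.copy()
        interpolate_gaps(track, GapPolicy(max_interp_gap=2.0))
        np.testing.assert_array_equal(track.states, before)
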