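"""Shared fixtures and independent oracles used across the test suite."""

import numpy as np
import pytest

from movemetrics.core import N_JOINTS, NOT_TRACKED, TRACKED, SkeletonStream
from movemetrics.joints import CANONICAL_JOINTS, JOINT_INDEX
from movemetrics.tracking import BodyTrack


def make_track(times, joint=None, positions=None, states=None, default_pos=(0.0, 0.0, 2.0), persistent_id=1):
    """Build a BodyTrack with every joint parked at ``default_pos`` and one
    joint optionally overridden with explicit positions/states."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    pos = np.tile(np.asarray(default_pos, dtype=float), (n, N_JOINTS, 1))
    st = np.full((n, N_JOINTS), TRACKED, dtype=np.int8)
    if joint is not None:
        j = JOINT_INDEX[joint]
        pos[:, j, :] = np.asarray(positions, dtype=float)
        if states is not None:
            st[:, j] = np.asarray(states, dtype=np.int8)
            pos[st[:, j] == NOT_TRACKED, j, :] = np.nan
    return BodyTrack(
        persistent_id=persistent_id,
        times=times,
        positions=pos,
        states=st,
        body_index=np.zeros(n, dtype=np.int64),
    )


def make_stream(entries):
    """Stream from (time, slot, centre_xyz) tuples; all 25 joints at the
    centre, all tracked."""
    n = len(entries)
    times = np.array([e[0] for e in entries], dtype=float)
    body = np.array([e[1] for e in entries], dtype=np.int64)
    pos = np.zeros((n, N_JOINTS, 3))
    for i, e in enumerate(entries):
        pos[i, :, :] = np.asarray(e[2], dtype=float)[None, :]
    states = np.full((n, N_JOINTS), TRACKED, dtype=np.int8)
    order = np.lexsort((body, times))
    return SkeletonStream(times[order], body[order], pos[order], states[order])


def brute_force_minute_paths(times, positions, states, session_length, max_gap, include_inferred=True):
    """Independent per-pair summation oracle for the minute-binned path
    length: explicit Python loop over consecutive valid samples, distance
    added to the minute containing the later endpoint."""
    sums = [0.0] * session_length
    counts = [0] * session_length
    last = None  # (t, p)
    for t, p, s in zip(times, positions, states):
        ok = s == TRACKED or (include_inferred and s == 1)
        ok = ok and np.all(np.isfinite(p))
        if not ok:
            continue
        if last is not None:
            t0, p0 = last
            if 0 < t - t0 <= max_gap:
                b = int(t // 60)
                if b < session_length:
                    sums[b] += float(np.linalg.norm(np.asarray(p) - p0))
                    counts[b] += 1
        last = (t, np.asarray(p, dtype=float))
    return np.array([s if c > 0 else np.nan for s, c in zip(sums, counts)])


def brute_force_auc(pos, neg):
    """Exhaustive pair-count AUC oracle with half-credit ties."""
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
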