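"""Per-joint, per-minute 3-D path length — the core movement quantity.

For each joint, movement during a minute is the sum of Euclidean distances
between consecutive valid sampled positions whose segment ends in that
minute.  A segment is valid when both endpoints are tracked or inferred and
the segment does not span more than the interpolation gap bound (so an
unrepaired occlusion never contributes a long straight "jump").  A minute
with no valid segment is missing (NaN), never zero: zero would fabricate
stillness during occlusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .core import INFERRED, TRACKED, MovementMatrix, SessionMeta
from .errors import ValidationError
from .joints import ANALYSIS_JOINTS, JOINT_INDEX, REJECTED_JOINTS, normalize_joint
from .tracking import BodyTrack, GapPolicy

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class TrajectorySegment:
    """A straight-line trajectory piece between two consecutive samples."""

    joint: str
    t0: float
    t1: float
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    valid: bool

    def __post_init__(self):
        if self.t1 <= self.t0:
            raise ValidationError("segment must have t1 > t0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))


def select_analysis_joints(joints: Iterable[str]) -> set[str]:
    """Drop the seated-recording rejects (hand, hand tip, thumb, foot on
    both sides) from a set of canonical joints; 25 in -> 17 out."""
    out = set()
    for j in joints:
        name = normalize_joint(j)
        if name not in REJECTED_JOINTS:
            out.add(name)
    return out


def _segment_arrays(track: BodyTrack, joint: str, max_segment_gap: float, include_inferred: bool, smooth_window: int | None):
    """Valid-segment endpoint arrays (t0, t1, lengths) for one joint."""
    j = JOINT_INDEX[normalize_joint(joint)]
    t = track.times
    pos = track.positions[:, j, :]
    st = track.states[:, j]
    ok = (st == TRACKED) | ((st == INFERRED) & include_inferred)
    ok &= np.all(np.isfinite(pos), axis=1)
    v = np.flatnonzero(ok)
    if len(v) < 2:
        return np.empty(0), np.empty(0), np.empty(0)
    pv = pos[v]
    if smooth_window and smooth_window > 1:
        pv = _smooth_runs(t[v], pv, v, smooth_window)
    t0, t1 = t[v[:-1]], t[v[1:]]
    d = np.linalg.norm(np.diff(pv, axis=0), axis=1)
    keep = (t1 - t0) <= max_segment_gap
    keep &= (t1 - t0) > 0
    return t0[keep], t1[keep], d[keep]


def _smooth_runs(tv: np.ndarray, pv: np.ndarray, v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average applied within contiguous valid runs only."""
    out = pv.copy()
    run_breaks = np.flatnonzero(np.diff(v) > 1)
    starts = np.concatenate([[0], run_breaks + 1])
    ends = np.concatenate([run_breaks + 1, [len(v)]])
    kernel = np.ones(window) / window
    half = window // 2
    for s, e in zip(starts, ends):
        if e - s < window:
            continue
        for axis in range(3):
            seg = pv[s:e, axis]
            sm = np.convolve(seg, kernel, mode="same")
            # keep run edges unsmoothed (incomplete kernel support)
            out[s + half : e - half, axis] = sm[half : len(seg) - half]
    return out


def path_length_per_minute(
    track: BodyTrack,
    joint: str,
    session_length: int,
    *,
    max_segment_gap: float | None = None,
    policy: GapPolicy | None = None,
    include_inferred: bool = True,
    smooth_window: int | None = None,
) -> np.ndarray:
    """Distance (m) covered by ``joint`` in each minute bin of the session.

    Segments are assigned to the minute containing their *later* endpoint,
    so every segment is counted exactly once and minute sums conserve the
    total path length.  Returns a ``(session_length,)`` vector with NaN for
    minutes with no valid segment.  Data beyond the session length is
    ignored with a warning.
    """
    if session_length <= 0:
        raise ValidationError("session_length must be positive")
    if max_segment_gap is None:
        max_segment_gap = (policy or GapPolicy()).max_interp_gap
    _, t1, d = _segment_arrays(track, joint, max_segment_gap, include_inferred, smooth_window)
    out = np.full(session_length, np.nan)
    if len(d) == 0:
        return out
    bins = np.floor(t1 / SECONDS_PER_MINUTE).astype(int)
    inside = bins < session_length
    if not np.all(inside):
        warnings.warn(
            f"track extends past the declared session length ({session_length} min); trailing data ignored",
            stacklevel=2,
        )
        bins, d = bins[inside], d[inside]
    acc = np.zeros(session_length)
    cnt = np.zeros(session_length, dtype=int)
    np.add.at(acc, bins, d)
    np.add.at(cnt, bins, 1)
    out[cnt > 0] = acc[cnt > 0]
    return out


def total_path_length(track: BodyTrack, joint: str, *, max_segment_gap: float = 0.5, include_inferred: bool = True) -> float:
    """Unbinned total path length over all valid segments (conservation
    oracle for the minute binning)."""
    _, _, d = _segment_arrays(track, joint, max_segment_gap, include_inferred, None)
    return float(d.sum())


def build_movement_matrix(
    track: BodyTrack,
    meta: SessionMeta,
    *,
    joints: tuple[str, ...] = ANALYSIS_JOINTS,
    max_segment_gap: float | None = None,
    policy: GapPolicy | None = None,
    include_inferred: bool = True,
    smooth_window: int | None = None,
) -> MovementMatrix:
    """Movement matrix (17 analysis joints x session minutes) for one track."""
    rows = [
        path_length_per_minute(
            track,
            j,
            meta.session_length,
            max_segment_gap=max_segment_gap,
            policy=policy,
            include_inferred=include_inferred,
            smooth_window=smooth_window,
        )
        for j in joints
    ]
    return MovementMatrix(meta.subject_id, tuple(joints), np.vstack(rows))
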