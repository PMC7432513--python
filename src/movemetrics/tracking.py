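"""Persistent multi-body identity assignment and occlusion-gap repair.

A consumer-grade body tracker reports up to six concurrent skeletons in
device "slots" that are not stable: when a subject is momentarily lost
(walks out of view, full occlusion) and re-detected, the detection may come
back in a different slot.  This module reconstructs persistent subject
identities the way the original classroom application did: each newly
detected body receives the next number (1-6) in order of first detection and
its seat location is remembered; a detection that appears after a body went
missing is re-attached to the nearest remembered location, provided it lies
within a re-identification radius.

Short per-joint dropouts (``not_tracked`` runs) are repaired by linear
interpolation; long gaps are left missing so that a subject leaving the
field of view cannot inject a spurious "teleport" distance downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import INFERRED, N_JOINTS, NOT_TRACKED, SkeletonStream, as_stream
from .errors import CapacityError, ValidationError
from .joints import JOINT_INDEX

MAX_BODIES = 6
_SPINE_BASE = JOINT_INDEX["spine_base"]


@dataclass
class GapPolicy:
    """Tracking/repair policy.

    Parameters
    ----------
    max_interp_gap : float
        Longest occlusion (seconds) bridged by interpolation; also the
        longest time span a single trajectory segment may cover.
    reid_radius : float
        Maximum distance (metres) between a new detection and a lost
        track's anchor for the track to be re-used.
    presence_timeout : float
        A body slot silent for longer than this (seconds) is considered
        lost (ends its detection run).
    anchor_half_life : float
        Half-life (seconds) of the exponential moving average of the
        spine-base position that serves as a track's anchor location.
    """

    max_interp_gap: float = 0.5
    reid_radius: float = 0.5
    presence_timeout: float = 0.5
    anchor_half_life: float = 2.0

    def __post_init__(self):
        if self.max_interp_gap <= 0 or self.reid_radius <= 0:
            raise ValidationError("GapPolicy parameters must be positive")


@dataclass
class BodyTrack:
    """One persistent subject identity with its time-ordered observations."""

    persistent_id: int
    times: np.ndarray  # (n,)
    positions: np.ndarray  # (n, 25, 3)
    states: np.ndarray  # (n, 25) int8
    body_index: np.ndarray  # (n,) raw slot provenance
    anchor: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    active: bool = True

    def __len__(self) -> int:
        return len(self.times)

    @property
    def frames(self):
        """Frame-object view (materialised on demand)."""
        return SkeletonStream(self.times, self.body_index, self.positions, self.states)

    def joint_position(self, joint: str) -> np.ndarray:
        return self.positions[:, JOINT_INDEX[joint], :]

    def joint_states(self, joint: str) -> np.ndarray:
        return self.states[:, JOINT_INDEX[joint]]


def _ema_final(times: np.ndarray, points: np.ndarray, half_life: float, init: np.ndarray | None) -> np.ndarray:
    """Final value of an exponential moving average of ``points`` over time.

    NaN points (spine base not tracked) are skipped.  Uses a constant
    smoothing factor from the median sampling interval; an irregular stream
    only changes the effective averaging window, not correctness, since the
    anchor is a smoothed location, not an estimator with a contract.
    """
    ok = np.all(np.isfinite(points), axis=1)
    times, points = times[ok], points[ok]
    if len(points) == 0:
        return init if init is not None else np.full(3, np.nan)
    if len(points) == 1:
        start = init if init is not None and np.all(np.isfinite(init)) else points[0]
        dt = half_life  # single sample: blend halfway toward it
        a = 1.0 - 0.5 ** (dt / half_life)
        return start + a * (points[0] - start)
    dt = float(np.median(np.diff(times)))
    if dt <= 0:
        return points[-1]
    a = 1.0 - 0.5 ** (dt / half_life)
    start = init if init is not None and np.all(np.isfinite(init)) else points[0]
    out = np.empty_like(points)
    for axis in range(3):
        zi = np.array([(1.0 - a) * start[axis]])
        out[:, axis], _ = lfilter([a], [1.0, a - 1.0], points[:, axis], zi=zi)
    return out[-1]


def _detection_runs(stream: SkeletonStream, timeout: float):
    """Split the stream into per-slot contiguous detection runs.

    Returns a list of (start_time, slot, frame_indices) sorted by start time
    (ties: lower slot first).
    """
    runs = []
    for b in np.unique(stream.body_index):
        idx = np.flatnonzero(stream.body_index == b)
        tb = stream.times[idx]
        breaks = np.flatnonzero(np.diff(tb) > timeout)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(idx)]])
        for s, e in zip(starts, ends):
            runs.append((float(tb[s]), int(b), idx[s:e]))
    runs.sort(key=lambda r: (r[0], r[1]))
    return runs


def _entry_point(stream: SkeletonStream, frame_indices: np.ndarray) -> np.ndarray:
    """Representative location of a run's first detection: first finite
    spine-base position, else the centroid of the first frame's valid
    joints."""
    sb = stream.positions[frame_indices, _SPINE_BASE, :]
    finite = np.all(np.isfinite(sb), axis=1)
    if np.any(finite):
        return sb[np.argmax(finite)]
    first = stream.positions[frame_indices[0]]
    ok = np.all(np.isfinite(first), axis=1)
    if np.any(ok):
        return first[ok].mean(axis=0)
    return np.full(3, np.nan)


def assign_identities(frames, policy: GapPolicy | None = None) -> list[BodyTrack]:
    """Group raw detections into persistent subject tracks.

    A detection run starting while a previously seen track is inactive is
    attached to the inactive track with the nearest anchor, if that anchor
    lies within ``policy.reid_radius``; equidistant anchors break toward the
    lower persistent id.  Otherwise the run founds a new track with the next
    unused id; a seventh identity raises :class:`CapacityError`.

    Returns tracks sorted by persistent id (1-based, order of first
    detection).
    """
    policy = policy or GapPolicy()
    stream = as_stream(frames)
    if len(stream) == 0:
        return []
    runs = _detection_runs(stream, policy.presence_timeout)

    # per-track bookkeeping
    segments: list[list[np.ndarray]] = []  # frame-index blocks per track
    anchors: list[np.ndarray] = []
    end_times: list[float] = []

    for start_t, slot, idx in runs:
        entry = _entry_point(stream, idx)
        # candidate tracks: inactive at start_t (their last frame is older)
        best, best_d = None, np.inf
        for tid in range(len(segments)):
            if end_times[tid] + policy.presence_timeout >= start_t:
                continue  # still active (or concurrently detected)
            d = float(np.linalg.norm(entry - anchors[tid]))
            if np.isfinite(d) and d < best_d - 1e-12 and d <= policy.reid_radius:
                best, best_d = tid, d
        if best is None:
            if len(segments) >= MAX_BODIES:
                raise CapacityError(
                    f"more than {MAX_BODIES} bodies required; the tracker "
                    f"can only detect and track {MAX_BODIES}"
                )
            segments.append([])
            anchors.append(entry.copy())
            end_times.append(-np.inf)
            best = len(segments) - 1
        segments[best].append(idx)
        anchors[best] = _ema_final(
            stream.times[idx],
            stream.positions[idx, _SPINE_BASE, :],
            policy.anchor_half_life,
            anchors[best],
        )
        end_times[best] = float(stream.times[idx[-1]])

    t_end = float(stream.times.max())
    tracks = []
    for tid, blocks in enumerate(segments):
        idx = np.concatenate(blocks)
        order = np.argsort(stream.times[idx], kind="stable")
        idx = idx[order]
        tracks.append(
            BodyTrack(
                persistent_id=tid + 1,
                times=stream.times[idx].copy(),
                positions=stream.positions[idx].copy(),
                states=stream.states[idx].copy(),
                body_index=stream.body_index[idx].copy(),
                anchor=np.asarray(anchors[tid], dtype=float),
                active=end_times[tid] + policy.presence_timeout >= t_end,
            )
        )
    return tracks


def interpolate_gaps(track: BodyTrack, policy: GapPolicy | None = None) -> BodyTrack:
    """Fill short per-joint occlusions by linear interpolation.

    For each joint, a run of ``not_tracked`` samples bounded on both sides
    by tracked/inferred samples whose time span does not exceed
    ``policy.max_interp_gap`` is filled per coordinate by linear
    interpolation in time and marked ``inferred``.  Longer gaps and gaps at
    the track ends stay missing.  Returns a new track; the input is not
    modified.
    """
    policy = policy or GapPolicy()
    pos = track.positions.copy()
    states = track.states.copy()
    t = track.times
    for j in range(N_JOINTS):
        valid = states[:, j] != NOT_TRACKED
        v = np.flatnonzero(valid)
        if len(v) < 2:
            continue
        gap_at = np.flatnonzero(np.diff(v) > 1)
        for g in gap_at:
            i0, i1 = v[g], v[g + 1]
            if t[i1] - t[i0] > policy.max_interp_gap:
                continue
            inner = np.arange(i0 + 1, i1)
            for axis in range(3):
                pos[inner, j, axis] = np.interp(t[inner], [t[i0], t[i1]], [pos[i0, j, axis], pos[i1, j, axis]])
            states[inner, j] = INFERRED
    return BodyTrack(
        persistent_id=track.persistent_id,
        times=t.copy(),
        positions=pos,
        states=states,
        body_index=track.body_index.copy(),
        anchor=track.anchor.copy(),
        active=track.active,
    )
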