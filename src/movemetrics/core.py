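"""Core in-memory containers: joint samples, skeleton frames and streams,
session metadata, and the per-joint / per-minute movement matrix.

A *skeleton frame* is one timestamped observation of one body: 25 joint
positions in camera space (x, y lateral/vertical, z distance to the sensor,
metres) each with a tracking state.  A :class:`SkeletonStream` stores many
frames column-wise in NumPy arrays; indexing materialises
:class:`SkeletonFrame` objects on demand, so large sessions stay cheap while
the frame-level API remains available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ValidationError
from .joints import ANALYSIS_JOINTS, CANONICAL_JOINTS, JOINT_INDEX, normalize_joint

N_JOINTS = len(CANONICAL_JOINTS)

# Tracking states, encoded as small ints in array storage.
NOT_TRACKED, INFERRED, TRACKED = 0, 1, 2
STATE_NAMES = {NOT_TRACKED: "not_tracked", INFERRED: "inferred", TRACKED: "tracked"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}


@dataclass(frozen=True)
class JointSample:
    """One joint observation: canonical name, 3-vector position (m), state."""

    joint: str
    position: tuple[float, float, float]
    tracking_state: str = "tracked"

    def __post_init__(self):
        object.__setattr__(self, "joint", normalize_joint(self.joint))
        if self.tracking_state not in STATE_CODES:
            raise ValidationError(f"unknown tracking state: {self.tracking_state!r}")
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,):
            raise ValidationError("position must be a 3-vector")
        if self.tracking_state != "not_tracked" and not np.all(np.isfinite(p)):
            raise ValidationError(
                f"non-finite position for {self.joint} with state {self.tracking_state}"
            )
        object.__setattr__(self, "position", (float(p[0]), float(p[1]), float(p[2])))


@dataclass(frozen=True)
class SkeletonFrame:
    """One body at one instant: timestamp (s from session start), the raw
    device body slot (0-5), and exactly one sample per canonical joint."""

    timestamp: float
    raw_body_index: int
    samples: tuple[JointSample, ...]

    def __post_init__(self):
        if self.timestamp < 0:
            raise ValidationError("timestamp must be non-negative")
        if not 0 <= self.raw_body_index <= 5:
            raise ValidationError("raw_body_index must be in 0..5")
        names = [s.joint for s in self.samples]
        if len(names) != N_JOINTS or len(set(names)) != N_JOINTS:
            raise ValidationError(
                f"a frame needs exactly {N_JOINTS} distinct joints, got {len(names)}"
            )
        ordered = tuple(sorted(self.samples, key=lambda s: JOINT_INDEX[s.joint]))
        object.__setattr__(self, "samples", ordered)

    def sample(self, joint: str) -> JointSample:
        return self.samples[JOINT_INDEX[normalize_joint(joint)]]


class SkeletonStream(Sequence[SkeletonFrame]):
    """Column-wise storage for a sequence of skeleton frames.

    Attributes
    ----------
    times : (n,) float64 — seconds from session start, non-decreasing.
    body_index : (n,) int — raw device slot per frame.
    positions : (n, 25, 3) float64 — NaN where not tracked.
    states : (n, 25) int8 — tracking-state codes.
    """

    def __init__(self, times, body_index, positions, states):
        self.times = np.asarray(times, dtype=float)
        self.body_index = np.asarray(body_index, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=float)
        self.states = np.asarray(states, dtype=np.int8)
        n = len(self.times)
        if not (
            self.body_index.shape == (n,)
            and self.positions.shape == (n, N_JOINTS, 3)
            and self.states.shape == (n, N_JOINTS)
        ):
            raise ValidationError("inconsistent stream array shapes")
        self._validate()

    def _validate(self):
        if len(self.times) == 0:
            return
        if np.any(self.times < 0):
            raise ValidationError("timestamps must be non-negative")
        for b in np.unique(self.body_index):
            tb = self.times[self.body_index == b]
            if np.any(np.diff(tb) < 0):
                raise ValidationError(
                    f"timestamps not non-decreasing for body {b}"
                )
        tracked_pos = self.positions[self.states > NOT_TRACKED]
        if tracked_pos.size and not np.all(np.isfinite(tracked_pos)):
            raise ValidationError("non-finite position on a tracked/inferred joint")

    @classmethod
    def from_frames(cls, frames: Iterable[SkeletonFrame]) -> "SkeletonStream":
        frames = list(frames)
        n = len(frames)
        times = np.empty(n)
        body = np.empty(n, dtype=np.int64)
        pos = np.full((n, N_JOINTS, 3), np.nan)
        states = np.zeros((n, N_JOINTS), dtype=np.int8)
        for i, fr in enumerate(frames):
            times[i] = fr.timestamp
            body[i] = fr.raw_body_index
            for j, s in enumerate(fr.samples):
                states[i, j] = STATE_CODES[s.tracking_state]
                if s.tracking_state != "not_tracked":
                    pos[i, j] = s.position
        return cls(times, body, pos, states)

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i) -> SkeletonFrame:
        if isinstance(i, slice):
            return [self[k] for k in range(*i.indices(len(self)))]
        samples = []
        for j, name in enumerate(CANONICAL_JOINTS):
            st = STATE_NAMES[int(self.states[i, j])]
            p = self.positions[i, j]
            if st == "not_tracked":
                p = (np.nan, np.nan, np.nan)
            samples.append(JointSample(name, tuple(p), st))
        return SkeletonFrame(float(self.times[i]), int(self.body_index[i]), tuple(samples))

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return (self[i] for i in range(len(self)))


def as_stream(frames) -> SkeletonStream:
    """Coerce a SkeletonStream or an iterable of SkeletonFrame to a stream."""
    if isinstance(frames, SkeletonStream):
        return frames
    return SkeletonStream.from_frames(frames)


@dataclass
class SessionMeta:
    """Descriptive metadata for one recorded subject-session."""

    subject_id: str
    group: str = "experimental"  # experimental | control
    medication: str = "n/a"  # with | without | n/a
    sex: str = "boy"  # boy | girl
    age: float | None = None
    session_length: int = 30  # minutes

    def __post_init__(self):
        if self.group not in ("experimental", "control"):
            raise ValidationError(f"unknown group: {self.group!r}")
        if self.medication not in ("with", "without", "n/a"):
            raise ValidationError(f"unknown medication status: {self.medication!r}")
        if self.sex not in ("boy", "girl"):
            raise ValidationError(f"unknown sex label: {self.sex!r}")
        if self.session_length <= 0:
            raise ValidationError("session_length must be positive")


@dataclass
class MovementMatrix:
    """Per-subject table of path length (metres) per joint per minute.

    ``values[j, m]`` is the 3-D distance covered by joint ``joint_names[j]``
    during minute ``m+1``; NaN marks a minute with no valid trajectory
    segment (fully occluded), which is *missing*, never zero.
    """

    subject_id: str
    joint_names: tuple[str, ...]
    values: np.ndarray  # (n_joints, n_minutes), NaN = missing

    def __post_init__(self):
        self.joint_names = tuple(normalize_joint(j) for j in self.joint_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.joint_names):
            raise ValidationError("values must be (n_joints, n_minutes)")
        if len(set(self.joint_names)) != len(self.joint_names):
            raise ValidationError("duplicate joint rows")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite < 0):
            raise ValidationError("path lengths must be non-negative")

    @property
    def minutes(self) -> int:
        return self.values.shape[1]

    def row(self, joint: str) -> np.ndarray:
        joint = normalize_joint(joint)
        try:
            return self.values[self.joint_names.index(joint)]
        except ValueError:
            raise KeyError(f"joint {joint!r} not in matrix") from None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            index=list(self.joint_names),
            columns=[f"minute_{m + 1}" for m in range(self.minutes)],
        )


DEFAULT_ANALYSIS_ORDER = ANALYSIS_JOINTS
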