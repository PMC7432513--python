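"""Plain-text readers/writers for skeleton streams and movement matrices.

Skeleton streams come in two equivalent formats:

* **CSV** (long format, one row per joint sample)::

      # movemetrics skeleton stream; units: metres; timestamps: seconds from session start
      timestamp_s,body_index,joint,x_m,y_m,z_m,tracking_state
      0.000000,0,spine_base,0.012000,0.850000,2.410000,tracked
      ...

  ``#``-prefixed comment/metadata lines may precede the header.  Position
  cells are empty for ``not_tracked`` samples.

* **JSON lines**, one frame object per line::

      {"timestamp_s": 0.0, "body_index": 0,
       "joints": {"spine_base": {"pos": [0.012, 0.85, 2.41], "state": "tracked"}, ...}}

Movement matrices are TSV: first column the joint name, then
``minute_1..minute_N``; an empty cell is a missing minute (not zero).
Joint names are validated against the canonical 25-name vocabulary in every
format; an unknown name is an error, never silently dropped.
"""

from __future__ import annotations

import json
import os
import numpy as np

from .core import (
    N_JOINTS,
    NOT_TRACKED,
    STATE_CODES,
    STATE_NAMES,
    MovementMatrix,
    SkeletonStream,
    as_stream,
)
from .errors import FormatError, ValidationError
from .joints import CANONICAL_JOINTS, JOINT_INDEX, normalize_joint

CSV_HEADER = "timestamp_s,body_index,joint,x_m,y_m,z_m,tracking_state"
_CSV_COLUMNS = CSV_HEADER.split(",")


def _open_maybe(source, mode: str):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode, newline=""), True
    return source, False


# ---------------------------------------------------------------------------
# skeleton streams


def read_skeleton_stream(source, format: str = "csv") -> SkeletonStream:
    """Read a skeleton-frame stream from a path or text stream.

    Frames are returned time-sorted (stable across bodies); timestamps must
    be non-decreasing within each raw body slot.

    Raises
    ------
    FormatError
        Malformed row or unknown joint name, with the 1-based line number.
    ValidationError
        Duplicate (timestamp, body, joint) sample or a frame without
        exactly 25 distinct joints.
    """
    f, should_close = _open_maybe(source, "r")
    try:
        if format == "csv":
            return _read_csv(f)
        if format == "jsonl":
            return _read_jsonl(f)
        raise ValueError(f"unknown format: {format!r}")
    finally:
        if should_close:
            f.close()


def _read_csv(f) -> SkeletonStream:
    lines = f.read().splitlines()
    # skip leading comment/blank lines, remember the offset for line numbers
    k = 0
    while k < len(lines) and (not lines[k].strip() or lines[k].lstrip().startswith("#")):
        k += 1
    if k >= len(lines):
        return SkeletonStream(
            np.empty(0), np.empty(0, dtype=int), np.empty((0, N_JOINTS, 3)), np.empty((0, N_JOINTS), dtype=np.int8)
        )
    header = [c.strip() for c in lines[k].split(",")]
    if header != _CSV_COLUMNS:
        raise FormatError(f"expected header {CSV_HEADER!r}, got {lines[k]!r}", line=k + 1)

    rows = []  # (t, body, joint_idx, x, y, z, state_code, lineno)
    for i, raw in enumerate(lines[k + 1 :], start=k + 2):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split(",")
        if len(parts) != 7:
            raise FormatError(f"expected 7 fields, got {len(parts)}", line=i)
        t_s, b_s, joint_s, x_s, y_s, z_s, state_s = (p.strip() for p in parts)
        try:
            joint = normalize_joint(joint_s)
        except KeyError:
            raise FormatError(f"unknown joint name: {joint_s!r}", line=i) from None
        state_s = state_s or "tracked"
        if state_s not in STATE_CODES:
            raise FormatError(f"unknown tracking state: {state_s!r}", line=i)
        try:
            t = float(t_s)
            b = int(b_s)
            if state_s == "not_tracked" and not (x_s or y_s or z_s):
                x = y = z = np.nan
            else:
                x, y, z = float(x_s), float(y_s), float(z_s)
        except ValueError as exc:
            raise FormatError(f"malformed numeric field ({exc})", line=i) from None
        rows.append((t, b, JOINT_INDEX[joint], x, y, z, STATE_CODES[state_s], i))
    return _assemble(rows)


def _read_jsonl(f) -> SkeletonStream:
    rows = []
    for i, raw in enumerate(f.read().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        try:
            obj = json.loads(raw)
            t = float(obj["timestamp_s"])
            b = int(obj["body_index"])
            joints = obj["joints"]
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"malformed frame object ({exc})", line=i) from None
        for joint_s, rec in joints.items():
            try:
                joint = normalize_joint(joint_s)
            except KeyError:
                raise FormatError(f"unknown joint name: {joint_s!r}", line=i) from None
            state = rec.get("state", "tracked")
            if state not in STATE_CODES:
                raise FormatError(f"unknown tracking state: {state!r}", line=i)
            pos = rec.get("pos")
            if pos is None:
                x = y = z = np.nan
            else:
                x, y, z = (float(v) for v in pos)
            rows.append((t, b, JOINT_INDEX[joint], x, y, z, STATE_CODES[state], i))
    return _assemble(rows)


def _assemble(rows) -> SkeletonStream:
    """Group per-joint rows into frames and validate stream invariants."""
    if not rows:
        return SkeletonStream(
            np.empty(0), np.empty(0, dtype=int), np.empty((0, N_JOINTS, 3)), np.empty((0, N_JOINTS), dtype=np.int8)
        )
    arr = np.array([(r[0], r[1], r[2]) for r in rows])
    t_col, b_col, j_col = arr[:, 0], arr[:, 1].astype(int), arr[:, 2].astype(int)

    # duplicate (timestamp, body, joint) detection
    key = np.stack([t_col, b_col.astype(float), j_col.astype(float)], axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    if np.any(counts > 1):
        raise ValidationError("duplicate (timestamp, body, joint) sample in stream")

    # frame key = (timestamp, body); stable sort by time then body
    order = np.lexsort((j_col, b_col, t_col))
    frame_keys, starts = np.unique(key[order][:, :2], axis=0, return_index=True)
    n_frames = len(frame_keys)
    times = frame_keys[:, 0]
    body = frame_keys[:, 1].astype(np.int64)
    pos = np.full((n_frames, N_JOINTS, 3), np.nan)
    states = np.zeros((n_frames, N_JOINTS), dtype=np.int8)

    bounds = np.append(starts, len(rows))
    for fi in range(n_frames):
        idx = order[bounds[fi] : bounds[fi + 1]]
        joints_here = j_col[idx]
        if len(idx) != N_JOINTS or len(np.unique(joints_here)) != N_JOINTS:
            raise ValidationError(
                f"frame (t={times[fi]:g}, body={body[fi]}) has {len(idx)} joint "
                f"samples; exactly {N_JOINTS} distinct joints required"
            )
        for ridx in idx:
            t, b, j, x, y, z, st, lineno = rows[ridx]
            states[fi, j] = st
            if st != NOT_TRACKED:
                if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                    raise FormatError(
                        f"non-finite position for tracked joint {CANONICAL_JOINTS[j]}",
                        line=lineno,
                    )
                pos[fi, j] = (x, y, z)
    for b in np.unique(body):
        if np.any(np.diff(times[body == b]) < 0):
            raise ValidationError(f"timestamps not non-decreasing for body {b}")
    return SkeletonStream(times, body, pos, states)


def write_skeleton_stream(frames, sink, format: str = "csv") -> None:
    """Write frames (SkeletonStream or iterable of SkeletonFrame) to a path
    or text stream.  CSV carries six-decimal fixed-point values; JSONL keeps
    full float precision.  Output round-trips through
    :func:`read_skeleton_stream`."""
    stream = as_stream(frames)
    f, should_close = _open_maybe(sink, "w")
    try:
        if format == "csv":
            f.write("# movemetrics skeleton stream; units: metres; timestamps: seconds from session start\n")
            f.write(CSV_HEADER + "\n")
            for i in range(len(stream)):
                t = stream.times[i]
                b = stream.body_index[i]
                for j, name in enumerate(CANONICAL_JOINTS):
                    st = STATE_NAMES[int(stream.states[i, j])]
                    if st == "not_tracked":
                        xyz = ",,"
                    else:
                        x, y, z = stream.positions[i, j]
                        xyz = f"{x:.6f},{y:.6f},{z:.6f}"
                    f.write(f"{t:.6f},{b},{name},{xyz},{st}\n")
        elif format == "jsonl":
            for i in range(len(stream)):
                joints = {}
                for j, name in enumerate(CANONICAL_JOINTS):
                    st = STATE_NAMES[int(stream.states[i, j])]
                    pos = None if st == "not_tracked" else [float(v) for v in stream.positions[i, j]]
                    joints[name] = {"pos": pos, "state": st}
                f.write(
                    json.dumps(
                        {
                            "timestamp_s": float(stream.times[i]),
                            "body_index": int(stream.body_index[i]),
                            "joints": joints,
                        }
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown format: {format!r}")
    finally:
        if should_close:
            f.close()


# ---------------------------------------------------------------------------
# movement matrices


def write_movement_matrix(matrix: MovementMatrix, sink) -> None:
    """Write a movement matrix as TSV (empty cell = missing minute)."""
    f, should_close = _open_maybe(sink, "w")
    try:
        f.write(f"# movemetrics movement matrix; subject_id: {matrix.subject_id}; units: m/min\n")
        cols = "\t".join(f"minute_{m + 1}" for m in range(matrix.minutes))
        f.write(f"joint\t{cols}\n")
        for j, name in enumerate(matrix.joint_names):
            cells = [
                "" if not np.isfinite(v) else repr(float(v))
                for v in matrix.values[j]
            ]
            f.write(name + "\t" + "\t".join(cells) + "\n")
    finally:
        if should_close:
            f.close()


def read_movement_matrix(source) -> MovementMatrix:
    """Read a movement-matrix TSV; missing cells stay NaN, negative values
    are rejected."""
    f, should_close = _open_maybe(source, "r")
    try:
        lines = f.read().splitlines()
    finally:
        if should_close:
            f.close()
    subject_id = ""
    k = 0
    while k < len(lines) and (not lines[k].strip() or lines[k].lstrip().startswith("#")):
        if "subject_id:" in lines[k]:
            subject_id = lines[k].split("subject_id:")[1].split(";")[0].strip()
        k += 1
    if k >= len(lines):
        raise FormatError("empty movement-matrix file")
    header = lines[k].split("\t")
    if header[0] != "joint":
        raise FormatError("first column must be 'joint'", line=k + 1)
    n_min = len(header) - 1
    names, rows = [], []
    for i, raw in enumerate(lines[k + 1 :], start=k + 2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != n_min + 1:
            raise FormatError(
                f"ragged row: expected {n_min + 1} columns, got {len(parts)}", line=i
            )
        try:
            name = normalize_joint(parts[0])
        except KeyError:
            raise FormatError(f"unknown joint name: {parts[0]!r}", line=i) from None
        try:
            vals = [float(c) if c.strip() else np.nan for c in parts[1:]]
        except ValueError as exc:
            raise FormatError(f"malformed value ({exc})", line=i) from None
        for v in vals:
            if np.isfinite(v) and v < 0:
                raise ValidationError(f"negative path length for {name} (line {i})")
        names.append(name)
        rows.append(vals)
    return MovementMatrix(subject_id, tuple(names), np.array(rows, dtype=float))
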