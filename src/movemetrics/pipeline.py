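"""End-to-end orchestration: skeleton streams (recorded or simulated) ->
per-subject movement matrices -> group-comparison and ROC tables ->
per-minute group-mean curves, with a run log recording every parameter.

All report artefacts are plain TSV so they are diffable and testable;
plotting is a convenience layer left to the caller.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import MovementMatrix, SessionMeta
from .errors import MovemetricsError, ValidationError
from .io import read_skeleton_stream, write_movement_matrix
from .joints import ANALYSIS_JOINTS
from .kinematics import build_movement_matrix
from .simulate import SimConfig, SubjectProfile, simulate_two_groups
from .stats import compare_groups, roc_table, rows_to_dataframe
from .tracking import GapPolicy, assign_identities, interpolate_gaps

log = logging.getLogger("movemetrics")


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-representable).

    Either ``group1_dir``/``group2_dir`` point at directories of skeleton
    stream CSVs, or ``simulate`` is set and two groups are generated with
    the programmed effect size.
    """

    out_dir: str = "movemetrics_out"
    group1_dir: str | None = None
    group2_dir: str | None = None
    simulate: bool = False
    n_per_group: int = 8
    effect_size_d: float = 0.8
    session_length: int = 30
    frame_rate: float = 30.0
    n_subjects: int = 4
    seed: int = 0
    unit: str = "minute"
    alpha: float = 0.05
    reid_radius_m: float = 0.5
    max_interp_gap_s: float = 0.5
    include_inferred: bool = True
    smooth_window: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def policy(self) -> GapPolicy:
        return GapPolicy(max_interp_gap=self.max_interp_gap_s, reid_radius=self.reid_radius_m)


class StageError(MovemetricsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def quantify_stream(stream, session_length: int, policy: GapPolicy, *, subject_prefix: str = "subject",
                    include_inferred: bool = True, smooth_window: int | None = None) -> list[MovementMatrix]:
    """Track, repair and quantify one stream into per-subject matrices."""
    tracks = assign_identities(stream, policy)
    out = []
    for track in tracks:
        track = interpolate_gaps(track, policy)
        meta = SessionMeta(f"{subject_prefix}_{track.persistent_id}", session_length=session_length)
        out.append(
            build_movement_matrix(
                track, meta, policy=policy, include_inferred=include_inferred, smooth_window=smooth_window
            )
        )
    return out


def render_minute_curves(
    matrices_group1: Sequence[MovementMatrix],
    matrices_group2: Sequence[MovementMatrix],
    joint: str,
) -> pd.DataFrame:
    """Per-minute group means for one joint (the data behind the classic
    minute-by-minute average curves).

    Missing minutes are excluded from the mean; the per-group contributing
    subject count is reported per minute.
    """
    def cols(matrices):
        n_min = max((m.minutes for m in matrices), default=0)
        vals = np.full((len(matrices), n_min), np.nan)
        for i, m in enumerate(matrices):
            try:
                row = m.row(joint)
            except KeyError:
                continue
            vals[i, : len(row)] = row
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(vals, axis=0) if len(matrices) else np.empty(0)
        count = np.sum(np.isfinite(vals), axis=0)
        return mean, count

    m1, c1 = cols(matrices_group1)
    m2, c2 = cols(matrices_group2)
    n_min = max(len(m1), len(m2))

    def pad(a, fill=np.nan):
        return np.concatenate([a, np.full(n_min - len(a), fill)])

    return pd.DataFrame(
        {
            "minute": np.arange(1, n_min + 1),
            "mean_group1": pad(m1),
            "n_group1": pad(c1, 0).astype(int),
            "mean_group2": pad(m2),
            "n_group2": pad(c2, 0).astype(int),
        }
    )


def _load_group(directory: str, config: RunConfig) -> list[MovementMatrix]:
    paths = sorted(Path(directory).glob("*.csv"))
    if not paths:
        raise ValidationError(f"no skeleton stream CSV files found in {directory!r}")
    matrices = []
    for p in paths:
        stream = read_skeleton_stream(p, format="csv")
        matrices.extend(
            quantify_stream(
                stream,
                config.session_length,
                config.policy(),
                subject_prefix=p.stem,
                include_inferred=config.include_inferred,
                smooth_window=config.smooth_window,
            )
        )
    return matrices


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write all report files into
    ``config.out_dir``.

    Outputs: per-subject matrices (``matrices/``), ``comparison.tsv``
    (joint rows with Levene, t, df, p, d, magnitude), ``roc.tsv``,
    ``minute_curves.tsv`` (all joints stacked) and ``run_log.yaml``.  A
    stage failure leaves an ``INCOMPLETE`` marker naming the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("pipeline running\n")
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            sim_cfg = SimConfig(
                n_subjects=config.n_subjects,
                session_length=config.session_length,
                frame_rate=config.frame_rate,
                seed=config.seed,
            )
            sessions1, sessions2 = simulate_two_groups(
                config.n_per_group, config.effect_size_d, config=sim_cfg, seed=config.seed
            )
            stage = "quantify"
            g1, g2 = [], []
            for group_sessions, acc in ((sessions1, g1), (sessions2, g2)):
                for si, sess in enumerate(group_sessions):
                    acc.extend(
                        quantify_stream(
                            sess["stream"],
                            config.session_length,
                            config.policy(),
                            subject_prefix=f"g{1 if acc is g1 else 2}_s{si:02d}",
                            include_inferred=config.include_inferred,
                            smooth_window=config.smooth_window,
                        )
                    )
        else:
            stage = "load"
            if not config.group1_dir or not config.group2_dir:
                raise ValidationError("group1_dir and group2_dir are required unless simulate=true")
            g1 = _load_group(config.group1_dir, config)
            g2 = _load_group(config.group2_dir, config)

        stage = "write_matrices"
        mat_dir = out / "matrices"
        mat_dir.mkdir(exist_ok=True)
        for gi, group in ((1, g1), (2, g2)):
            for m in group:
                path = mat_dir / f"group{gi}_{m.subject_id}.tsv"
                write_movement_matrix(m, path)
        written["matrices"] = mat_dir

        stage = "compare"
        rows = compare_groups(g1, g2, unit=config.unit, alpha=config.alpha)
        comp = rows_to_dataframe(rows)
        comp_path = out / "comparison.tsv"
        comp.to_csv(comp_path, sep="\t", index=False, float_format="%.6g")
        written["comparison"] = comp_path

        stage = "roc"
        roc_rows = roc_table(g1, g2, unit=config.unit)
        roc_path = out / "roc.tsv"
        pd.DataFrame([vars(r) for r in roc_rows]).to_csv(roc_path, sep="\t", index=False, float_format="%.6g")
        written["roc"] = roc_path

        stage = "curves"
        curves = []
        for joint in ANALYSIS_JOINTS:
            df = render_minute_curves(g1, g2, joint)
            df.insert(0, "joint", joint)
            curves.append(df)
        curves_path = out / "minute_curves.tsv"
        pd.concat(curves, ignore_index=True).to_csv(curves_path, sep="\t", index=False, float_format="%.6g")
        written["minute_curves"] = curves_path

        stage = "log"
        log_path = out / "run_log.yaml"
        with open(log_path, "w") as f:
            yaml.safe_dump(
                {
                    "movemetrics_version": __version__,
                    "config": asdict(config),
                    "seed": config.seed,
                    "n_matrices_group1": len(g1),
                    "n_matrices_group2": len(g2),
                },
                f,
                sort_keys=True,
            )
        written["run_log"] = log_path
    except Exception as exc:
        marker.write_text(f"pipeline failed at stage {stage!r}: {exc}\n")
        raise StageError(stage, exc) from exc
    marker.unlink(missing_ok=True)
    log.info("pipeline complete: %s", ", ".join(str(p) for p in written.values()))
    return written
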