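"""Synthetic classroom sessions with known per-joint movement ground truth.

The generator emulates what a depth-camera body tracker would record during
a 30-minute seated workshop of up to six children:

* Each subject sits at a fixed seat; every joint follows a **tethered
  (mean-reverting) random walk** around its seated rest pose.  The
  per-frame innovation SD is calibrated in closed form so that the expected
  per-minute 3-D path length equals the profile's target intensity: for an
  isotropic Gaussian per-axis displacement SD s, the expected step norm is
  ``E||step|| = s * 2 * sqrt(2/pi)`` (the chi-distribution mean with 3
  degrees of freedom), so a minute of n steps covers ``n * s * 2*sqrt(2/pi)``
  metres in expectation.  The mean-reversion (AR(1) coefficient phi) and
  additive sensor noise are folded into that effective SD exactly, so the
  calibration holds at stationarity for any reversion rate and frame rate.
* Movement is **bursty**: a per-minute gamma-distributed intensity
  multiplier (mean 1) shared by all of a subject's joints modulates the walk,
  giving minute-to-minute variability of the same order seen in real seated
  recordings.
* **Occlusions** arrive as a Poisson process per subject: short joint-level
  dropouts (a joint goes ``not_tracked``) and rare whole-body dropouts
  (the subject disappears and is re-detected, possibly in a different
  device slot), which exercises identity re-assignment.

Everything is reproducible from a seed; ground-truth movement matrices are
computed from the noiseless pre-occlusion trajectories with the same
minute-binning used by the kinematics module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .core import NOT_TRACKED, TRACKED, MovementMatrix, SessionMeta, SkeletonStream
from .errors import CapacityError, ValidationError
from .joints import ANALYSIS_JOINTS, CANONICAL_JOINTS, JOINT_INDEX
from .stats import ObserverCounts

N_JOINTS = len(CANONICAL_JOINTS)

# E||N(0, s^2 I_3)|| = s * CHI3_MEAN ; Var||.|| = s^2 * CHI3_VAR
CHI3_MEAN = 2.0 * math.sqrt(2.0 / math.pi)
CHI3_VAR = 3.0 - 8.0 / math.pi

# Typical seated per-minute path lengths (m/min) for the 17 analysis joints:
# trunk joints move a couple of metres per minute, wrists an order of
# magnitude more, ankles in between.
DEFAULT_INTENSITY: dict[str, float] = {
    "spine_base": 2.5,
    "spine_mid": 1.6,
    "neck": 2.3,
    "head": 2.4,
    "left_shoulder": 2.1,
    "left_elbow": 6.5,
    "left_wrist": 12.8,
    "right_shoulder": 2.0,
    "right_elbow": 7.9,
    "right_wrist": 15.4,
    "left_hip": 2.7,
    "left_knee": 3.2,
    "left_ankle": 8.2,
    "right_hip": 2.7,
    "right_knee": 3.1,
    "right_ankle": 8.6,
    "spine_shoulder": 2.0,
}

# Hand-region joints inherit the wrist intensity, feet the ankle intensity.
_DERIVED_FROM = {
    "left_hand": "left_wrist",
    "left_hand_tip": "left_wrist",
    "left_thumb": "left_wrist",
    "right_hand": "right_wrist",
    "right_hand_tip": "right_wrist",
    "right_thumb": "right_wrist",
    "left_foot": "left_ankle",
    "right_foot": "right_ankle",
}

# Seated rest pose: joint offsets (m) from the seat reference point
# (spine base), camera coordinates (x lateral, y vertical, z depth).
REST_OFFSETS: dict[str, tuple[float, float, float]] = {
    "spine_base": (0.0, 0.0, 0.0),
    "spine_mid": (0.0, 0.25, 0.0),
    "spine_shoulder": (0.0, 0.45, 0.0),
    "neck": (0.0, 0.52, 0.0),
    "head": (0.0, 0.68, 0.02),
    "left_shoulder": (-0.18, 0.45, 0.0),
    "left_elbow": (-0.24, 0.22, -0.05),
    "left_wrist": (-0.22, 0.05, -0.18),
    "left_hand": (-0.22, 0.02, -0.24),
    "left_hand_tip": (-0.22, 0.01, -0.28),
    "left_thumb": (-0.19, 0.02, -0.24),
    "right_shoulder": (0.18, 0.45, 0.0),
    "right_elbow": (0.24, 0.22, -0.05),
    "right_wrist": (0.22, 0.05, -0.18),
    "right_hand": (0.22, 0.02, -0.24),
    "right_hand_tip": (0.22, 0.01, -0.28),
    "right_thumb": (0.19, 0.02, -0.24),
    "left_hip": (-0.09, -0.02, 0.0),
    "left_knee": (-0.12, -0.35, -0.25),
    "left_ankle": (-0.13, -0.72, -0.18),
    "left_foot": (-0.13, -0.78, -0.30),
    "right_hip": (0.09, -0.02, 0.0),
    "right_knee": (0.12, -0.35, -0.25),
    "right_ankle": (0.13, -0.72, -0.18),
    "right_foot": (0.13, -0.78, -0.30),
}

_DEFAULT_SEATS = [
    (-1.2, 0.85, 2.4),
    (-0.4, 0.85, 2.6),
    (0.4, 0.85, 2.6),
    (1.2, 0.85, 2.4),
    (-0.8, 0.85, 3.2),
    (0.8, 0.85, 3.2),
]


@dataclass
class SubjectProfile:
    """Generating parameters for one simulated subject.

    ``intensities`` maps each of the 17 analysis joints to its target
    expected path length per minute (m); hand/foot-region joints inherit
    from the wrist/ankle.  ``minute_cv`` is the coefficient of variation of
    the per-minute burst multiplier (0 disables bursts).  Occlusion events
    (joint-level) and dropouts (whole-body) are Poisson with the given
    per-minute rates and exponential mean durations (s).
    """

    subject_id: str
    group: str = "experimental"
    medication: str = "n/a"
    sex: str = "boy"
    intensities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITY))
    seat: tuple[float, float, float] | None = None
    minute_cv: float = 0.5
    occlusion_rate: float = 0.5  # joint-level events / minute
    occlusion_duration: float = 0.3  # mean seconds
    dropout_rate: float = 0.02  # body-loss events / minute
    dropout_duration: float = 5.0  # mean seconds

    def __post_init__(self):
        for j, v in self.intensities.items():
            if v < 0:
                raise ValidationError(f"negative intensity for {j}")
        for name in ("minute_cv", "occlusion_rate", "occlusion_duration", "dropout_rate", "dropout_duration"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def full_intensities(self) -> np.ndarray:
        """Per-joint intensity vector over all 25 joints (m/min)."""
        out = np.zeros(N_JOINTS)
        for j, name in enumerate(CANONICAL_JOINTS):
            src = _DERIVED_FROM.get(name, name)
            out[j] = self.intensities.get(src, 0.0)
        return out

    def scaled(self, factor: float) -> "SubjectProfile":
        return replace(self, intensities={k: v * factor for k, v in self.intensities.items()})


@dataclass
class SimConfig:
    """Session-level simulation parameters."""

    n_subjects: int = 4
    session_length: int = 30  # minutes
    frame_rate: float = 30.0  # Hz
    noise_sd: float = 0.0  # additive sensor noise per axis (m)
    mean_revert_rate: float = 0.5  # 1/s pull toward the rest pose
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_subjects <= 6:
            raise ValidationError("n_subjects must be in 1..6")
        if self.frame_rate <= 0 or self.session_length <= 0:
            raise ValidationError("frame_rate and session_length must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _step_sigma(intensity_per_min: np.ndarray, frame_rate: float, phi: float, noise_sd: float) -> np.ndarray:
    """Innovation SD per axis so the expected per-minute path equals the
    target.

    The observed per-frame displacement of a stationary AR(1) walk with
    coefficient phi and innovation SD q has per-axis variance
    2 q^2/(1+phi); independent sensor noise adds 2*noise_sd^2.  Solving
    ``sqrt(total) * CHI3_MEAN * steps_per_minute = intensity`` for q.
    """
    n = 60.0 * frame_rate
    lam = np.asarray(intensity_per_min, dtype=float)
    target = lam / (n * CHI3_MEAN)  # required total per-axis SD
    q2 = (target**2 - 2.0 * noise_sd**2) * (1.0 + phi) / 2.0
    if np.any((q2 < -1e-18) & (lam > 0)):
        warnings.warn(
            "sensor noise floor exceeds a positive target intensity; the "
            "affected joints will move at the noise floor instead",
            stacklevel=2,
        )
    return np.sqrt(np.clip(q2, 0.0, None))


def expected_minute_sd(intensity: float, frame_rate: float, minute_cv: float, subject_cv: float = 0.0) -> float:
    """Closed-form SD of the per-minute path length under the generator.

    Combines the step-sum sampling noise (chi-distribution variance over
    ``60*frame_rate`` steps), the per-minute burst multiplier and an
    optional subject-level multiplier, all multiplicative and independent.
    """
    n = 60.0 * frame_rate
    cv_samp2 = CHI3_VAR / (n * CHI3_MEAN**2)
    cv_tot2 = (1 + subject_cv**2) * (1 + minute_cv**2) * (1 + cv_samp2) - 1
    return intensity * math.sqrt(cv_tot2)


def _poisson_intervals(rng, rate_per_min: float, mean_duration_s: float, total_s: float):
    """Poisson event windows [(start, end), ...] within the session."""
    if rate_per_min <= 0 or mean_duration_s <= 0:
        return []
    n = rng.poisson(rate_per_min * total_s / 60.0)
    starts = np.sort(rng.uniform(0, total_s, n))
    durs = rng.exponential(mean_duration_s, n)
    return [(float(s), float(min(s + d, total_s))) for s, d in zip(starts, durs)]


def _simulate_subject(profile: SubjectProfile, config: SimConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray, MovementMatrix]:
    """One subject's trajectories.

    Returns (times, positions (n,25,3), states (n,25), truth matrix).
    """
    f = config.frame_rate
    n_frames = int(round(config.session_length * 60 * f))
    times = np.arange(n_frames) / f
    phi = math.exp(-config.mean_revert_rate / f)

    lam = profile.full_intensities()  # (25,)
    # per-minute burst multipliers, shared across joints
    if profile.minute_cv > 0:
        k = 1.0 / profile.minute_cv**2
        bursts = rng.gamma(k, 1.0 / k, config.session_length)
    else:
        bursts = np.ones(config.session_length)
    minute_of_frame = np.minimum((times // 60).astype(int), config.session_length - 1)
    lam_frame = lam[None, :] * bursts[minute_of_frame, None]  # (n, 25)
    q = _step_sigma(lam_frame, f, phi, config.noise_sd)  # (n, 25)

    # AR(1) around the rest pose, vectorised with a linear filter.
    rest = np.array([REST_OFFSETS[name] for name in CANONICAL_JOINTS]) + np.asarray(profile.seat)
    innov = rng.standard_normal((n_frames, N_JOINTS, 3)) * q[:, :, None]
    # stationary initial deviation
    q0 = q[0] / math.sqrt(1.0 - phi**2)
    y0 = rng.standard_normal((N_JOINTS, 3)) * q0[:, None]
    flat = innov.reshape(n_frames, -1)
    zi = (phi * y0.reshape(1, -1))
    dev, _ = lfilter([1.0], [1.0, -phi], flat, axis=0, zi=zi)
    pos_true = rest[None, :, :] + dev.reshape(n_frames, N_JOINTS, 3)
    if config.noise_sd > 0:
        pos_obs = pos_true + rng.standard_normal(pos_true.shape) * config.noise_sd
    else:
        pos_obs = pos_true

    # ground truth from the observed pre-occlusion trajectory, same binning
    d = np.linalg.norm(np.diff(pos_obs, axis=0), axis=2)  # (n-1, 25)
    bins = (times[1:] // 60).astype(int)
    truth = np.zeros((N_JOINTS, config.session_length))
    np.add.at(truth.T, bins, d)
    analysis_idx = [JOINT_INDEX[j] for j in ANALYSIS_JOINTS]
    truth_matrix = MovementMatrix(profile.subject_id, ANALYSIS_JOINTS, truth[analysis_idx])

    # joint-level occlusions
    states = np.full((n_frames, N_JOINTS), TRACKED, dtype=np.int8)
    total_s = config.session_length * 60.0
    for start, end in _poisson_intervals(rng, profile.occlusion_rate, profile.occlusion_duration, total_s):
        j = rng.integers(N_JOINTS)
        mask = (times >= start) & (times < end)
        states[mask, j] = NOT_TRACKED
    pos_obs = pos_obs.copy()
    pos_obs[states == NOT_TRACKED] = np.nan

    # whole-body dropouts: frames removed entirely
    present = np.ones(n_frames, dtype=bool)
    for start, end in _poisson_intervals(rng, profile.dropout_rate, profile.dropout_duration, total_s):
        present &= ~((times >= start) & (times < end))

    return times[present], pos_obs[present], states[present], truth_matrix


def _assign_slots(per_subject_times: list[np.ndarray], frame_rate: float) -> list[np.ndarray]:
    """Device slot index per frame for each subject.

    Subjects keep a slot while continuously present; on re-detection after a
    dropout the lowest currently free slot is taken (device-like churn).
    """
    gap = 1.5 / frame_rate
    events = []  # (time, kind, subject, run_slice)
    runs_per_subject = []
    for s, t in enumerate(per_subject_times):
        if len(t) == 0:
            runs_per_subject.append([])
            continue
        breaks = np.flatnonzero(np.diff(t) > gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(t)]])
        runs = list(zip(starts, ends))
        runs_per_subject.append(runs)
        for rs, re_ in runs:
            events.append((t[rs], "start", s, (rs, re_)))
            events.append((t[re_ - 1], "end", s, (rs, re_)))
    events.sort(key=lambda e: (e[0], e[1] == "start", e[2]))  # ends before starts at ties

    slots = [np.full(len(t), -1, dtype=np.int64) for t in per_subject_times]
    free = list(range(6))
    held: dict[int, int] = {}
    for _, kind, s, (rs, re_) in events:
        if kind == "start":
            if not free:
                raise CapacityError("more than 6 concurrently detected bodies")
            slot = min(free)
            free.remove(slot)
            held[s] = slot
            slots[s][rs:re_] = slot
        else:
            slot = held.pop(s, None)
            if slot is not None:
                free.append(slot)
    return slots


def simulate_session(
    profiles: list[SubjectProfile], config: SimConfig
) -> tuple[SkeletonStream, dict[str, MovementMatrix]]:
    """Simulate one multi-subject session.

    Returns the interleaved skeleton stream (time-sorted) and the
    ground-truth movement matrix per subject id.  Fully reproducible from
    ``config.seed``.
    """
    if len(profiles) > 6:
        raise CapacityError("at most 6 subjects per session")
    if len(profiles) == 0:
        raise ValidationError("at least one subject profile required")
    seeds = np.random.SeedSequence(config.seed).spawn(len(profiles))
    truths: dict[str, MovementMatrix] = {}
    per_times, per_pos, per_states = [], [], []
    for i, profile in enumerate(profiles):
        if profile.seat is None:
            profile = replace(profile, seat=_DEFAULT_SEATS[i % len(_DEFAULT_SEATS)])
        rng = np.random.default_rng(seeds[i])
        t, p, st, truth = _simulate_subject(profile, config, rng)
        truths[profile.subject_id] = truth
        per_times.append(t)
        per_pos.append(p)
        per_states.append(st)

    slots = _assign_slots(per_times, config.frame_rate)
    times = np.concatenate(per_times)
    body = np.concatenate(slots)
    pos = np.concatenate(per_pos)
    states = np.concatenate(per_states)
    order = np.lexsort((body, times))
    stream = SkeletonStream(times[order], body[order], pos[order], states[order])
    return stream, truths


def two_group_intensity_ratio(effect_size_d: float, frame_rate: float, minute_cv: float, subject_cv: float) -> float:
    """Multiplicative intensity shift giving a standardized per-minute
    path-length difference of ``effect_size_d``.

    With multiplicative within/between-subject variability the group-2 SD
    scales with its mean, so the ratio r solves the fixed point
    ``r = 1 + d * cv * sqrt((1 + r^2)/2)``.
    """
    if effect_size_d < 0:
        raise ValidationError("effect size must be >= 0")
    cv = expected_minute_sd(1.0, frame_rate, minute_cv, subject_cv)
    r = 1.0
    for _ in range(100):
        r_new = 1.0 + effect_size_d * cv * math.sqrt((1.0 + r * r) / 2.0)
        if abs(r_new - r) < 1e-12:
            break
        r = r_new
    return r


def simulate_two_groups(
    n_per_group: int,
    effect_size_d: float,
    base_profile: SubjectProfile | None = None,
    config: SimConfig | None = None,
    subject_cv: float = 0.05,
    seed: int | None = None,
):
    """Simulate two groups of subjects whose per-minute path lengths differ
    by a programmed standardized effect size.

    Subjects are partitioned into sessions of ``config.n_subjects``; each
    subject's intensities get an independent lognormal factor (CV
    ``subject_cv``), and every group-2 subject's intensities are scaled by
    the ratio that realises ``effect_size_d`` on the pooled minute
    distribution in expectation.

    Returns ``(sessions1, sessions2)``; each session is a dict with keys
    ``stream``, ``truths`` (subject_id -> MovementMatrix) and ``metas``
    (subject_id -> SessionMeta).
    """
    config = config or SimConfig()
    base = base_profile or SubjectProfile(subject_id="base")
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    ratio = two_group_intensity_ratio(effect_size_d, config.frame_rate, base.minute_cv, subject_cv)
    group_scale = {"experimental": ratio, "control": 1.0}

    out = {"experimental": [], "control": []}
    mu = -0.5 * math.log(1 + subject_cv**2)
    sig = math.sqrt(math.log(1 + subject_cv**2))
    rng_subj = np.random.default_rng(root.spawn(1)[0])
    session_seeds = iter(np.random.SeedSequence(seed + 1).generate_state(10_000))
    for group in ("experimental", "control"):
        remaining = n_per_group
        sess_no = 0
        while remaining > 0:
            k = min(config.n_subjects, remaining)
            profiles = []
            metas = {}
            for i in range(k):
                sid = f"{group[:3]}_{sess_no:02d}_{i}"
                factor = float(rng_subj.lognormal(mu, sig)) if subject_cv > 0 else 1.0
                prof = base.scaled(factor * group_scale[group])
                prof = replace(prof, subject_id=sid, group=group)
                profiles.append(prof)
                metas[sid] = SessionMeta(sid, group=group, session_length=config.session_length)
            sess_cfg = replace(config, n_subjects=k, seed=int(next(session_seeds) % (2**31)))
            stream, truths = simulate_session(profiles, sess_cfg)
            out[group].append({"stream": stream, "truths": truths, "metas": metas})
            remaining -= k
            sess_no += 1
    return out["experimental"], out["control"]


def sample_minute_paths(
    intensity: float,
    n_minutes: int,
    config: SimConfig | None = None,
    minute_cv: float = 0.5,
    rng=None,
) -> np.ndarray:
    """Draw i.i.d. per-minute path lengths directly from the walk model
    (no tracking pipeline): each minute sums ``60*frame_rate`` independent
    3-D Gaussian step norms at the burst-modulated step SD.

    Useful for statistical calibration at scale (e.g. type-I error of the
    group comparison under the null).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = int(round(60 * config.frame_rate))
    if minute_cv > 0:
        k = 1.0 / minute_cv**2
        lam = intensity * rng.gamma(k, 1.0 / k, n_minutes)
    else:
        lam = np.full(n_minutes, float(intensity))
    s = lam / (n * CHI3_MEAN)
    steps = rng.standard_normal((n_minutes, n, 3)) * s[:, None, None]
    return np.linalg.norm(steps, axis=2).sum(axis=1)


def simulate_observer_counts(
    n_subjects: int,
    rate_a: float = 8.0,
    agreement_prob: float = 0.9,
    seed: int = 0,
    behaviours: tuple[str, ...] = ("squirm", "leave_seat"),
) -> list[ObserverCounts]:
    """Dual-observer behaviour counts: observer A draws Poisson counts;
    observer B reproduces A's count with probability ``agreement_prob``,
    otherwise draws independently from the same Poisson law."""
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        for b in behaviours:
            a = int(rng.poisson(rate_a))
            if rng.random() < agreement_prob:
                bb = a
            else:
                bb = int(rng.poisson(rate_a))
            out.append(ObserverCounts(f"subj_{s:02d}", b, a, bb))
    return out
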