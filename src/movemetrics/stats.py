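"""Group-comparison statistics: Levene-gated two-sample t-tests, Cohen's d
with magnitude bands, rank-based ROC AUC with accuracy bands, and Cohen's
kappa for dual-observer behaviour counts.

Conventions
-----------
* The variance-homogeneity gate is Levene's test with mean centering; the
  ``auto`` rule uses the pooled-variance Student t when Levene's p >= alpha
  and Welch's t (Welch-Satterthwaite df) otherwise.
* Cohen's d is reported unsigned.  Two poolings of the SD are exposed:
  ``df_weighted`` (the usual (n-1)-weighted pooled SD) and ``equal``
  (s_p^2 = (s1^2 + s2^2)/2, appropriate when group sizes are unknown or a
  paired/summary design makes per-group ns meaningless).
* AUC is the normalized Mann-Whitney U statistic
  P(X > Y) + P(X = Y)/2, computed from ranks (exact tie handling).
* Magnitude bands: d < 0.20 below threshold, 0.20 <= d <= 0.50 small,
  0.50 < d <= 0.80 moderate, d > 0.80 large.  AUC bands: 0.5 chance,
  (0.5, 0.7) lower, [0.7, 0.9] moderate, > 0.9 higher accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .core import MovementMatrix
from .errors import ValidationError
from .joints import ANALYSIS_JOINTS, normalize_joint

__all__ = [
    "levene_test",
    "two_sample_t",
    "two_sample_t_from_stats",
    "cohens_d",
    "classify_d",
    "roc_auc",
    "classify_auc",
    "cohens_kappa",
    "contingency_table",
    "observer_kappa",
    "compare_groups",
    "roc_table",
    "GroupComparisonRow",
    "RocRow",
    "ObserverCounts",
]


# ---------------------------------------------------------------------------
# elementary tests


def _check_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) < min_n:
        raise ValidationError(f"sample {name!r} needs >= {min_n} finite values")
    return x


def levene_test(x, y) -> tuple[float, float]:
    """Levene's variance-homogeneity test (mean centering).

    Returns (F, p).  If every value in both groups is identical the
    statistic degenerates; (0.0, 1.0) is returned.
    """
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = sps.levene(x, y, center="mean")
    if not np.isfinite(F):
        return 0.0, 1.0
    return float(F), float(p)


def two_sample_t(x, y, variance_rule: str = "auto", alpha: float = 0.05) -> tuple[float, float, float]:
    """Two-sample t-test; returns (t, df, p), with t > 0 when mean(x) > mean(y).

    ``variance_rule``: ``pooled`` (Student), ``welch``, or ``auto`` which
    gates on Levene's test at ``alpha`` (pooled when homogeneous).
    A zero-variance degenerate pair with unequal means signals infinite
    separation via t = +/-inf, p = 0.
    """
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    if variance_rule == "auto":
        _, lev_p = levene_test(x, y)
        variance_rule = "pooled" if lev_p >= alpha else "welch"
    if variance_rule not in ("pooled", "welch"):
        raise ValueError(f"unknown variance rule: {variance_rule!r}")
    equal_var = variance_rule == "pooled"
    n1, n2 = len(x), len(y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = n1 + n2 - 2 if equal_var else max(n1, n2) - 1
        if x.mean() == y.mean():
            return 0.0, float(df), 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), float(df), 0.0
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int, variance_rule: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t from summary statistics (means, SDs, ns)."""
    equal_var = variance_rule == "pooled"
    if variance_rule not in ("pooled", "welch"):
        raise ValueError(f"unknown variance rule: {variance_rule!r}")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:
        a, b = sd1**2 / n1, sd2**2 / n2
        df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def cohens_d(
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    n1: int | None = None,
    n2: int | None = None,
    weighting: str = "df_weighted",
) -> float:
    """Unsigned standardized mean difference |m1 - m2| / s_pooled.

    ``df_weighted``: s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)
    (requires n1, n2); ``equal``: s_p^2 = (s1^2 + s2^2)/2.

    A zero pooled SD yields d = 0 for equal means and ``inf`` (explicit
    infinite-separation signal) for unequal means.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be non-negative")
    if weighting == "df_weighted":
        if n1 is None or n2 is None or n1 < 2 or n2 < 2:
            raise ValidationError("df_weighted pooling needs n1, n2 >= 2")
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    elif weighting == "equal":
        sp2 = (sd1**2 + sd2**2) / 2.0
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    diff = abs(mean1 - mean2)
    if sp2 == 0:
        return 0.0 if diff == 0 else float(np.inf)
    return float(diff / np.sqrt(sp2))


def classify_d(d: float) -> str:
    """Magnitude band of an unsigned effect size."""
    if d < 0:
        raise ValidationError("d must be unsigned (>= 0)")
    if d < 0.20:
        return "below_threshold"
    if d <= 0.50:
        return "small"
    if d <= 0.80:
        return "moderate"
    return "large"


def roc_auc(positives, negatives) -> float:
    """Area under the ROC curve as the normalized Mann-Whitney U:
    P(positive > negative) + P(tie)/2, exact under ties."""
    pos = _check_sample(positives, "positives", min_n=1)
    neg = _check_sample(negatives, "negatives", min_n=1)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    n1, n2 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def classify_auc(auc: float) -> tuple[str, bool]:
    """Accuracy band of an AUC value; the flag marks a value below 0.5
    (chance-or-inverted separation)."""
    if not 0 <= auc <= 1:
        raise ValidationError("AUC must lie in [0, 1]")
    if auc < 0.5:
        return "chance", True
    if auc == 0.5:
        return "chance", False
    if auc < 0.7:
        return "lower", False
    if auc <= 0.9:
        return "moderate", False
    return "higher", False


def cohens_kappa(table) -> float:
    """Unweighted Cohen's kappa from a K x K contingency table of two
    observers' category assignments.

    kappa = (p_o - p_e) / (1 - p_e); the degenerate case p_e = 1 (all mass
    in one cell, hence perfect agreement) returns 1.0 with a warning.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValidationError("contingency table must be square")
    if np.any(table < 0) or not np.all(table == np.floor(table)):
        raise ValidationError("contingency table must hold non-negative integers")
    total = table.sum()
    if total < 1:
        raise ValidationError("empty contingency table")
    p_o = np.trace(table) / total
    rows = table.sum(axis=1) / total
    cols = table.sum(axis=0) / total
    p_e = float(rows @ cols)
    if p_e >= 1.0:
        warnings.warn("degenerate agreement table: expected agreement is 1", stacklevel=2)
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# observer counts


@dataclass(frozen=True)
class ObserverCounts:
    """Counts of one target behaviour for one subject from two observers."""

    subject_id: str
    behaviour: str  # leave_seat | squirm
    observer_a_count: int
    observer_b_count: int

    def __post_init__(self):
        if self.behaviour not in ("leave_seat", "squirm"):
            raise ValidationError(f"unknown behaviour: {self.behaviour!r}")
        if self.observer_a_count < 0 or self.observer_b_count < 0:
            raise ValidationError("behaviour counts must be non-negative")


def contingency_table(counts: Sequence[ObserverCounts]) -> np.ndarray:
    """Square contingency table over the union of count values seen by
    either observer, pooling all (subject, behaviour) pairs."""
    if not counts:
        raise ValidationError("no observer counts")
    cats = sorted({c.observer_a_count for c in counts} | {c.observer_b_count for c in counts})
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), dtype=int)
    for c in counts:
        table[index[c.observer_a_count], index[c.observer_b_count]] += 1
    return table


def observer_kappa(counts: Sequence[ObserverCounts]) -> float:
    """Inter-observer agreement (Cohen's kappa) on exact count categories."""
    return cohens_kappa(contingency_table(counts))


# ---------------------------------------------------------------------------
# joint-wise group comparison


@dataclass
class GroupComparisonRow:
    """One analysis joint's full comparison record (one table row)."""

    joint: str
    levene_F: float = np.nan
    levene_p: float = np.nan
    mean1: float = np.nan
    sd1: float = np.nan
    n1: int = 0
    mean2: float = np.nan
    sd2: float = np.nan
    n2: int = 0
    t: float = np.nan
    df: float = np.nan
    p: float = np.nan
    d: float = np.nan
    magnitude: str = ""
    valid: bool = True
    note: str = ""


@dataclass
class RocRow:
    joint: str
    auc: float
    band: str
    inverted: bool = False
    n1: int = 0
    n2: int = 0


def _observations(matrices: Iterable[MovementMatrix], joint: str, unit: str) -> np.ndarray:
    vals = []
    for m in matrices:
        try:
            row = m.row(joint)
        except KeyError:
            continue
        row = row[np.isfinite(row)]
        if len(row) == 0:
            continue
        if unit == "minute":
            vals.append(row)
        elif unit == "subject":
            vals.append([row.mean()])
        else:
            raise ValueError(f"unknown unit: {unit!r}")
    return np.concatenate(vals) if vals else np.empty(0)


def _has_joint(matrices, joint) -> bool:
    return any(joint in m.joint_names for m in matrices)


def compare_groups(
    matrices_group1: Sequence[MovementMatrix],
    matrices_group2: Sequence[MovementMatrix],
    unit: str = "minute",
    alpha: float = 0.05,
    joints: tuple[str, ...] = ANALYSIS_JOINTS,
    holm: bool = False,
) -> list[GroupComparisonRow]:
    """Joint-by-joint two-group comparison of movement matrices.

    ``unit='minute'`` pools per-minute path lengths across subjects (large
    df, the classic presentation); ``unit='subject'`` compares per-subject
    session means (conservative).  Missing minutes are excluded.  A joint
    absent from either group, or with < 2 observations in a group, yields a
    flagged row rather than being dropped.

    ``holm=True`` appends Holm-corrected p-values in each row's note field
    (an extension; no correction is applied to ``p`` itself).
    """
    rows: list[GroupComparisonRow] = []
    for joint in joints:
        joint = normalize_joint(joint)
        x = _observations(matrices_group1, joint, unit)
        y = _observations(matrices_group2, joint, unit)
        if not (_has_joint(matrices_group1, joint) and _has_joint(matrices_group2, joint)):
            rows.append(GroupComparisonRow(joint=joint, valid=False, note="joint absent from a group"))
            continue
        if len(x) < 2 or len(y) < 2:
            rows.append(
                GroupComparisonRow(
                    joint=joint, n1=len(x), n2=len(y), valid=False, note="fewer than 2 observations in a group"
                )
            )
            continue
        F, lev_p = levene_test(x, y)
        rule = "pooled" if lev_p >= alpha else "welch"
        t, df, p = two_sample_t(x, y, variance_rule=rule)
        d = cohens_d(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1), len(x), len(y), weighting="df_weighted")
        rows.append(
            GroupComparisonRow(
                joint=joint,
                levene_F=F,
                levene_p=lev_p,
                mean1=float(x.mean()),
                sd1=float(x.std(ddof=1)),
                n1=len(x),
                mean2=float(y.mean()),
                sd2=float(y.std(ddof=1)),
                n2=len(y),
                t=t,
                df=df,
                p=p,
                d=d,
                magnitude=classify_d(d) if np.isfinite(d) else "large",
            )
        )
    if holm:
        valid = [r for r in rows if r.valid and np.isfinite(r.p)]
        order = np.argsort([r.p for r in valid])
        m = len(valid)
        running = 0.0
        for rank, oi in enumerate(order):
            adj = min(1.0, (m - rank) * valid[oi].p)
            running = max(running, adj)
            valid[oi].note = (valid[oi].note + f" holm_p={running:.6g}").strip()
    return rows


def roc_table(
    matrices_group1: Sequence[MovementMatrix],
    matrices_group2: Sequence[MovementMatrix],
    unit: str = "minute",
    joints: tuple[str, ...] = ANALYSIS_JOINTS,
) -> list[RocRow]:
    """Per-joint AUC with group 1 as the positive class."""
    rows = []
    for joint in joints:
        joint = normalize_joint(joint)
        x = _observations(matrices_group1, joint, unit)
        y = _observations(matrices_group2, joint, unit)
        if len(x) == 0 or len(y) == 0:
            rows.append(RocRow(joint=joint, auc=np.nan, band="", n1=len(x), n2=len(y)))
            continue
        auc = roc_auc(x, y)
        band, inverted = classify_auc(auc)
        rows.append(RocRow(joint=joint, auc=auc, band=band, inverted=inverted, n1=len(x), n2=len(y)))
    return rows


def rows_to_dataframe(rows: Sequence[GroupComparisonRow]):
    import pandas as pd

    return pd.DataFrame([vars(r) for r in rows])
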