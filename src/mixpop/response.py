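"""Chemo-resistance classification and the sensitivity/specificity decision curve.

Within one treatment arm, patients who died of their disease within five
years of diagnosis are classified resistant; patients who demonstrably
survived five years (dead or alive) are sensitive. Two exclusion rules
apply: death from another cause within five years, and censoring before
five years (survival status at five years unknowable). Expression is then
related to outcome through per-survival-year bins (one-way ANOVA plus a
linear trend contrast) and through a decision curve of sensitivity and
specificity against an expression cut-off, whose crossing point estimates
the optimum single-gene cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

STATUSES = ("resistant", "sensitive", "excluded")
EXCLUSION_REASONS = ("died_other_cause_lt5y", "followup_lt5y", "not_in_arm", "none")


@dataclass
class ResponseClassification:
    patient_ids: list
    status: np.ndarray  # resistant / sensitive / excluded
    reason: np.ndarray  # exclusion reason, "none" for classified patients

    def mask(self, status: str) -> np.ndarray:
        return self.status == status


@dataclass
class BinSummary:
    label: str  # "1".."5" (completed survival year) or ">5"
    n: int
    mean: float  # nan when empty
    values: np.ndarray


@dataclass
class DecisionCurve:
    cutoffs: np.ndarray
    sensitivity: np.ndarray  # P(value < c | resistant), non-decreasing in c
    specificity: np.ndarray  # P(value >= c | sensitive), non-increasing in c
    crossover_cutoff: float
    crossover_value: float


def classify_patients(records, arm: str = "chemo_only", threshold: float = 5.0) -> ResponseClassification:
    """Resistant/sensitive/excluded status for every record.

    Within the arm: disease death before ``threshold`` years is resistant;
    survival to ``threshold`` (any vital status, including death at
    exactly the threshold) is sensitive; other-cause death or censoring
    before the threshold is excluded. Records outside the arm are
    excluded with reason ``not_in_arm``.
    """
    ids, status, reason = [], [], []
    for r in records:
        ids.append(r.patient_id)
        if r.treatment != arm:
            status.append("excluded")
            reason.append("not_in_arm")
        elif r.survival_time >= threshold:
            status.append("sensitive")
            reason.append("none")
        elif r.outcome == "died_of_disease":
            status.append("resistant")
            reason.append("none")
        elif r.outcome == "died_other_cause":
            status.append("excluded")
            reason.append("died_other_cause_lt5y")
        else:  # alive or unknown with short follow-up
            status.append("excluded")
            reason.append("followup_lt5y")
    return ResponseClassification(
        patient_ids=ids,
        status=np.array(status, dtype=object),
        reason=np.array(reason, dtype=object),
    )


def survival_bins(records, values, arm: str = "chemo_only", threshold: float = 5.0) -> list[BinSummary]:
    """Mean expression by completed survival year 1..threshold, plus > threshold.

    Bin k covers disease deaths with survival in [k-1, k) years; all
    patients classified sensitive (survival >= threshold) form the final
    bin. Excluded patients appear in no bin. Empty bins are reported with
    n = 0 and an undefined mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size != len(records):
        raise ValueError("values must align with records")
    cls = classify_patients(records, arm=arm, threshold=threshold)
    n_year_bins = int(np.ceil(threshold))
    bins: list[BinSummary] = []
    times = np.array([r.survival_time for r in records])
    for k in range(1, n_year_bins + 1):
        in_bin = (cls.status == "resistant") & (times >= k - 1) & (times < k)
        v = values[in_bin]
        bins.append(
            BinSummary(
                label=str(k),
                n=int(in_bin.sum()),
                mean=float(v.mean()) if v.size else float("nan"),
                values=v,
            )
        )
    sens = cls.status == "sensitive"
    v = values[sens]
    bins.append(
        BinSummary(
            label=f">{threshold:g}",
            n=int(sens.sum()),
            mean=float(v.mean()) if v.size else float("nan"),
            values=v,
        )
    )
    return bins


def anova_trend(bins: list[BinSummary]) -> tuple["TestStat", "TestStat"]:
    """One-way ANOVA across non-empty bins plus a linear trend contrast.

    The trend statistic is the linear contrast of bin means with equally
    spaced scores, standardised by the pooled within-bin variance, on the
    ANOVA residual degrees of freedom (two-sided t).
    """
    groups = [b.values for b in bins if b.n > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty bins")
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    n_total = int(ns.sum())
    df_w = n_total - k
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_w = ss_w / df_w
    if ms_w == 0:
        f_stat, p_f = 0.0, 1.0
    else:
        f_stat = (ss_b / (k - 1)) / ms_w
        p_f = float(stats.f.sf(f_stat, k - 1, df_w))
    anova = TestStat(statistic=float(f_stat), df=(k - 1, df_w), p=p_f)

    scores = np.arange(1, k + 1, dtype=float)
    c = scores - scores.mean()
    contrast = float(np.sum(c * means))
    se2 = ms_w * float(np.sum(c**2 / ns))
    if se2 == 0:
        trend = TestStat(statistic=0.0, df=(1, df_w), p=1.0)
    else:
        t = contrast / np.sqrt(se2)
        trend = TestStat(statistic=float(t), df=(1, df_w), p=float(2 * stats.t.sf(abs(t), df_w)))
    return anova, trend


@dataclass
class TestStat:
    statistic: float
    df: tuple
    p: float


def decision_curve(values, status, grid=None) -> DecisionCurve:
    """Sensitivity/specificity of a low-expression cut-off for resistance.

    sensitivity(c) = P(value < c | resistant) and specificity(c) =
    P(value >= c | sensitive). The grid defaults to all observed values
    plus midpoints. The crossover is the linearly interpolated point where
    sensitivity - specificity first changes sign along the ascending grid;
    extra sign changes (small-sample noise) are reported with a warning.
    """
    values = np.asarray(values, dtype=float)
    status = np.asarray(status, dtype=object)
    resistant = values[status == "resistant"]
    sensitive = values[status == "sensitive"]
    if resistant.size == 0 or sensitive.size == 0:
        raise ValueError("both resistant and sensitive classes must be non-empty")
    if grid is None:
        pts = np.unique(values)
        mids = (pts[:-1] + pts[1:]) / 2.0
        grid = np.sort(np.concatenate([pts, mids]))
    grid = np.asarray(grid, dtype=float)

    rs = np.sort(resistant)
    ss = np.sort(sensitive)
    sens = np.searchsorted(rs, grid, side="left") / rs.size
    spec = 1.0 - np.searchsorted(ss, grid, side="left") / ss.size

    diff = sens - spec
    cross_c = float("nan")
    cross_v = float("nan")
    changes = [i for i in range(len(diff) - 1) if diff[i] == 0 or diff[i] * diff[i + 1] < 0]
    if diff[-1] == 0:
        changes.append(len(diff) - 1)
    if changes:
        i = changes[0]
        if diff[i] == 0:
            cross_c, cross_v = float(grid[i]), float(sens[i])
        else:
            t = diff[i] / (diff[i] - diff[i + 1])
            cross_c = float(grid[i] + t * (grid[i + 1] - grid[i]))
            cross_v = float(sens[i] + t * (sens[i + 1] - sens[i]))
        if len(changes) > 1:
            logger.warning(
                "decision curve has %d sign changes; reporting the lowest cutoff",
                len(changes),
            )
    return DecisionCurve(
        cutoffs=grid,
        sensitivity=sens,
        specificity=spec,
        crossover_cutoff=cross_c,
        crossover_value=cross_v,
    )


def years_per_log2(bins: list[BinSummary]) -> float:
    """Survival years gained per log2 unit over the year bins.

    Least-squares line of bin-mean expression (y) on bin-midpoint year
    (x) over the non-empty completed-year bins; the reciprocal slope is
    the years of survival associated with one log2 unit of expression.
    NaN when fewer than two bins are populated or the slope vanishes.
    """
    xs, ys = [], []
    for b in bins:
        if b.label.startswith(">") or b.n == 0:
            continue
        xs.append(int(b.label) - 0.5)
        ys.append(b.mean)
    if len(xs) < 2:
        return float("nan")
    slope = np.polyfit(np.asarray(xs), np.asarray(ys), 1)[0]
    return float(1.0 / slope) if slope != 0 else float("nan")
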