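"""Expression-stability statistics: ENCAS filtering and PIRS ranking.

A candidate reference gene must (1) express above a cutoff, (2) not be
rhythmically regulated, and (3) show no significant time effect by one-way
ANOVA — the surviving genes form the ENCAS set ("expressing, noncircadian,
ANOVA selected").  ENCAS genes are then ranked by the prediction interval
ranking score (PIRS): ordinary least squares of log10 FPKM on time yields a
95% prediction interval at each distinct time point, and

    PIRS = sum_i ( |U_i - m| + |L_i - m| )

where (L_i, U_i) are the interval bounds at time point i and m is the gene's
overall mean log expression.  Flat, low-noise genes minimize the score.  An
independent SD/RSD ranking (SD of log values <= 0.5% of the mean) and a
Jaccard comparison of rankings are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .expression import SampleMeta, TimeCourseMatrix

__all__ = [
    "EncasFlags",
    "RegressionFit",
    "StabilityScore",
    "expression_filter",
    "anova_time",
    "fit_regression_pi",
    "pirs_score",
    "sd_rsd_rank",
    "cross_course_candidates",
    "jaccard_topk",
    "quintile_report",
    "DEFAULT_EXPRESSION_CUTOFF",
    "DEFAULT_ANOVA_ALPHA",
    "DEFAULT_PI_LEVEL",
    "DEFAULT_RSD_FRACTION",
]

DEFAULT_EXPRESSION_CUTOFF = -2.0  # mean log10 FPKM must exceed this
DEFAULT_ANOVA_ALPHA = 0.05
DEFAULT_PI_LEVEL = 0.95
DEFAULT_RSD_FRACTION = 0.005  # SD <= 0.5% of |mean log10 FPKM|


@dataclass
class EncasFlags:
    """Per-gene filter outcome; ``is_encas`` is the conjunction of the three."""

    gene_id: str
    passes_expression: bool
    passes_rhythm: bool  # True = not rhythmic
    passes_anova: bool  # True = no significant time effect

    @property
    def is_encas(self) -> bool:
        return self.passes_expression and self.passes_rhythm and self.passes_anova


@dataclass
class RegressionFit:
    """OLS fit of log expression on time, with what the prediction interval needs."""

    gene_id: str
    slope: float
    intercept: float
    s: float  # residual standard deviation
    n: int
    t_mean: float
    s_tt: float  # sum of squared time deviations
    pi_level: float = DEFAULT_PI_LEVEL


@dataclass
class StabilityScore:
    gene_id: str
    pirs: float
    mean_expr: float
    sd: float
    rsd: float | None
    bounds: list[tuple[float, float]] = field(default_factory=list)
    quintile: int | None = None


def expression_filter(
    m: TimeCourseMatrix, cutoff: float = DEFAULT_EXPRESSION_CUTOFF
) -> dict[str, bool]:
    """Expression cutoff: mean log10 FPKM across all samples strictly above ``cutoff``.

    Undefined (and an error) on a t0-normalized matrix, where absolute levels
    are gone.
    """
    if m.scale != "absolute":
        raise ValueError("expression filter undefined on a relative_to_t0 matrix")
    means = m.values.mean(axis=1)
    return {g: bool(mu > cutoff) for g, mu in zip(m.gene_ids, means)}


def anova_time(gene_row: Sequence[float], meta: Sequence[SampleMeta]) -> float:
    """One-way fixed-effects ANOVA p-value with time point as the factor.

    Within-time-point replicate variation is compared against between-time
    variation.  No multiple-testing adjustment is applied (the filter screens
    genes out, so an adjustment would only let more variable genes through).
    """
    x = np.asarray(gene_row, dtype=float)
    if x.size != len(meta):
        raise ValueError("gene_row and meta length mismatch")
    times = np.array([s.time for s in meta])
    groups = [x[times == t] for t in np.unique(times)]
    if len(groups) < 2:
        raise ValueError("need at least 2 distinct time points")
    if all(len(g) < 2 for g in groups):
        raise ValueError("no replication at any time point; within-group variance undefined")
    if np.ptp(x) == 0:
        return 1.0  # constant gene: no variance to partition
    res = stats.f_oneway(*groups)
    p = float(res.pvalue)
    return 1.0 if not np.isfinite(p) else p


def fit_regression_pi(
    gene_row: Sequence[float],
    meta: Sequence[SampleMeta],
    level: float = DEFAULT_PI_LEVEL,
    *,
    gene_id: str = "",
) -> RegressionFit:
    """Least-squares fit of log expression on time, for interval construction."""
    y = np.asarray(gene_row, dtype=float)
    t = np.array([s.time for s in meta], dtype=float)
    n = y.size
    if n != len(meta):
        raise ValueError("gene_row and meta length mismatch")
    if n < 3:
        raise ValueError("need at least 3 points (n - 2 >= 1 degrees of freedom)")
    t_mean = float(t.mean())
    s_tt = float(np.sum((t - t_mean) ** 2))
    if s_tt == 0:
        raise ValueError("need at least 2 distinct time points")
    slope = float(np.sum((t - t_mean) * (y - y.mean())) / s_tt)
    intercept = float(y.mean() - slope * t_mean)
    resid = y - (intercept + slope * t)
    s = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return RegressionFit(
        gene_id=gene_id,
        slope=slope,
        intercept=intercept,
        s=s,
        n=n,
        t_mean=t_mean,
        s_tt=s_tt,
        pi_level=level,
    )


def prediction_bounds(
    fit: RegressionFit, t_points: Sequence[float], *, interval: Literal["prediction", "confidence"] = "prediction"
) -> list[tuple[float, float]]:
    """Interval bounds at each time point for a fitted regression.

    ``prediction`` (default) is the interval for a new observation,
    ``y_hat +- t * s * sqrt(1 + 1/n + (t_i - t_bar)^2 / S_tt)``; the
    ``confidence`` variant drops the leading 1 (interval for the mean).
    """
    tcrit = stats.t.ppf((1 + fit.pi_level) / 2, fit.n - 2)
    extra = 1.0 if interval == "prediction" else 0.0
    out = []
    for ti in t_points:
        yhat = fit.intercept + fit.slope * ti
        half = tcrit * fit.s * np.sqrt(extra + 1 / fit.n + (ti - fit.t_mean) ** 2 / fit.s_tt)
        out.append((float(yhat - half), float(yhat + half)))
    return out


def pirs_score(
    fit: RegressionFit,
    gene_row: Sequence[float],
    meta: Sequence[SampleMeta],
    *,
    interval: Literal["prediction", "confidence"] = "prediction",
    formula: Literal["mean_deviation", "width"] = "mean_deviation",
) -> StabilityScore:
    """Prediction interval ranking score of one gene; lower = more stable.

    ``mean_deviation`` (default) sums |U_i - m| + |L_i - m| over distinct
    time points, m the overall mean log expression; the ``width`` variant
    sums the plain interval widths |U_i - L_i| instead.
    """
    y = np.asarray(gene_row, dtype=float)
    times = sorted(set(s.time for s in meta))
    bounds = prediction_bounds(fit, times, interval=interval)
    m_overall = float(y.mean())
    if formula == "mean_deviation":
        score = sum(abs(u - m_overall) + abs(lo - m_overall) for lo, u in bounds)
    else:
        score = sum(u - lo for lo, u in bounds)
    sd = float(y.std(ddof=1)) if y.size > 1 else 0.0
    rsd = sd / abs(m_overall) if m_overall != 0 else None
    return StabilityScore(
        gene_id=fit.gene_id,
        pirs=float(score),
        mean_expr=m_overall,
        sd=sd,
        rsd=rsd,
        bounds=bounds,
    )


def sd_rsd_rank(
    m: TimeCourseMatrix, fraction: float = DEFAULT_RSD_FRACTION
) -> dict[str, dict]:
    """SD/RSD stability summary per gene.

    A gene is an SD-method candidate when the SD of its log values is at most
    ``fraction`` (default 0.5%) of the absolute mean log value.  A zero mean
    leaves RSD undefined; the gene is flagged not-a-candidate with a reason.
    """
    if m.scale != "absolute":
        raise ValueError("SD/RSD ranking undefined on a relative_to_t0 matrix")
    out: dict[str, dict] = {}
    means = m.values.mean(axis=1)
    sds = m.values.std(axis=1, ddof=1)
    for g, mu, sd in zip(m.gene_ids, means, sds):
        if mu == 0:
            out[g] = {
                "sd": float(sd),
                "rsd": None,
                "candidate": False,
                "reason": "zero mean: RSD undefined",
            }
        else:
            out[g] = {
                "sd": float(sd),
                "rsd": float(sd / abs(mu)),
                "candidate": bool(sd <= fraction * abs(mu)),
                "reason": None,
            }
    return out


def cross_course_candidates(
    courses: Sequence[TimeCourseMatrix],
    averaged: TimeCourseMatrix,
    fraction: float = DEFAULT_RSD_FRACTION,
) -> list[str]:
    """SD-method consensus: candidate in the averaged course AND >= 1 individual course."""
    if not courses:
        raise ValueError("need at least one individual course")
    avg_flags = sd_rsd_rank(averaged, fraction)
    course_flags = [sd_rsd_rank(c, fraction) for c in courses]
    out = []
    for g in averaged.gene_ids:
        if not avg_flags[g]["candidate"]:
            continue
        if any(f.get(g, {}).get("candidate") for f in course_flags):
            out.append(g)
    return out


def jaccard_topk(rank_a: Sequence[str], rank_b: Sequence[str], k: int) -> float:
    """Jaccard similarity of the top-k elements of two rankings."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(len(rank_a), len(rank_b)):
        raise ValueError("k exceeds a ranking length")
    a, b = set(rank_a[:k]), set(rank_b[:k])
    return len(a & b) / len(a | b)


def quintile_report(
    scores: Sequence[StabilityScore], per_quintile: int = 2
) -> list[str]:
    """Top reference candidates per expression quintile.

    Genes are split into 5 equal-frequency bins by mean expression; within
    each bin the ``per_quintile`` lowest-PIRS genes are reported, so the
    candidates span the expression range.  Ties break by gene ID.
    """
    if len(scores) < 5:
        raise ValueError("need at least 5 genes to form quintiles")
    order = sorted(scores, key=lambda s: (s.mean_expr, s.gene_id))
    n = len(order)
    # equal-frequency bin edges: bin i gets genes [i*n//5, (i+1)*n//5)
    out: list[str] = []
    for i in range(5):
        lo, hi = i * n // 5, (i + 1) * n // 5
        binned = order[lo:hi]
        for s in binned:
            s.quintile = i + 1
        best = sorted(binned, key=lambda s: (s.pirs, s.gene_id))[:per_quintile]
        out.extend(s.gene_id for s in best)
    return out
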