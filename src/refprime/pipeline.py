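"""End-to-end reference-gene selection.

Per dataset: expression cutoff -> rhythmicity rejection -> per-gene ANOVA
(the ENCAS chain) -> PIRS scoring of the survivors.  Stages that need
structure the dataset lacks are skipped and logged: the rhythm test and the
ANOVA need replicates, and the expression filter, SD/RSD ranking and
expression quintiles need absolute (not t0-normalized) values.  Across
datasets, per-gene PIRS vectors feed the pareto/summed-normalized consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import MultiScore, normalize_and_sum, select_candidates
from .expression import TimeCourseMatrix
from .rhythm import DEFAULT_ALPHA, RhythmResult, jtk_scan
from .stability import (
    DEFAULT_ANOVA_ALPHA,
    DEFAULT_EXPRESSION_CUTOFF,
    DEFAULT_PI_LEVEL,
    StabilityScore,
    anova_time,
    expression_filter,
    fit_regression_pi,
    pirs_score,
    quintile_report,
)

__all__ = ["RefGeneConfig", "stability_report", "refgenes_workflow"]

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "gene_id",
    "mean_expr",
    "pirs",
    "sd",
    "rsd",
    "passes_expression",
    "passes_rhythm",
    "passes_anova",
    "is_encas",
    "quintile",
    "pirs_rank",
]


@dataclass
class RefGeneConfig:
    expression_cutoff: float = DEFAULT_EXPRESSION_CUTOFF
    rhythm_alpha: float = DEFAULT_ALPHA
    anova_alpha: float = DEFAULT_ANOVA_ALPHA
    pi_level: float = DEFAULT_PI_LEVEL
    periods: tuple[float, ...] = (22.0,)
    top_n: int = 10
    per_quintile: int = 2
    run_rhythm_test: bool = True  # False when precomputed calls are supplied
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "expression_cutoff": self.expression_cutoff,
            "rhythm_alpha": self.rhythm_alpha,
            "anova_alpha": self.anova_alpha,
            "pi_level": self.pi_level,
            "periods": list(self.periods),
            "top_n": self.top_n,
            "per_quintile": self.per_quintile,
            "run_rhythm_test": self.run_rhythm_test,
            "seed": self.seed,
        }


def _has_replicates(m: TimeCourseMatrix) -> bool:
    per_time: dict[tuple[str, float], int] = {}
    for s in m.samples:
        key = (s.course_id, s.time)
        per_time[key] = per_time.get(key, 0) + 1
    return any(v >= 2 for v in per_time.values())


def stability_report(
    m: TimeCourseMatrix,
    config: RefGeneConfig | None = None,
    rhythm_calls: Sequence[RhythmResult] | None = None,
) -> tuple[pd.DataFrame, list[StabilityScore]]:
    """ENCAS filtering + PIRS scoring of one dataset.

    Returns the per-gene report (one row per gene) and the
    :class:`StabilityScore` objects of the genes that were scored.
    Precomputed rhythm calls, when given, replace the built-in test.
    """
    config = config or RefGeneConfig()
    absolute = m.scale == "absolute"
    replicated = _has_replicates(m)

    if absolute:
        expr_pass = expression_filter(m, config.expression_cutoff)
    else:
        log.info("relative-scale dataset: expression cutoff skipped")
        expr_pass = {g: True for g in m.gene_ids}

    if rhythm_calls is not None:
        by_gene = {r.gene_id: r for r in rhythm_calls}
        rhythm_pass = {g: not by_gene[g].is_rhythmic if g in by_gene else True for g in m.gene_ids}
    elif replicated and config.run_rhythm_test:
        results = jtk_scan(m, config.periods, config.rhythm_alpha, rng=config.seed)
        rhythm_pass = {r.gene_id: not r.is_rhythmic for r in results}
    else:
        if not replicated:
            log.info("un-replicated dataset: rhythm test skipped")
        rhythm_pass = {g: True for g in m.gene_ids}

    anova_pass: dict[str, bool] = {}
    if replicated:
        for i, g in enumerate(m.gene_ids):
            p = anova_time(m.values[i], m.samples)
            anova_pass[g] = p >= config.anova_alpha
    else:
        log.info("un-replicated dataset: ANOVA skipped")
        anova_pass = {g: True for g in m.gene_ids}

    scores: list[StabilityScore] = []
    rows = []
    for i, g in enumerate(m.gene_ids):
        fit = fit_regression_pi(m.values[i], m.samples, config.pi_level, gene_id=g)
        score = pirs_score(fit, m.values[i], m.samples)
        scores.append(score)
        rows.append(
            {
                "gene_id": g,
                "mean_expr": score.mean_expr,
                "pirs": score.pirs,
                "sd": score.sd,
                "rsd": score.rsd,
                "passes_expression": expr_pass[g],
                "passes_rhythm": rhythm_pass[g],
                "passes_anova": anova_pass[g],
                "is_encas": expr_pass[g] and rhythm_pass[g] and anova_pass[g],
                "quintile": None,
                "pirs_rank": None,
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    encas_scores = [s for s, r in zip(scores, rows) if r["is_encas"]]
    if absolute and len(encas_scores) >= 5:
        quintile_report(encas_scores, config.per_quintile)  # assigns quintiles in place
        qmap = {s.gene_id: s.quintile for s in encas_scores}
        df["quintile"] = df["gene_id"].map(qmap).astype("Int64")
    ranked = sorted(encas_scores, key=lambda s: (s.pirs, s.gene_id))
    rank_map = {s.gene_id: k + 1 for k, s in enumerate(ranked)}
    df["pirs_rank"] = df["gene_id"].map(rank_map).astype("Int64")
    return df, scores


def pooled_matrix(matrices: Mapping[str, TimeCourseMatrix]) -> TimeCourseMatrix:
    """Concatenate same-protocol courses into one matrix for a single screen.

    Samples keep their (course, time, replicate) identity; the ANOVA then
    groups by time with the courses acting as additional replicates, and the
    rhythm test sees all courses against shared references.
    """
    mats = list(matrices.values())
    genes = mats[0].gene_ids
    for m in mats[1:]:
        if m.gene_ids != genes:
            raise ValueError("courses must share an identical gene list to be pooled")
        if m.scale != mats[0].scale:
            raise ValueError("cannot pool matrices on different scales")
    samples = [s for m in mats for s in m.samples]
    values = np.concatenate([m.values for m in mats], axis=1)
    return TimeCourseMatrix(list(genes), samples, values, scale=mats[0].scale)


def refgenes_workflow(
    matrices: Mapping[str, TimeCourseMatrix],
    config: RefGeneConfig | None = None,
    rhythm_calls: Mapping[str, Sequence[RhythmResult]] | None = None,
    *,
    screen: str = "per-dataset",
) -> dict:
    """Run the full selection over several datasets.

    Returns a dict with per-dataset reports, per-dataset quintile picks
    (absolute-scale datasets only), the consensus table, and the final
    candidate list (top-n summed-normalized PIRS intersected with the
    pareto front, over genes that are ENCAS in every dataset).

    ``screen="pooled"`` runs the ENCAS filter chain once on the pooled
    courses (the courses acting as replicates of a single design) and
    applies the resulting gene set everywhere — the single-screen workflow;
    it requires all datasets to share a gene list and scale.  The default
    screens each dataset independently and intersects.
    """
    config = config or RefGeneConfig()
    if not matrices:
        raise ValueError("need at least one dataset")
    reports: dict[str, pd.DataFrame] = {}
    scores: dict[str, dict[str, float]] = {}
    encas_sets: dict[str, set[str]] = {}
    quintile_picks: dict[str, list[str]] = {}
    pooled_encas: set[str] | None = None
    if screen == "pooled":
        pooled = pooled_matrix(matrices)
        pooled_df, _ = stability_report(pooled, config, None)
        pooled_encas = set(pooled_df.loc[pooled_df.is_encas, "gene_id"])
    for name, m in matrices.items():
        calls = rhythm_calls.get(name) if rhythm_calls else None
        df, score_list = stability_report(m, config, calls)
        if pooled_encas is not None:
            df["is_encas"] = df["gene_id"].isin(pooled_encas)
        reports[name] = df
        encas_sets[name] = set(df.loc[df.is_encas, "gene_id"])
        for s in score_list:
            scores.setdefault(s.gene_id, {})[name] = s.pirs
        encas_scores = [s for s in score_list if s.gene_id in encas_sets[name]]
        if pooled_encas is not None:
            # rank/quintile columns must reflect the pooled screen
            ranked = sorted(encas_scores, key=lambda s: (s.pirs, s.gene_id))
            rank_map = {s.gene_id: k + 1 for k, s in enumerate(ranked)}
            df["pirs_rank"] = df["gene_id"].map(rank_map).astype("Int64")
            df["quintile"] = None
        if m.scale == "absolute" and len(encas_scores) >= 5:
            quintile_picks[name] = quintile_report(encas_scores, config.per_quintile)
            if pooled_encas is not None:
                qmap = {s.gene_id: s.quintile for s in encas_scores}
                df["quintile"] = df["gene_id"].map(qmap).astype("Int64")
        else:
            top = sorted(encas_scores, key=lambda s: (s.pirs, s.gene_id))[: config.top_n]
            quintile_picks[name] = [s.gene_id for s in top]
            log.info(
                "dataset %s: quintiles unavailable, reporting top %d overall",
                name,
                config.top_n,
            )

    shared_encas = set.intersection(*encas_sets.values())
    eligible = {g: v for g, v in scores.items() if g in shared_encas and len(v) == len(matrices)}
    if len(eligible) >= 2:
        multi = normalize_and_sum(eligible)
        candidates = select_candidates(multi, config.top_n)
    else:
        log.warning("fewer than 2 genes are ENCAS in every dataset; no consensus")
        multi = []
        candidates = sorted(eligible)
    consensus_rows = []
    for ms in sorted(multi, key=lambda s: (s.summed, s.gene_id)):
        row = {"gene_id": ms.gene_id}
        for d in matrices:
            row[f"pirs_{d}"] = ms.scores[d]
            row[f"norm_{d}"] = ms.normalized[d]
        row["summed"] = ms.summed
        row["on_pareto_front"] = ms.on_pareto_front
        row["selected"] = ms.gene_id in candidates
        consensus_rows.append(row)
    return {
        "reports": reports,
        "quintile_picks": quintile_picks,
        "consensus": pd.DataFrame(consensus_rows),
        "candidates": candidates,
        "config": config.to_dict(),
    }
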