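"""Multi-dataset consensus of stability scores.

A gene that looks stable in one time course may drift in another, so final
reference candidates are the genes that are (a) pareto-nondominated across
the per-dataset PIRS vectors — no other gene scores at least as well in
every dataset and strictly better in one — and (b) among the best summed
min-max-normalized scores.  The reported candidate list is the intersection
of the pareto front with the top-n summed-normalized genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = ["MultiScore", "pareto_front", "normalize_and_sum", "select_candidates"]

log = logging.getLogger(__name__)

DEFAULT_TOP_N = 10


@dataclass
class MultiScore:
    gene_id: str
    scores: dict[str, float]
    normalized: dict[str, float] = field(default_factory=dict)
    summed: float = 0.0
    on_pareto_front: bool = False


def pareto_front(scores: Mapping[str, Sequence[float]]) -> dict[str, bool]:
    """Nondominated flag per gene, minimizing every coordinate.

    A gene is dominated when some other gene is <= in all coordinates and
    < in at least one; the front is every gene not dominated.  Input order
    is preserved in the output mapping.
    """
    genes = list(scores)
    if not genes:
        return {}
    mat = np.array([scores[g] for g in genes], dtype=float)
    if mat.ndim != 2:
        raise ValueError("all genes must carry the same number of dataset scores")
    n = len(genes)
    on_front = np.ones(n, dtype=bool)
    # sort by first coordinate so dominators appear early; still O(n^2) worst case
    order = np.lexsort(mat.T[::-1])
    for pos, i in enumerate(order):
        if not on_front[i]:
            continue
        mi = mat[i]
        for j in order[:pos]:
            if not on_front[j]:
                continue
            mj = mat[j]
            if np.all(mj <= mi) and np.any(mj < mi):
                on_front[i] = False
                break
    return {g: bool(on_front[k]) for k, g in enumerate(genes)}


def normalize_and_sum(
    scores: Mapping[str, Mapping[str, float]],
    *,
    scheme: Literal["minmax", "zscore"] = "minmax",
) -> list[MultiScore]:
    """Min-max normalize PIRS per dataset and sum across datasets.

    ``scores`` maps gene_id -> {dataset_id -> PIRS}.  Genes missing any
    dataset are excluded (dominance and sums are undefined on missing
    coordinates) and logged.  A dataset with zero spread normalizes to all
    zeros with a warning.  Lower summed score = more stable overall.
    """
    datasets = sorted({d for per_gene in scores.values() for d in per_gene})
    complete = {
        g: per_gene for g, per_gene in scores.items() if set(per_gene) >= set(datasets)
    }
    dropped = sorted(set(scores) - set(complete))
    if dropped:
        log.info("excluded %d genes unscored in some dataset: %s", len(dropped), dropped[:10])
    if len(complete) < 2:
        raise ValueError("need at least 2 genes scored in every dataset")
    genes = list(complete)
    out = [MultiScore(gene_id=g, scores=dict(complete[g])) for g in genes]
    for d in datasets:
        vals = np.array([complete[g][d] for g in genes], dtype=float)
        if scheme == "minmax":
            span = vals.max() - vals.min()
            if span == 0:
                log.warning("dataset %s has zero PIRS spread; normalized to 0", d)
                norm = np.zeros_like(vals)
            else:
                norm = (vals - vals.min()) / span
        else:
            sd = vals.std(ddof=0)
            norm = np.zeros_like(vals) if sd == 0 else (vals - vals.mean()) / sd
        for ms, v in zip(out, norm):
            ms.normalized[d] = float(v)
    front = pareto_front({g: [complete[g][d] for d in datasets] for g in genes})
    for ms in out:
        ms.summed = float(sum(ms.normalized.values()))
        ms.on_pareto_front = front[ms.gene_id]
    return out


def select_candidates(ms: Sequence[MultiScore], top_n: int = DEFAULT_TOP_N) -> list[str]:
    """Final candidates: top-n by summed normalized score, intersected with the front.

    Deterministic: ties in the summed score break by gene ID; the returned
    list is ordered by (summed, gene_id).
    """
    ranked = sorted(ms, key=lambda s: (s.summed, s.gene_id))
    top = ranked[:top_n]
    selected = [s.gene_id for s in top if s.on_pareto_front]
    if not selected:
        log.warning("pareto front and top-%d summed scores do not overlap", top_n)
    return selected
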