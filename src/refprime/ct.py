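"""Ct-table processing for primer validation runs.

A quantification cycle (Ct) below 30 on at least one primer pair counts a
cDNA target as reliably detected.  Per-gene summaries average all readable
Ct values and report an SD only when three or more values are readable.
"Unreadable" (no amplification) is an explicit flag, never a sentinel
number.  A replicate-outlier rule on the linear relative-expression scale
drops a single replicate that differs from both others by more than
three-fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import PrimerPair

__all__ = [
    "CtObservation",
    "CtTable",
    "GeneCtSummary",
    "replicate_filter",
    "summarize_gene",
    "penalty_detection_summary",
    "ct_to_relative",
    "DETECT_THRESHOLD_DEFAULT",
]

log = logging.getLogger(__name__)

DETECT_THRESHOLD_DEFAULT = 30.0
FOLD_LIMIT = 3.0


@dataclass(frozen=True)
class CtObservation:
    gene_id: str
    primer_rank: int
    replicate: int
    ct: float | None  # None = unreadable (no amplification)

    def __post_init__(self) -> None:
        if self.ct is not None and not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(
                f"{self.gene_id} pair {self.primer_rank} rep {self.replicate}: "
                f"readable Ct must be finite and > 0, got {self.ct}"
            )


@dataclass
class CtTable:
    rows: list[CtObservation]

    def __post_init__(self) -> None:
        keys = [(r.gene_id, r.primer_rank, r.replicate) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (gene_id, primer_rank, replicate) in Ct table")

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.gene_id, None)
        return list(seen)

    def for_gene(self, gene_id: str) -> list[CtObservation]:
        out = [r for r in self.rows if r.gene_id == gene_id]
        if not out:
            raise KeyError(f"gene {gene_id!r} not in Ct table")
        return out

    @classmethod
    def read(cls, path: Path | str) -> "CtTable":
        """TSV with columns gene_id, primer_rank, replicate, ct (empty = unreadable)."""
        df = pd.read_csv(path, sep="\t")
        for col in ("gene_id", "primer_rank", "replicate", "ct"):
            if col not in df.columns:
                raise ValueError(f"Ct table missing column {col!r}")
        rows = [
            CtObservation(
                gene_id=str(r.gene_id),
                primer_rank=int(r.primer_rank),
                replicate=int(r.replicate),
                ct=None if pd.isna(r.ct) else float(r.ct),
            )
            for r in df.itertuples()
        ]
        return cls(rows)

    def write(self, path: Path | str) -> None:
        pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.rows],
                "primer_rank": [r.primer_rank for r in self.rows],
                "replicate": [r.replicate for r in self.rows],
                "ct": [r.ct if r.ct is not None else np.nan for r in self.rows],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GeneCtSummary:
    gene_id: str
    mean_ct: float | None
    sd_ct: float | None  # present only when >= 3 readable values
    n_readable: int
    detected: bool
    per_pair_ct: dict[int, float] = field(default_factory=dict)


def replicate_filter(values: Sequence[float]) -> list[float]:
    """Drop a single >3-fold outlier from a triple of relative-expression values.

    If exactly one value differs from BOTH others by more than three-fold
    (ratio > 3 or < 1/3) it is removed; any other pattern retains all three.
    Values are linear-scale relative levels and must be positive.
    """
    vals = list(values)
    if len(vals) != 3:
        raise ValueError("replicate filter is defined on triples")
    if any(v <= 0 for v in vals):
        raise ValueError("fold change undefined for non-positive values")

    def far(a: float, b: float) -> bool:
        r = a / b
        return r > FOLD_LIMIT or r < 1.0 / FOLD_LIMIT

    outliers = [
        i
        for i in range(3)
        if all(far(vals[i], vals[j]) for j in range(3) if j != i)
    ]
    if len(outliers) == 1:
        return [v for i, v in enumerate(vals) if i != outliers[0]]
    return vals


def ct_to_relative(ct: float, ct_reference: float) -> float:
    """Relative expression level 2**(-(ct - ct_reference)).

    Convenience for applying :func:`replicate_filter` to Ct readouts; the
    fold-change rule itself operates on the linear scale.
    """
    return 2.0 ** (-(ct - ct_reference))


def summarize_gene(
    t: CtTable, gene: str, detect_threshold: float = DETECT_THRESHOLD_DEFAULT
) -> GeneCtSummary:
    """Per-gene Ct summary under the any-pair, strict ``ct < threshold`` rule."""
    obs = t.for_gene(gene)
    readable = [r for r in obs if r.ct is not None]
    cts = [r.ct for r in readable if r.ct is not None]
    mean_ct = float(np.mean(cts)) if cts else None
    sd_ct = float(np.std(cts, ddof=1)) if len(cts) >= 3 else None
    per_pair: dict[int, float] = {}
    for r in readable:
        assert r.ct is not None
        # replicate-mean per pair, built incrementally
        per_pair.setdefault(r.primer_rank, 0.0)
    for rank in per_pair:
        vals = [r.ct for r in readable if r.primer_rank == rank and r.ct is not None]
        per_pair[rank] = float(np.mean(vals))
    detected = any(ct < detect_threshold for ct in cts)
    return GeneCtSummary(
        gene_id=gene,
        mean_ct=mean_ct,
        sd_ct=sd_ct,
        n_readable=len(cts),
        detected=detected,
        per_pair_ct=per_pair,
    )


def penalty_detection_summary(
    summaries: Sequence[GeneCtSummary], catalog: Sequence[PrimerPair]
) -> tuple[float | None, float | None]:
    """Mean engine pair penalty of tested pairs, split by gene detection status.

    Returns ``(mean_penalty_detected, mean_penalty_undetected)``; an empty
    group yields ``None`` with a warning.  Only pairs that were actually
    tested (present in a gene's summary) contribute.
    """
    by_key = {(p.gene_id, p.rank): p.pair_penalty for p in catalog}
    det: list[float] = []
    undet: list[float] = []
    for s in summaries:
        for rank in s.per_pair_ct:
            key = (s.gene_id, rank)
            if key not in by_key:
                raise KeyError(f"pair {key} missing from catalog")
            (det if s.detected else undet).append(by_key[key])
    mean_det = float(np.mean(det)) if det else None
    mean_undet = float(np.mean(undet)) if undet else None
    if mean_det is None:
        log.warning("no detected genes; detected-group penalty mean absent")
    if mean_undet is None:
        log.warning("no undetected genes; undetected-group penalty mean absent")
    return mean_det, mean_undet
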