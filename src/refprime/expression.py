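"""Expression time-course matrices and their sample metadata.

The substrate of every stability statistic downstream is a genes x samples
matrix of log10(FPKM) values together with per-sample annotations: the
sampling time in hours, the biological replicate index, and a course
identifier (e.g. one of several circadian courses, or an induction series).
Raw FPKM input is log10-transformed on load; zero FPKM is mapped to a
configurable floor that sits below any sensible expression cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "TimeCourseMatrix",
    "MatrixParseError",
    "log_transform",
    "read_matrix",
    "write_matrix",
    "normalize_to_t0",
    "DEFAULT_LOG_FLOOR",
]

#: substitute for log10(0); below the -2 expression cutoff so that
#: non-detected genes always fail the expression filter
DEFAULT_LOG_FLOOR = -4.0


class MatrixParseError(ValueError):
    """Structured parse/validation failure naming the offending row or column."""


@dataclass(frozen=True)
class SampleMeta:
    """Annotation of a single sample column.

    Attributes
    ----------
    sample_id : unique column identifier
    time : sampling time in hours (>= 0)
    replicate : biological replicate index (>= 1)
    course_id : which time course the sample belongs to
    """

    sample_id: str
    time: float
    replicate: int
    course_id: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"sample {self.sample_id!r}: time must be >= 0, got {self.time}")
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be >= 1, got {self.replicate}"
            )


@dataclass
class TimeCourseMatrix:
    """Genes x samples matrix of log10-FPKM values with sample metadata.

    ``scale`` records whether values are absolute log10 FPKM or were
    normalized to the earliest time point of each course (every gene then
    has value 0 at t0 on the log scale).
    """

    gene_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    scale: Literal["absolute", "relative_to_t0"] = "absolute"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise MatrixParseError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise MatrixParseError(f"duplicate gene ID {dup!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise MatrixParseError("duplicate sample_id in metadata")
        triples = [(s.course_id, s.time, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise MatrixParseError("duplicate (course_id, time, replicate) triple in metadata")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples], dtype=float)

    @property
    def course_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.course_id, None)
        return list(seen)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None
        return self.values[i]

    def subset_course(self, course_id: str) -> "TimeCourseMatrix":
        """Restrict to the samples of one course."""
        idx = [i for i, s in enumerate(self.samples) if s.course_id == course_id]
        if not idx:
            raise KeyError(f"course {course_id!r} not present")
        return TimeCourseMatrix(
            gene_ids=list(self.gene_ids),
            samples=[self.samples[i] for i in idx],
            values=self.values[:, idx].copy(),
            scale=self.scale,
        )


def log_transform(fpkm: float, floor: float = DEFAULT_LOG_FLOOR) -> float:
    """log10 of an FPKM value; zero maps to ``floor``, negatives are an error."""
    if fpkm < 0:
        raise ValueError(f"FPKM must be non-negative, got {fpkm}")
    if fpkm == 0:
        return float(floor)
    return math.log10(fpkm)


def _log_transform_array(values: np.ndarray, floor: float) -> np.ndarray:
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise MatrixParseError(f"negative FPKM at row {i}, column {j}")
    out = np.full_like(values, float(floor), dtype=float)
    pos = values > 0
    out[pos] = np.log10(values[pos])
    return out


def _read_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_matrix(
    matrix_path: Path | str,
    meta_path: Path | str,
    *,
    already_log: bool = False,
    floor: float = DEFAULT_LOG_FLOOR,
    scale: Literal["absolute", "relative_to_t0"] = "absolute",
) -> TimeCourseMatrix:
    """Load an expression matrix and its sample metadata.

    The matrix is gene-per-row: first column gene ID, header row of sample
    IDs; tab-delimited by default, comma for ``.csv``. Metadata columns:
    ``sample_id, time, replicate, course_id``. Raw FPKM is log10-transformed
    unless ``already_log`` declares the file log-scaled.
    """
    mat = _read_table(matrix_path)
    meta = _read_table(meta_path)
    for col in ("sample_id", "time", "replicate", "course_id"):
        if col not in meta.columns:
            raise MatrixParseError(f"metadata missing column {col!r}")
    meta_by_id = {
        str(r.sample_id): SampleMeta(
            sample_id=str(r.sample_id),
            time=float(r.time),
            replicate=int(r.replicate),
            course_id=str(r.course_id),
        )
        for r in meta.itertuples()
    }
    gene_col = mat.columns[0]
    sample_cols = list(mat.columns[1:])
    missing = [c for c in sample_cols if c not in meta_by_id]
    if missing:
        raise MatrixParseError(f"sample column {missing[0]!r} absent from metadata")
    gene_ids = [str(g) for g in mat[gene_col]]
    values = mat[sample_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise MatrixParseError(
            f"non-finite value for gene {gene_ids[i]!r}, column {sample_cols[j]!r}"
        )
    if not already_log:
        values = _log_transform_array(values, floor)
    return TimeCourseMatrix(
        gene_ids=gene_ids,
        samples=[meta_by_id[c] for c in sample_cols],
        values=values,
        scale=scale,
    )


def write_matrix(m: TimeCourseMatrix, matrix_path: Path | str, meta_path: Path | str) -> None:
    """Write a matrix and metadata back in the dialect :func:`read_matrix` reads.

    Values are written on the log scale, so the round trip uses
    ``already_log=True``.
    """
    sep_for = lambda p: "," if Path(p).suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(m.values, columns=[s.sample_id for s in m.samples])
    df.insert(0, "gene_id", m.gene_ids)
    df.to_csv(matrix_path, sep=sep_for(matrix_path), index=False)
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in m.samples],
            "time": [s.time for s in m.samples],
            "replicate": [s.replicate for s in m.samples],
            "course_id": [s.course_id for s in m.samples],
        }
    )
    meta.to_csv(meta_path, sep=sep_for(meta_path), index=False)


def normalize_to_t0(m: TimeCourseMatrix) -> TimeCourseMatrix:
    """Normalize each gene to its earliest time point, per course.

    On the log scale this subtracts the (replicate-mean) value at the
    earliest time point of each course from every sample of that course, the
    construction used for induction series where only relative expression is
    meaningful. Requires an absolute-scale matrix.
    """
    if m.scale != "absolute":
        raise ValueError("matrix is already on the relative_to_t0 scale")
    values = m.values.copy()
    for course in m.course_ids:
        idx = [i for i, s in enumerate(m.samples) if s.course_id == course]
        t0 = min(m.samples[i].time for i in idx)
        t0_idx = [i for i in idx if m.samples[i].time == t0]
        if not t0_idx:  # pragma: no cover - t0 is derived from idx
            raise ValueError(f"course {course!r} has no earliest-time sample")
        baseline = values[:, t0_idx].mean(axis=1)
        values[:, idx] -= baseline[:, None]
    return TimeCourseMatrix(
        gene_ids=list(m.gene_ids),
        samples=list(m.samples),
        values=values,
        scale="relative_to_t0",
    )
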