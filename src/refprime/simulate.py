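"""Seeded synthetic inputs with the statistical structure the analyses assume.

Three generators cover every input the toolkit consumes:

* :func:`simulate_expression` — replicated circadian time courses (plus
  optional un-replicated induction-style series) of log10-FPKM values with
  planted gene classes: flat genes, cosine cyclers, linear trenders, and
  low-expressed genes below the detection cutoff.  Ground-truth class labels
  ride along.
* :func:`simulate_genome` — a small genome FASTA + GFF3 with genes of each
  exon class (no introns / one / several) on both strands, constructed with
  moderate GC and no long homopolymers so that ordinary primer design
  succeeds.
* :func:`simulate_ct` — a Ct table for a primer catalog in which Ct tracks
  log expression with slope log2(10) cycles per decade and the dropout
  probability rises with pair penalty and with high Ct.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import PrimerPair
from .ct import CtObservation, CtTable
from .expression import SampleMeta, TimeCourseMatrix

__all__ = [
    "ExpressionSimSpec",
    "GenomeSimSpec",
    "CtSimSpec",
    "simulate_expression",
    "simulate_genome",
    "simulate_ct",
]

GENE_CLASSES = ("flat", "cycler", "trender", "low_expressed")


@dataclass
class ExpressionSimSpec:
    """Study design of a simulated expression experiment.

    Defaults mirror a replicated 2-day circadian sampling: 0-44 h every 2 h,
    two replicates, three courses, a 22 h period, log10-FPKM baselines
    spread over three decades.
    """

    n_genes: int = 200
    time_points: tuple[float, ...] = tuple(float(t) for t in range(0, 45, 2))
    replicates: int = 2
    courses: tuple[str, ...] = ("c1", "c2", "c3")
    proportions: dict[str, float] = field(
        default_factory=lambda: {
            "flat": 0.3,
            "cycler": 0.4,
            "trender": 0.2,
            "low_expressed": 0.1,
        }
    )
    base_expr_range: tuple[float, float] = (0.0, 3.0)
    flat_sigma: float = 0.05
    cycler_period: float = 22.0
    cycler_amplitude: float = 0.5
    cycler_sigma: float = 0.1
    trender_slope: float = 0.02  # log10 FPKM per hour
    trender_sigma: float = 0.1
    low_expr_mean: float = -3.0
    low_expr_sigma: float = 0.1
    seed: int = 0
    #: optional (n_flat, n_courses) noise SDs for the flat genes; lets a
    #: planted design give each flat gene a distinct per-course noise profile
    flat_sigma_per_course: np.ndarray | None = None

    def validate(self) -> None:
        if not self.time_points:
            raise ValueError("empty time grid")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if set(self.proportions) - set(GENE_CLASSES):
            raise ValueError(f"unknown gene class in {set(self.proportions)}")


def _class_counts(spec: ExpressionSimSpec) -> dict[str, int]:
    counts = {c: int(round(spec.proportions.get(c, 0.0) * spec.n_genes)) for c in GENE_CLASSES}
    # fix rounding drift on the largest class
    drift = spec.n_genes - sum(counts.values())
    largest = max(counts, key=lambda c: counts[c])
    counts[largest] += drift
    return counts


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[dict[str, TimeCourseMatrix], pd.DataFrame]:
    """Generate one matrix per course plus a ground-truth table.

    Values are base + class signal + Gaussian noise on the log10 scale; the
    signal (baseline, cycler phase, trend) is shared across courses while
    noise is drawn independently per course.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    classes: list[str] = []
    for c in GENE_CLASSES:
        classes.extend([c] * counts[c])
    n = spec.n_genes
    width = len(str(n))
    gene_ids = [f"gene{str(i + 1).zfill(width)}" for i in range(n)]

    base = rng.uniform(*spec.base_expr_range, size=n)
    base[np.array(classes) == "low_expressed"] = spec.low_expr_mean
    phase = rng.uniform(0, spec.cycler_period, size=n)
    sigma = np.empty(n)
    flat_idx = [i for i, c in enumerate(classes) if c == "flat"]
    for i, c in enumerate(classes):
        sigma[i] = {
            "flat": spec.flat_sigma,
            "cycler": spec.cycler_sigma,
            "trender": spec.trender_sigma,
            "low_expressed": spec.low_expr_sigma,
        }[c]

    samples_per_course: dict[str, list[SampleMeta]] = {}
    for course in spec.courses:
        samples_per_course[course] = [
            SampleMeta(
                sample_id=f"{course}_t{t:g}_r{r}",
                time=t,
                replicate=r,
                course_id=course,
            )
            for t in spec.time_points
            for r in range(1, spec.replicates + 1)
        ]

    matrices: dict[str, TimeCourseMatrix] = {}
    for ci, course in enumerate(spec.courses):
        samples = samples_per_course[course]
        t = np.array([s.time for s in samples])
        values = np.empty((n, len(samples)))
        for i, c in enumerate(classes):
            signal = np.full(t.size, base[i])
            if c == "cycler":
                signal = signal + spec.cycler_amplitude * np.cos(
                    2 * np.pi * (t - phase[i]) / spec.cycler_period
                )
            elif c == "trender":
                signal = signal + spec.trender_slope * (t - t.mean())
            sd = sigma[i]
            if c == "flat" and spec.flat_sigma_per_course is not None:
                sd = float(spec.flat_sigma_per_course[flat_idx.index(i), ci])
            values[i] = signal + (rng.normal(0.0, sd, size=t.size) if sd > 0 else 0.0)
        matrices[course] = TimeCourseMatrix(
            gene_ids=list(gene_ids), samples=samples, values=values, scale="absolute"
        )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": classes,
            "base_expr": base,
            "phase": phase,
            "sigma": sigma,
        }
    )
    return matrices, truth


def planted_reference_spec(
    n_genes: int = 200, n_flat: int = 10, seed: int = 0
) -> ExpressionSimSpec:
    """A recovery benchmark: planted near-constant genes among cyclers/trenders.

    The planted flat genes get tiny per-course noise SDs in opposed orders
    (ascending in course 1, descending in course 2) so that each is
    pareto-nondominated across courses by construction, while every non-flat
    gene carries effects an order of magnitude larger.  The ideal selection
    therefore recovers exactly the planted set.
    """
    frac = n_flat / n_genes
    rest = 1.0 - frac
    sig_up = 0.004 * 1.35 ** np.arange(n_flat)
    sigma = np.stack([sig_up, sig_up[::-1], np.full(n_flat, 0.01)], axis=1)
    return ExpressionSimSpec(
        n_genes=n_genes,
        proportions={
            "flat": frac,
            "cycler": rest * (0.55 / 0.95),
            "trender": rest * (0.30 / 0.95),
            "low_expressed": rest * (0.10 / 0.95),
        },
        flat_sigma_per_course=sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


@dataclass
class GenomeSimSpec:
    """Design of a small synthetic genome for catalog testing."""

    n_genes: int = 50
    #: probabilities of 1, 2, and >= 3 exons
    exon_class_probs: tuple[float, float, float] = (0.34, 0.33, 0.33)
    mono_exon_len: tuple[int, int] = (700, 2400)
    exon_len: tuple[int, int] = (150, 700)
    intron_len: tuple[int, int] = (60, 200)
    max_exons: int = 4
    gc_fraction: float = 0.5
    max_homopolymer: int = 6
    intergenic: int = 200
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.exon_class_probs) - 1.0) > 1e-9:
            raise ValueError("exon class probabilities must sum to 1")
        if self.exon_len[0] < 40 or self.mono_exon_len[0] < 300:
            raise ValueError("exons too short to host a primer plus margin")


def _random_seq(rng: np.random.Generator, length: int, gc: float, max_run: int) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = "ACGT"
    out: list[str] = []
    run = 0
    for _ in range(length):
        b = bases[rng.choice(4, p=probs)]
        while out and b == out[-1] and run >= max_run - 1:
            b = bases[rng.choice(4, p=probs)]
        if out and b == out[-1]:
            run += 1
        else:
            run = 0
        out.append(b)
    return "".join(out)


def simulate_genome(
    spec: GenomeSimSpec, fasta_path: Path | str, gff3_path: Path | str
) -> pd.DataFrame:
    """Write a FASTA + GFF3 pair with planted genes; returns the truth table.

    Genes alternate strand, sit on a single contig separated by intergenic
    spacers, and are named ``gene0001`` (transcripts ``gene0001.t1``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chunks: list[str] = []
    pos = 0
    records = []
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        gid = f"gene{str(i + 1).zfill(width)}"
        strand = "+" if i % 2 == 0 else "-"
        cls = rng.choice(3, p=spec.exon_class_probs)
        if cls == 0:
            n_exons = 1
        elif cls == 1:
            n_exons = 2
        else:
            n_exons = int(rng.integers(3, spec.max_exons + 1))
        spacer = _random_seq(rng, spec.intergenic, spec.gc_fraction, spec.max_homopolymer)
        chunks.append(spacer)
        pos += len(spacer)
        gene_start = pos
        exons = []
        for k in range(n_exons):
            if n_exons == 1:
                length = int(rng.integers(*spec.mono_exon_len))
            else:
                length = int(rng.integers(*spec.exon_len))
            exon_seq = _random_seq(rng, length, spec.gc_fraction, spec.max_homopolymer)
            chunks.append(exon_seq)
            exons.append((pos, pos + length))
            pos += length
            if k < n_exons - 1:
                ilen = int(rng.integers(*spec.intron_len))
                chunks.append(_random_seq(rng, ilen, spec.gc_fraction, spec.max_homopolymer))
                pos += ilen
        records.append(
            {
                "gene_id": gid,
                "transcript_id": f"{gid}.t1",
                "strand": strand,
                "n_exons": n_exons,
                "exons": exons,
                "start": gene_start,
                "end": pos,
            }
        )
    chunks.append(_random_seq(rng, spec.intergenic, spec.gc_fraction, spec.max_homopolymer))
    contig = "".join(chunks)

    with open(fasta_path, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(contig), 80):
            fh.write(contig[i : i + 80] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                f"chr1\trefprime_sim\tgene\t{r['start'] + 1}\t{r['end']}\t.\t"
                f"{r['strand']}\t.\tID={r['gene_id']}\n"
            )
            fh.write(
                f"chr1\trefprime_sim\tmRNA\t{r['start'] + 1}\t{r['end']}\t.\t"
                f"{r['strand']}\t.\tID={r['transcript_id']};Parent={r['gene_id']}\n"
            )
            for k, (s, e) in enumerate(r["exons"], 1):
                fh.write(
                    f"chr1\trefprime_sim\texon\t{s + 1}\t{e}\t.\t{r['strand']}\t.\t"
                    f"ID={r['transcript_id']}.exon{k};Parent={r['transcript_id']}\n"
                )
    truth = pd.DataFrame(
        [
            {
                "gene_id": r["gene_id"],
                "transcript_id": r["transcript_id"],
                "strand": r["strand"],
                "n_exons": r["n_exons"],
                "spliced_len": sum(e - s for s, e in r["exons"]),
            }
            for r in records
        ]
    )
    return truth


# ---------------------------------------------------------------------------
# Ct simulation
# ---------------------------------------------------------------------------


@dataclass
class CtSimSpec:
    """Calibration of the simulated qPCR readout.

    Ct falls by ~3.32 cycles (log2 of 10) per decade of expression; dropout
    probability grows with pair penalty and with Ct beyond a soft ceiling.
    """

    intercept: float = 30.0  # Ct at log10 expression 0
    slope: float = 3.321928  # cycles per decade, log2(10)
    noise_sd: float = 0.3
    replicates: int = 3
    dropout_base: float = 0.02
    dropout_per_penalty: float = 0.12
    dropout_per_cycle: float = 0.15  # per cycle above the soft ceiling
    soft_ceiling: float = 32.0
    seed: int = 0


def simulate_ct(
    catalog: Sequence[PrimerPair],
    expression: dict[str, float],
    spec: CtSimSpec | None = None,
) -> tuple[CtTable, pd.DataFrame]:
    """Simulate a Ct table for every pair of a catalog.

    ``expression`` maps gene_id to log10 expression.  Returns the table and
    a truth sidecar with each observation's dropout probability.
    """
    spec = spec or CtSimSpec()
    rng = np.random.default_rng(spec.seed)
    rows: list[CtObservation] = []
    truth_rows = []
    for pair in catalog:
        if pair.gene_id not in expression:
            raise KeyError(f"no expression level for {pair.gene_id}")
        expr = expression[pair.gene_id]
        ct_true = spec.intercept - spec.slope * expr
        for rep in range(1, spec.replicates + 1):
            ct = ct_true + rng.normal(0.0, spec.noise_sd)
            p_drop = min(
                0.95,
                spec.dropout_base
                + spec.dropout_per_penalty * pair.pair_penalty
                + spec.dropout_per_cycle * max(0.0, ct - spec.soft_ceiling),
            )
            dropped = bool(rng.random() < p_drop)
            rows.append(
                CtObservation(
                    gene_id=pair.gene_id,
                    primer_rank=pair.rank,
                    replicate=rep,
                    ct=None if dropped else float(ct),
                )
            )
            truth_rows.append(
                {
                    "gene_id": pair.gene_id,
                    "primer_rank": pair.rank,
                    "replicate": rep,
                    "ct_true": ct_true,
                    "p_dropout": p_drop,
                    "dropped": dropped,
                }
            )
    return CtTable(rows), pd.DataFrame(truth_rows)
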