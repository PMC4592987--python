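"""Gene models from genome FASTA + GFF3, and design-region selection.

The catalog builder needs, per transcript, the spliced (mRNA-side) sequence
and the positions of the exon-exon junctions, because qPCR primers are
placed so that the product either sits in the 3' tail of an intronless gene
or straddles the LAST exon-exon junction of an intron-containing gene —
the standard construction that keeps genomic DNA from yielding the same
product.

Region rules per gene class:

* mono-exonic — primers fall in the window between ``tail_window`` (500 bp)
  and ``tail_margin`` (100 bp) from the 3' end; genes shorter than the
  window use the whole sequence minus the margin and are flagged.
* one intron — the amplicon must span the single exon-exon junction.
* several introns — the amplicon must span the last junction, whatever the
  intron count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "DesignRegion",
    "DegenerateRegionError",
    "load_annotation",
    "write_gff3",
    "select_region",
    "DEFAULT_TAIL_WINDOW",
    "DEFAULT_TAIL_MARGIN",
]

log = logging.getLogger(__name__)

DEFAULT_TAIL_WINDOW = 500
DEFAULT_TAIL_MARGIN = 100
MIN_JUNCTION_ANCHOR = 18  # bp of exon sequence required on each side of a junction


class DegenerateRegionError(ValueError):
    """A gene whose structure cannot host a valid design region.

    ``reason`` is machine-readable and becomes the catalog's failure record.
    """

    def __init__(self, gene_id: str, reason: str, detail: str = ""):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(f"{gene_id}: {reason}" + (f" ({detail})" if detail else ""))


@dataclass
class GeneModel:
    """One annotated transcript.

    ``exons`` are 0-based half-open genomic intervals ordered 5'->3' in
    TRANSCRIPT orientation (i.e. descending genomic coordinate on the minus
    strand); ``spliced_seq`` is the mRNA-sense sequence; ``introns`` are the
    gaps between consecutive exons, in the same orientation.
    """

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: list[tuple[int, int]]
    spliced_seq: str
    introns: list[tuple[int, int]]
    genomic_span: tuple[int, int]

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def spliced_length(self) -> int:
        return len(self.spliced_seq)

    def junction_positions(self) -> list[int]:
        """Exon-exon junction offsets on the spliced sequence.

        Position ``j`` means the junction lies between spliced bases
        ``j - 1`` and ``j``.
        """
        out, acc = [], 0
        for start, end in self.exons[:-1]:
            acc += end - start
            out.append(acc)
        return out


@dataclass
class DesignRegion:
    gene_id: str
    mode: Literal["tail_window", "span_single_intron", "span_last_intron"]
    search_seq: str
    included_range: tuple[int, int]  # half-open on search_seq
    junction_target: int | None = None
    truncated: bool = False  # mono-exonic gene shorter than the tail window


def load_annotation(fasta: Path | str, gff3: Path | str) -> list[GeneModel]:
    """Parse genome FASTA + GFF3 into one :class:`GeneModel` per transcript.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Exon features are preferred; CDS features are used for transcripts that
    carry no exons.  Transcripts with neither are skipped with a log entry.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    transcripts = list(db.features_of_type("mRNA")) or list(db.features_of_type("gene"))
    for tr in transcripts:
        parts = list(db.children(tr, featuretype="exon", order_by="start"))
        if not parts:
            parts = list(db.children(tr, featuretype="CDS", order_by="start"))
        if not parts and tr.featuretype == "gene":
            # gene used directly as the transcript body
            parts = [tr]
        if not parts:
            log.info("transcript %s has no exon/CDS features; skipped", tr.id)
            continue
        if tr.seqid not in contigs:
            raise ValueError(f"feature {tr.id}: seqid {tr.seqid!r} not in FASTA")
        contig = contigs[tr.seqid]
        exons = sorted((p.start - 1, p.end) for p in parts)  # 0-based half-open
        for s, e in exons:
            if s < 0 or e > len(contig):
                raise ValueError(
                    f"feature {tr.id}: exon {s + 1}-{e} outside contig "
                    f"{tr.seqid} (length {len(contig)})"
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"feature {tr.id}: overlapping exons")
        strand = "-" if tr.strand == "-" else "+"
        spliced = "".join(contig[s:e] for s, e in exons)
        if strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
            exons = exons[::-1]
        introns = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            introns.append((e1, s2) if strand == "+" else (e2, s1))
        models.append(
            GeneModel(
                gene_id=tr.id,
                chrom=tr.seqid,
                strand=strand,
                exons=exons,
                spliced_seq=spliced,
                introns=introns,
                genomic_span=(min(s for s, _ in exons), max(e for _, e in exons)),
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: Path | str) -> None:
    """Emit gene/mRNA/exon features (1-based inclusive) for a set of models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            lo, hi = g.genomic_span
            base = g.gene_id.removesuffix(".t1")
            if base == g.gene_id:  # keep gene and mRNA IDs distinct
                base = g.gene_id + "_g"
            fh.write(
                f"{g.chrom}\t.\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tID={base}\n"
            )
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Parent={base}\n"
            )
            for k, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


def select_region(
    g: GeneModel,
    tail_window: int = DEFAULT_TAIL_WINDOW,
    tail_margin: int = DEFAULT_TAIL_MARGIN,
    *,
    max_product: int = 250,
    min_product: int = 100,
) -> DesignRegion:
    """Apply the intron-aware region rules to one gene model."""
    L = g.spliced_length
    if g.n_introns == 0:
        truncated = L < tail_window
        lo = max(0, L - tail_window)
        hi = L - tail_margin
        if hi - lo < min_product:
            raise DegenerateRegionError(
                g.gene_id,
                "gene_too_short",
                f"usable window {max(0, hi - lo)} bp < minimum product {min_product} bp",
            )
        if truncated:
            log.info(
                "gene %s shorter than the %d bp tail window; using the whole "
                "sequence minus the %d bp margin",
                g.gene_id,
                tail_window,
                tail_margin,
            )
        return DesignRegion(
            gene_id=g.gene_id,
            mode="tail_window",
            search_seq=g.spliced_seq,
            included_range=(lo, hi),
            truncated=truncated,
        )
    junction = g.junction_positions()[-1]
    upstream, downstream = junction, L - junction
    if upstream < MIN_JUNCTION_ANCHOR or downstream < MIN_JUNCTION_ANCHOR:
        raise DegenerateRegionError(
            g.gene_id,
            "exon_too_short",
            f"{upstream} bp upstream / {downstream} bp downstream of the last junction",
        )
    lo = max(0, junction - (max_product - 1))
    hi = min(L, junction + (max_product - 1))
    if hi - lo < min_product:
        raise DegenerateRegionError(g.gene_id, "gene_too_short")
    mode = "span_single_intron" if g.n_introns == 1 else "span_last_intron"
    return DesignRegion(
        gene_id=g.gene_id,
        mode=mode,
        search_seq=g.spliced_seq,
        included_range=(lo, hi),
        junction_target=junction,
    )
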