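"""Interpret external alignments of assigned elements and annotate insertions.

Alignment itself is delegated to standard tools: this module consumes their
output — BLAST 12-column tabular (``-outfmt 6``) or SAM — for the
well-tagged element sequences, decides whether each sequence anchors to a
unique locus, places the insertion point on the reference, classifies its
gene context against a GFF3 annotation (exon k of n, intron, within 1 kb
up/downstream, intergenic), and checks 5'/3' end concordance: both ends of
one well mapping to the same location is strong evidence the element is
genuine (the two flanks straddle the insertion and share only the short
target site duplication).

Coordinates are 1-based inclusive on the forward reference strand
throughout (BLAST/GFF3 convention; SAM positions converted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from intervaltree import IntervalTree

import pandas as pd

GENE_WINDOW = 1000  # bp scanned up/downstream of a gene span

__all__ = [
    "AlignmentHit",
    "AnnotatedInsertion",
    "Gene",
    "GeneModels",
    "parse_alignments",
    "classify_locus",
    "insertion_point",
    "annotate_insertion",
    "annotate_assignments",
    "pair_ends",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of a query flank to the reference genome."""

    query_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    identity_pct: float
    aln_length: int
    score: float  # BLAST bitscore or SAM MAPQ

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("hit start must be <= end after normalization")
        if not (0 <= self.identity_pct <= 100):
            raise ValueError("identity_pct must lie in [0, 100]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be +/-, got {self.strand!r}")


@dataclass
class AnnotatedInsertion:
    """A mapped element end with its genomic and gene context."""

    well: str
    end_label: str
    locus_status: str  # unique | multiple | unmapped
    chrom: str | None = None
    insertion_point: int | None = None
    strand: str | None = None
    gene_context: str | None = None  # exon|intron|within_1kb_upstream|...
    gene_id: str | None = None
    exon_index: int | None = None
    exon_count: int | None = None
    paired: bool = False

    def context_label(self) -> str:
        """Human-readable context, exon shown in the ``k/n`` convention."""
        if self.locus_status == "unmapped" or self.gene_context is None:
            return ""
        if self.gene_context == "exon":
            return f"exon({self.exon_index}/{self.exon_count})"
        return self.gene_context


# ---------------------------------------------------------------------------
# Alignment parsing
# ---------------------------------------------------------------------------


def _parse_blast_tabular(path: str | Path) -> dict[str, list[AlignmentHit]]:
    hits: dict[str, list[AlignmentHit]] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns "
                    f"(BLAST -outfmt 6), got {len(fields)}"
                )
            try:
                qid = fields[0]
                chrom = fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                sstart, send = int(fields[8]), int(fields[9])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            strand = "+" if sstart <= send else "-"
            lo, hi = min(sstart, send), max(sstart, send)
            hits.setdefault(qid, []).append(
                AlignmentHit(qid, chrom, lo, hi, strand, pident, length, bitscore)
            )
    return hits


def _parse_sam(path: str | Path) -> dict[str, list[AlignmentHit]]:
    hits: dict[str, list[AlignmentHit]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            qid = rec.query_name
            hits.setdefault(qid, [])
            if rec.is_unmapped:
                continue
            aln_len = rec.query_alignment_length
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            identity = 100.0 * (aln_len - nm) / aln_len if aln_len else 0.0
            hits[qid].append(
                AlignmentHit(
                    qid,
                    rec.reference_name,
                    rec.reference_start + 1,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    identity,
                    aln_len,
                    float(rec.mapping_quality),
                )
            )
    return hits


def parse_alignments(
    path: str | Path, fmt: str = "blast_tabular"
) -> dict[str, list[AlignmentHit]]:
    """Parse alignment results into per-query hit lists.

    `fmt` is ``blast_tabular`` (12-column ``-outfmt 6``) or ``sam``.
    Reverse-strand hits have coordinates normalized ascending and strand
    '-'; SAM unmapped records yield a query with an empty hit list.
    """
    if fmt == "blast_tabular":
        return _parse_blast_tabular(path)
    if fmt == "sam":
        return _parse_sam(path)
    raise ValueError(f"unknown alignment format {fmt!r} (blast_tabular or sam)")


# ---------------------------------------------------------------------------
# Locus classification
# ---------------------------------------------------------------------------


def classify_locus(
    hits: Sequence[AlignmentHit],
    min_identity: float = 95.0,
    min_length: int = 0,
    score_margin: float = 0.90,
) -> tuple[str, AlignmentHit | None]:
    """Decide unique / multiple / unmapped for one query's hits.

    Hits below `min_identity` percent identity or shorter than `min_length`
    are discarded. No survivor → unmapped; one → unique; otherwise a second
    hit scoring at least ``score_margin`` of the best is treated as genuine
    ambiguity (multiple), while strictly weaker secondaries are ignored.
    The best hit is returned for unique queries.
    """
    surviving = [
        h for h in hits if h.identity_pct >= min_identity and h.aln_length >= min_length
    ]
    if not surviving:
        return "unmapped", None
    surviving.sort(key=lambda h: (-h.score, h.chrom, h.start))
    if len(surviving) > 1 and surviving[1].score >= score_margin * surviving[0].score:
        return "multiple", None
    return "unique", surviving[0]


def insertion_point(hit: AlignmentHit) -> int:
    """Flank-proximal reference coordinate of a hit.

    The aligned flank starts with the target site duplication at the
    element junction, so the reference base matching the query start
    approximates the insertion site to within the TSD length: the hit start
    for a forward hit, the hit end for a reverse one.
    """
    return hit.start if hit.strand == "+" else hit.end


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive span
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # ascending (start, end)

    def exon_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcription order (reversed for '-' genes)."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


class GeneModels:
    """Gene/exon annotation with interval lookup per chromosome."""

    def __init__(self, genes: Iterable[Gene]) -> None:
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # half-open tree interval padded by the flank window
            tree.addi(g.start - GENE_WINDOW, g.end + GENE_WINDOW + 1, g)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModels":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type("gene"):
            exons = tuple(
                sorted(
                    (e.start, e.end)
                    for e in db.children(feat, featuretype="exon")
                )
            )
            genes.append(
                Gene(feat.id, feat.seqid, feat.start, feat.end, feat.strand, exons)
            )
        return cls(genes)

    def nearby(self, chrom: str, point: int) -> list[Gene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.at(point)),
            key=lambda g: (g.start, g.gene_id),
        )

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees


def _gene_distance(gene: Gene, point: int) -> int:
    if point < gene.start:
        return gene.start - point
    if point > gene.end:
        return point - gene.end
    return 0


def classify_point(
    models: GeneModels, chrom: str, point: int, window: int = GENE_WINDOW
) -> tuple[str, Gene | None, int | None, int | None]:
    """Gene context of a reference point.

    Returns (context, gene, exon_index, exon_count). Inside a gene span the
    context is ``exon`` (with its 1-based index in transcription order) or
    ``intron``; within `window` bp of a gene span it is the flank class
    relative to the gene's orientation; otherwise ``intergenic``. When
    several genes qualify the nearest (then lowest-coordinate) one wins.
    """
    if window > GENE_WINDOW:
        raise ValueError(f"window may not exceed the indexed pad ({GENE_WINDOW})")
    candidates = [
        g for g in models.nearby(chrom, point) if _gene_distance(g, point) <= window
    ]
    if not candidates:
        return "intergenic", None, None, None
    gene = min(candidates, key=lambda g: (_gene_distance(g, point), g.start, g.gene_id))
    if gene.start <= point <= gene.end:
        for k, (es, ee) in enumerate(gene.exon_order(), 1):
            if es <= point <= ee:
                return "exon", gene, k, len(gene.exons)
        return "intron", gene, None, None
    before_span = point < gene.start
    if (gene.strand == "+") == before_span:
        return "within_1kb_upstream", gene, None, None
    return "within_1kb_downstream", gene, None, None


def annotate_insertion(
    well: str,
    end_label: str,
    locus_status: str,
    best_hit: AlignmentHit | None,
    models: GeneModels,
    window: int = GENE_WINDOW,
) -> AnnotatedInsertion:
    """Build the annotated record for one element end.

    Only uniquely anchored ends receive a gene context; a unique hit on a
    chromosome absent from the annotation is classified intergenic (this
    signals a genome/annotation mismatch).
    """
    ann = AnnotatedInsertion(well=well, end_label=end_label, locus_status=locus_status)
    if locus_status != "unique" or best_hit is None:
        return ann
    point = insertion_point(best_hit)
    ann.chrom = best_hit.chrom
    ann.insertion_point = point
    ann.strand = best_hit.strand
    context, gene, k, n = classify_point(models, best_hit.chrom, point, window)
    ann.gene_context = context
    ann.gene_id = gene.gene_id if gene else None
    ann.exon_index = k
    ann.exon_count = n
    return ann


# ---------------------------------------------------------------------------
# High-level driver
# ---------------------------------------------------------------------------


def _query_lengths(fasta_path: str | Path) -> dict[str, int]:
    with open(fasta_path, "rt") as fh:
        return {title.split()[0]: len(seq) for title, seq in SimpleFastaParser(fh)}


def annotate_assignments(
    assignments_fasta: str | Path,
    alignments_path: str | Path,
    models: GeneModels,
    fmt: str = "blast_tabular",
    end_label: str = "three_prime",
    min_identity: float = 95.0,
    min_length_fraction: float = 0.8,
    window: int = GENE_WINDOW,
) -> list[AnnotatedInsertion]:
    """Annotate every record of a well-tagged assignment FASTA.

    The minimum surviving alignment length for each query is
    ``ceil(min_length_fraction * query length)``. Queries without any
    alignment record are unmapped.
    """
    lengths = _query_lengths(assignments_fasta)
    all_hits = parse_alignments(alignments_path, fmt)
    out = []
    for qid, qlen in lengths.items():
        well = qid.split("|")[0]
        status, best = classify_locus(
            all_hits.get(qid, []),
            min_identity=min_identity,
            min_length=math.ceil(min_length_fraction * qlen),
        )
        out.append(annotate_insertion(well, end_label, status, best, models, window))
    return out


def pair_ends(
    five_prime: Iterable[AnnotatedInsertion],
    three_prime: Iterable[AnnotatedInsertion],
    max_gap: int = 16,
) -> set[str]:
    """Flag wells whose 5' and 3' ends anchor to the same locus.

    Two ends pair iff both are uniquely mapped to the same chromosome with
    insertion points within `max_gap` bp (default twice the 8-bp TSD, the
    span the duplicated target site can offset the two flanks). Sets
    ``paired`` on both records and returns the paired well labels.
    """
    five_by_well: dict[str, AnnotatedInsertion] = {}
    for a in five_prime:
        if a.locus_status == "unique":
            five_by_well[a.well] = a
    paired: set[str] = set()
    for b in three_prime:
        a = five_by_well.get(b.well)
        if (
            a is not None
            and b.locus_status == "unique"
            and a.chrom == b.chrom
            and abs(int(a.insertion_point) - int(b.insertion_point)) <= max_gap
        ):
            a.paired = True
            b.paired = True
            paired.add(b.well)
    return paired


def annotations_frame(records: Iterable[AnnotatedInsertion]) -> pd.DataFrame:
    rows = [
        {
            "well": r.well,
            "end": r.end_label,
            "chrom": r.chrom or "",
            "insertion_point": r.insertion_point,
            "locus_status": r.locus_status,
            "gene_id": r.gene_id or "",
            "gene_context": r.context_label(),
            "paired": r.paired,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "well", "end", "chrom", "insertion_point", "locus_status",
            "gene_id", "gene_context", "paired",
        ],
    )
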