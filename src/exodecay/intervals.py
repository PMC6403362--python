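"""Coordinate conventions, interval algebra and annotation I/O.

All coordinates inside the package are 0-based half-open ``[start, end)``.
GTF/GFF3 records (1-based closed) are converted at the boundary and never
leak their convention further in. Strand is one of ``+``, ``-`` or ``.``
(unstranded).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

#: Sentinel distance for features on different chromosomes.
INF_DISTANCE = math.inf


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >=1 base (strand-agnostic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Genome:
    """Chromosome-name -> length mapping (two-column chrom.sizes)."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {size}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def length(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    def contains_interval(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.chrom_sizes and 0 <= iv.start and iv.end <= self.chrom_sizes[iv.chrom]


@dataclass
class TranscriptModel:
    """One transcript isoform: ordered, disjoint exons on one chrom/strand."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes {chroms}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom


@dataclass
class GeneModel:
    """A gene: its span, biotype and transcript isoforms."""

    gene_id: str
    biotype: str
    span: GenomicInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        """Transcription start site (leftmost base on +, rightmost on -)."""
        return self.span.start if self.strand != "-" else self.span.end - 1

    def all_exons(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals into a minimal sorted disjoint set covering the same bases.

    Touching intervals (``[a,b)``, ``[b,c)``) are merged: bookended exons
    yield a single block and hence no zero-length intron downstream.
    All inputs must share one chromosome (and are given the strand of the
    first interval).
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"cannot merge intervals on multiple chromosomes: {sorted(chroms)}")
    strand = intervals[0].strand
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur_s, cur_e = ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.start <= cur_e:  # overlap or touch
            cur_e = max(cur_e, iv.end)
        else:
            out.append(GenomicInterval(ivs[0].chrom, cur_s, cur_e, strand))
            cur_s, cur_e = iv.start, iv.end
    out.append(GenomicInterval(ivs[0].chrom, cur_s, cur_e, strand))
    return out


def subtract_intervals(a: GenomicInterval, b: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Base-set difference ``bases(a) \\ bases(b)`` as sorted disjoint intervals.

    ``b`` must be disjoint and sorted (as produced by :func:`merge_intervals`);
    intervals of ``b`` on other chromosomes are ignored. The result may be
    empty.
    """
    pieces: list[GenomicInterval] = []
    cursor = a.start
    for iv in b:
        if iv.chrom != a.chrom or iv.end <= a.start or iv.start >= a.end:
            continue
        if iv.start > cursor:
            pieces.append(GenomicInterval(a.chrom, cursor, iv.start, a.strand))
        cursor = max(cursor, iv.end)
        if cursor >= a.end:
            break
    if cursor < a.end:
        pieces.append(GenomicInterval(a.chrom, cursor, a.end, a.strand))
    return pieces


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Number of bases strictly between two intervals.

    0 when they overlap or touch; ``math.inf`` when they lie on different
    chromosomes. Symmetric by construction.
    """
    if a.chrom != b.chrom:
        return INF_DISTANCE
    if a.start < b.end and b.start < a.end:
        return 0
    return max(b.start - a.end, a.start - b.end, 0)


# ---------------------------------------------------------------------------
# BED6 reads and the MAPQ filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bed6Record:
    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


def filter_reads(reads: Iterable[Bed6Record], min_mapq: int = 20) -> list[Bed6Record]:
    """Discard low-MAPQ reads (score column holds MAPQ; ``< min_mapq`` dropped).

    The boundary is inclusive on the keep side: MAPQ 20 survives the default
    filter, MAPQ 19 does not.
    """
    return [r for r in reads if r.score >= min_mapq]


def read_bed6(path: str) -> list[Bed6Record]:
    """Read a BED6 file (0-based half-open) into records."""
    out: list[Bed6Record] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append(Bed6Record(GenomicInterval(f[0], int(f[1]), int(f[2]), strand), name, score))
    return out


def write_bed6(records: Iterable[Bed6Record], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\t{score}\t{iv.strand}\n")


def read_chrom_sizes(path: str) -> Genome:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            name = fields[0]
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name}")
            sizes[name] = int(fields[1])
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        for name, size in genome.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


# ---------------------------------------------------------------------------
# GTF / GFF3 annotation reader
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"([^=;]+)=([^;]*)")


def _parse_attributes(raw: str, dialect: str) -> dict[str, str]:
    if dialect == "gtf":
        return dict(_GTF_ATTR.findall(raw))
    return {k.strip(): v for k, v in _GFF3_ATTR.findall(raw)}


def read_annotation(path: str, dialect: str = "gtf") -> list[GeneModel]:
    """Parse gene/transcript/exon records from a GTF or GFF3 file.

    1-based closed coordinates become 0-based half-open. Genes are returned
    sorted by (chrom, start, gene_id); exon records without a transcript_id
    and records whose end precedes their start are hard errors naming the
    offending line. Gene records are optional — when absent, the gene span
    is the exon hull.

    For GFF3, ``gene_id``/``transcript_id`` are taken from those attribute
    keys if present, else from ``Parent``/``ID``.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")

    gene_spans: dict[str, GenomicInterval] = {}
    gene_biotype: dict[str, str] = {}
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_strand: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, raw_attr = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(raw_attr, dialect)
            gene_id = attrs.get("gene_id")

            if feature == "gene":
                if gene_id is None:
                    gene_id = attrs.get("ID")
                if gene_id is None:
                    raise ValueError(f"{path}:{lineno}: gene record without gene_id")
                gene_spans[gene_id] = GenomicInterval(chrom, start, end, strand)
                gene_biotype[gene_id] = attrs.get("gene_biotype", attrs.get("biotype", attrs.get("gene_type", "unknown")))
            elif feature == "exon":
                tx_id = attrs.get("transcript_id", attrs.get("Parent"))
                if tx_id is None:
                    raise ValueError(f"{path}:{lineno}: exon record without transcript_id")
                if gene_id is None:
                    gene_id = tx_id  # GFF3 exon may only know its transcript
                tx_exons.setdefault(tx_id, []).append(GenomicInterval(chrom, start, end, strand))
                tx_gene.setdefault(tx_id, gene_id)
                tx_strand.setdefault(tx_id, strand)
            elif feature == "transcript" or feature == "mRNA":
                tx_id = attrs.get("transcript_id", attrs.get("ID"))
                if tx_id is not None and gene_id is not None:
                    tx_gene.setdefault(tx_id, gene_id)

    genes: dict[str, GeneModel] = {}
    for tx_id, exons in tx_exons.items():
        gid = tx_gene[tx_id]
        tm = TranscriptModel(tx_id, gid, tx_strand[tx_id], exons)
        if gid not in genes:
            span = gene_spans.get(gid)
            if span is None:
                span = GenomicInterval(
                    tm.chrom, min(e.start for e in exons), max(e.end for e in exons), tm.strand
                )
            genes[gid] = GeneModel(gid, gene_biotype.get(gid, "unknown"), span)
        genes[gid].transcripts.append(tm)

    # genes annotated without exon children still count (span-only records)
    for gid, span in gene_spans.items():
        if gid not in genes:
            genes[gid] = GeneModel(gid, gene_biotype.get(gid, "unknown"), span)

    # widen spans to the exon hull if exons poke out
    for g in genes.values():
        ex = g.all_exons()
        if ex:
            lo = min(g.span.start, min(e.start for e in ex))
            hi = max(g.span.end, max(e.end for e in ex))
            if (lo, hi) != (g.span.start, g.span.end):
                g.span = GenomicInterval(g.chrom, lo, hi, g.strand)

    return sorted(genes.values(), key=lambda g: (g.chrom, g.span.start, g.gene_id))


def iter_gtf_lines(genes: Iterable[GeneModel]) -> Iterator[str]:
    """Serialize gene models back to GTF lines (gene + exon records)."""
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        yield (
            f"{g.chrom}\texodecay\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for t in g.transcripts:
            for e in t.exons:
                yield (
                    f"{g.chrom}\texodecay\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; gene_biotype "{g.biotype}";'
                )


def write_annotation(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for line in iter_gtf_lines(genes):
            fh.write(line + "\n")
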