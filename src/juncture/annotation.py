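"""Gene/transcript/exon/intron data model and GTF I/O.

All coordinates are 0-based half-open internally. GTF is read and written in
its native 1-based inclusive convention; the conversion happens exactly once,
at the I/O boundary. SAM positions arrive 0-based from pysam and need no
conversion.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Transcript",
    "Intron",
    "Gene",
    "Annotation",
    "GtfParseError",
    "load_annotation",
    "write_gtf",
    "introns_to_bed",
]

STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Span containment on the same chromosome (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Minimum genomic gap between two intervals; 0 if they overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Transcript:
    """An ordered exon chain; introns are the gaps between consecutive exons."""

    id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.id} mixes chromosomes or strands")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"transcript {self.id} exons are not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.id} has overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    def subsumes(self, interval: GenomicInterval) -> bool:
        """True iff the transcript's genomic span contains the interval.

        A different chromosome yields False, not an error.
        """
        return self.span.contains(interval)


@dataclass(frozen=True)
class Intron:
    """A derived intron: the exon gap shared by one or more transcripts."""

    id: str
    interval: GenomicInterval
    gene_id: str
    transcript_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class Gene:
    id: str
    span: GenomicInterval
    transcripts: list[Transcript] = field(default_factory=list)


class Annotation:
    """Genes with transcripts and the deduplicated set of derived introns."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.genes: dict[str, Gene] = {}
        for tx in transcripts:
            gene = self.genes.get(tx.gene_id)
            if gene is None:
                self.genes[tx.gene_id] = Gene(tx.gene_id, tx.span, [tx])
            else:
                if gene.span.chrom != tx.chrom:
                    raise ValueError(f"gene {tx.gene_id} spans two chromosomes")
                gene.transcripts.append(tx)
                gene.span = GenomicInterval(
                    gene.span.chrom,
                    min(gene.span.start, tx.span.start),
                    max(gene.span.end, tx.span.end),
                    gene.span.strand,
                )
        self._introns: dict[str, Intron] = {}
        self._intron_by_interval: dict[tuple, Intron] = {}
        self._derive_introns()

    # -- intron derivation -------------------------------------------------

    def _derive_introns(self) -> None:
        self._introns.clear()
        self._intron_by_interval.clear()
        for gene in self.genes.values():
            seen: dict[tuple, list[str]] = {}
            for tx in gene.transcripts:
                for iv in tx.introns():
                    seen.setdefault(iv.key(), []).append(tx.id)
            for key, tx_ids in sorted(seen.items()):
                chrom, start, end, strand = key
                iv = GenomicInterval(chrom, start, end, strand)
                intron_id = f"{gene.id}:{start}-{end}"
                intron = Intron(intron_id, iv, gene.id, tuple(sorted(set(tx_ids))))
                self._introns[intron_id] = intron
                self._intron_by_interval[(chrom, start, end)] = intron

    def introns(self, gene_id: str | None = None) -> list[Intron]:
        if gene_id is None:
            return list(self._introns.values())
        return [i for i in self._introns.values() if i.gene_id == gene_id]

    def intron_by_id(self, intron_id: str) -> Intron:
        return self._introns[intron_id]

    def intron_at(self, chrom: str, start: int, end: int) -> Intron | None:
        """Derived intron exactly matching the interval (strand-blind lookup)."""
        return self._intron_by_interval.get((chrom, start, end))

    # -- queries -----------------------------------------------------------

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes.values():
            yield from gene.transcripts

    def transcripts_containing(self, interval: GenomicInterval) -> list[Transcript]:
        """Transcripts whose intron set contains the interval exactly.

        This is the "transcript contains a junction" relation: the junction
        interval must equal one of the transcript's introns. A junction found
        in no transcript is novel.
        """
        intron = self.intron_at(interval.chrom, interval.start, interval.end)
        if intron is None:
            return []
        gene = self.genes[intron.gene_id]
        wanted = set(intron.transcript_ids)
        return [tx for tx in gene.transcripts if tx.id in wanted]

    def assign_gene(self, chrom: str, start: int, end: int,
                    strand: str | None = None) -> Gene | None:
        """Gene owning a (possibly novel) junction interval.

        The gene span must contain both endpoints; among several overlapping
        genes, strand-matching genes win when a strand is given, then the
        smallest span, then lexicographic id — a deterministic assignment.
        """
        hits = [
            g for g in self.genes.values()
            if g.span.chrom == chrom and g.span.start <= start and end <= g.span.end
        ]
        if not hits:
            return None
        if strand is not None:
            stranded = [g for g in hits if g.span.strand == strand]
            if stranded:
                hits = stranded
        hits.sort(key=lambda g: (len(g.span), g.id))
        return hits[0]


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def load_annotation(source) -> Annotation:
    """Read an Annotation from GTF (path, file-like, or iterable of lines).

    Only ``exon`` features are used; other feature types are ignored. GTF
    1-based inclusive coordinates become 0-based half-open on read.
    """
    if isinstance(source, (str,)):
        with open(source) as fh:
            return load_annotation(fh)
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
        chrom, _, feature, start_s, end_s, _, strand, _, attrs_s = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
        if strand not in STRANDS:
            raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
        attrs = _parse_attributes(attrs_s)
        gene_id = attrs.get("gene_id")
        tx_id = attrs.get("transcript_id")
        if not gene_id or not tx_id:
            raise GtfParseError(
                f"line {lineno}: exon without gene_id/transcript_id attributes"
            )
        iv = GenomicInterval(chrom, start1 - 1, end1, strand)
        exons.setdefault((gene_id, tx_id), []).append(iv)

    transcripts = []
    for (gene_id, tx_id), ivs in exons.items():
        transcripts.append(Transcript(tx_id, gene_id, tuple(sorted(ivs))))
    return Annotation(transcripts)


def write_gtf(annotation: Annotation, destination=None) -> str | None:
    """Write exon features as GTF (1-based inclusive). Returns text if no sink."""
    buf = io.StringIO()
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        for tx in sorted(gene.transcripts, key=lambda t: t.id):
            for iv in tx.exons:
                attrs = f'gene_id "{gene_id}"; transcript_id "{tx.id}";'
                buf.write(
                    "\t".join(
                        [
                            iv.chrom,
                            "juncture",
                            "exon",
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    text = buf.getvalue()
    if destination is None:
        return text
    if isinstance(destination, str):
        with open(destination, "w") as fh:
            fh.write(text)
        return None
    destination.write(text)
    return None


def introns_to_bed(annotation: Annotation) -> str:
    """Derived introns as BED6 text (0-based half-open, name=intron id)."""
    lines = []
    for intron in sorted(annotation.introns(), key=lambda i: i.interval.key()):
        iv = intron.interval
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{intron.id}\t0\t{iv.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
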