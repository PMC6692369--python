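"""Junction-read extraction and strictly-intronic segment counting from SAM.

A junction read maps discontinuously within one gene: its CIGAR carries one
or more N gaps, each gap being independent evidence for one junction. The
minimum overhang — the shorter of the two aligned blocks immediately flanking
the gap — gates acceptance: 3 nt for annotated junctions, 6 nt for novel
ones. A strictly intronic read has no gap and lies entirely inside a single
derived intron; it is assigned to the intron segment containing its aligned
midpoint.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam
from intervaltree import IntervalTree

from .annotation import Annotation, GenomicInterval

__all__ = [
    "Junction",
    "JunctionTable",
    "SegmentCounts",
    "extract_junction_reads",
    "count_strictly_intronic",
    "classify_motif",
    "n_segments",
    "segment_boundaries",
]

logger = logging.getLogger(__name__)

# CIGAR numeric ops (pysam): M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_REF_CONSUMING = {0, 2, 3, 7, 8}
_SUPPORTED_OPS = {0, 1, 2, 3, 4, 7, 8}


@dataclass(frozen=True)
class Junction:
    """A splice junction: the intronic span it removes, plus its status."""

    interval: GenomicInterval
    status: str  # "annotated" | "novel"
    gene_id: str
    motif: str = "unknown"  # "canonical" | "non_canonical" | "unknown"


@dataclass
class JunctionTable:
    """Per-junction accepted read counts in two conditions."""

    junctions: dict[tuple, Junction] = field(default_factory=dict)
    count_a: dict[tuple, int] = field(default_factory=dict)
    count_b: dict[tuple, int] = field(default_factory=dict)
    discarded_outside_genes: int = 0

    def add(self, junction: Junction, condition: str, n: int = 1) -> None:
        key = junction.interval.key()[:3]
        self.junctions.setdefault(key, junction)
        counts = self.count_a if condition == "A" else self.count_b
        counts[key] = counts.get(key, 0) + n

    def counts(self, key: tuple) -> tuple[int, int]:
        return self.count_a.get(key, 0), self.count_b.get(key, 0)

    def total(self) -> int:
        return sum(self.count_a.values()) + sum(self.count_b.values())

    def merge(self, other: "JunctionTable") -> "JunctionTable":
        for key, j in other.junctions.items():
            self.junctions.setdefault(key, j)
        for key, n in other.count_a.items():
            self.count_a[key] = self.count_a.get(key, 0) + n
        for key, n in other.count_b.items():
            self.count_b[key] = self.count_b.get(key, 0) + n
        self.discarded_outside_genes += other.discarded_outside_genes
        return self


@dataclass
class SegmentCounts:
    """Strictly-intronic read counts per equal-width intron segment."""

    intron_id: str
    boundaries: tuple[int, ...]  # n_segments + 1 genomic breakpoints
    counts_a: list[int] = field(default_factory=list)
    counts_b: list[int] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) - 1

    def segment_lengths(self) -> list[int]:
        return [b - a for a, b in zip(self.boundaries, self.boundaries[1:])]

    def total(self, condition: str) -> int:
        return sum(self.counts_a if condition == "A" else self.counts_b)


def n_segments(length: int) -> int:
    """Number of intron segments for the robust IR median: max(2, floor(L/500))."""
    return max(2, length // 500)


def segment_boundaries(start: int, end: int) -> tuple[int, ...]:
    """Equal-width segment breakpoints; the last segment absorbs the remainder."""
    L = end - start
    k = n_segments(L)
    width = L // k
    bounds = [start + i * width for i in range(k)]
    bounds.append(end)
    return tuple(bounds)


def _iter_gaps(segment: pysam.AlignedSegment):
    """Yield (gap_start, gap_end, left_overhang, right_overhang) per N gap.

    Overhang is the reference length of the M (or =/X) block immediately
    flanking the gap; insertions and deletions do not contribute.
    """
    pos = segment.reference_start
    cig = segment.cigartuples or []
    # reference start/length of each op
    spans = []
    for op, n in cig:
        spans.append((op, n, pos))
        if op in _REF_CONSUMING:
            pos += n
    for idx, (op, n, start) in enumerate(spans):
        if op != 3:  # N
            continue
        left = 0
        for op2, n2, _ in reversed(spans[:idx]):
            if op2 in (0, 7, 8):
                left = n2
                break
            if op2 == 3:
                break
        right = 0
        for op2, n2, _ in spans[idx + 1 :]:
            if op2 in (0, 7, 8):
                right = n2
                break
            if op2 == 3:
                break
        yield start, start + n, left, right


def extract_junction_reads(
    sam_path: str,
    annotation: Annotation,
    condition: str = "A",
    min_overhang_annotated: int = 3,
    min_overhang_novel: int = 6,
    table: JunctionTable | None = None,
    require_strand_match: bool = False,
) -> JunctionTable:
    """Count accepted junction-read gap observations per junction.

    Each N gap of a read is a separate observation; a read with k gaps can
    support k junctions. Gaps whose junction equals a derived intron are
    annotated (overhang >= min_overhang_annotated); other gaps inside a gene
    span are novel (overhang >= min_overhang_novel); gaps outside every gene
    are discarded and tallied. Order-independent: shuffled input gives the
    same table.
    """
    table = table if table is not None else JunctionTable()
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.cigartuples is None:
                continue
            ops = {op for op, _ in read.cigartuples}
            if not ops <= _SUPPORTED_OPS:
                logger.warning("skipping read %s: unsupported CIGAR op", read.query_name)
                continue
            if 3 not in ops:
                continue
            chrom = read.reference_name
            for gstart, gend, left, right in _iter_gaps(read):
                overhang = min(left, right)
                intron = annotation.intron_at(chrom, gstart, gend)
                if intron is not None:
                    if overhang < min_overhang_annotated:
                        continue
                    iv = intron.interval
                    table.add(
                        Junction(iv, "annotated", intron.gene_id), condition
                    )
                else:
                    gene = annotation.assign_gene(chrom, gstart, gend)
                    if gene is None:
                        table.discarded_outside_genes += 1
                        continue
                    if overhang < min_overhang_novel:
                        continue
                    iv = GenomicInterval(chrom, gstart, gend, gene.span.strand)
                    table.add(Junction(iv, "novel", gene.id), condition)
    if table.discarded_outside_genes:
        logger.info(
            "%d junction gaps outside any gene span discarded",
            table.discarded_outside_genes,
        )
    return table


def _intron_trees(annotation: Annotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for intron in annotation.introns():
        iv = intron.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, intron)
    return trees


def count_strictly_intronic(
    sam_path: str,
    annotation: Annotation,
    condition: str = "A",
    segments: dict[str, SegmentCounts] | None = None,
) -> dict[str, SegmentCounts]:
    """Per-intron, per-segment counts of strictly intronic reads.

    A read qualifies iff it has no N gap and its full aligned reference span
    lies inside the intron interval. The read goes to the segment containing
    its aligned midpoint. Reads inside nested/overlapping introns count for
    every intron that fully contains them.
    """
    if segments is None:
        segments = {}
    for intron in annotation.introns():
        if intron.id not in segments:
            iv = intron.interval
            k = n_segments(intron.length)
            segments[intron.id] = SegmentCounts(
                intron.id,
                segment_boundaries(iv.start, iv.end),
                [0] * k,
                [0] * k,
            )
    trees = _intron_trees(annotation)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.cigartuples is None:
                continue
            if any(op == 3 for op, _ in read.cigartuples):
                continue
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            rstart, rend = read.reference_start, read.reference_end
            mid = (rstart + rend) // 2
            for hit in tree.overlap(rstart, rend):
                if hit.begin <= rstart and rend <= hit.end:
                    sc = segments[hit.data.id]
                    counts = sc.counts_a if condition == "A" else sc.counts_b
                    # midpoint segment; last boundary belongs to last segment
                    idx = sc.n_segments - 1
                    for i in range(sc.n_segments):
                        if mid < sc.boundaries[i + 1]:
                            idx = i
                            break
                    counts[idx] += 1
    return segments


def classify_motif(strand: str, donor_dinucleotide: str | None,
                   acceptor_dinucleotide: str | None) -> str:
    """GT..AG junctions (CT..AC on '-') are canonical; unknown without sequence."""
    if not donor_dinucleotide or not acceptor_dinucleotide:
        return "unknown"
    donor = donor_dinucleotide.upper()
    acceptor = acceptor_dinucleotide.upper()
    if strand == "+":
        return "canonical" if (donor, acceptor) == ("GT", "AG") else "non_canonical"
    return "canonical" if (donor, acceptor) == ("CT", "AC") else "non_canonical"
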