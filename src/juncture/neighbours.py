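"""Neighbour-junction, competing-junction and neighbour-intron sets.

Neighbour junctions provide the normalisation denominator for differential
junction usage. Junction N is a neighbour of junction J iff
(i) every transcript whose intron set contains N span-subsumes J,
(ii) every transcript containing J span-subsumes N, and
(iii) the minimum genomic gap between the two intervals is at most 5 kb.
A novel junction is contained in no transcript, so its side of (i)/(ii) holds
vacuously. Competing junctions — alternatives that partition the same read
evidence — are found by greedy closure over shared donor/acceptor
coordinates within the same window.
"""
from __future__ import annotations

from .annotation import Annotation, GenomicInterval
from .counting import JunctionTable

__all__ = [
    "neighbour_junctions",
    "build_neighbour_sets",
    "competing_junctions",
    "neighbour_introns",
]

DEFAULT_MAX_DIST = 5000


def _is_neighbour(
    j: GenomicInterval,
    n: GenomicInterval,
    annotation: Annotation,
    max_dist: int,
) -> bool:
    if j.chrom != n.chrom or (j.start, j.end) == (n.start, n.end):
        return False
    if j.gap_to(n) > max_dist:
        return False
    for tx in annotation.transcripts_containing(n):
        if not tx.subsumes(j):
            return False
    for tx in annotation.transcripts_containing(j):
        if not tx.subsumes(n):
            return False
    return True


def neighbour_junctions(
    junction_key: tuple,
    annotation: Annotation,
    table: JunctionTable,
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[tuple]:
    """Keys of detected junctions qualifying as neighbours of the given one.

    Candidates are restricted to detected junctions of the same gene; the
    result is sorted by coordinate for determinism.
    """
    j = table.junctions.get(junction_key)
    if j is None or j.gene_id not in annotation.genes:
        return []
    out = []
    for key, cand in table.junctions.items():
        if cand.gene_id != j.gene_id:
            continue
        if _is_neighbour(j.interval, cand.interval, annotation, max_dist):
            out.append(key)
    return sorted(out)


def build_neighbour_sets(
    annotation: Annotation,
    table: JunctionTable,
    max_dist: int = DEFAULT_MAX_DIST,
) -> dict[tuple, list[tuple]]:
    """Neighbour lists for every junction in the table (gene-local scan)."""
    by_gene: dict[str, list[tuple]] = {}
    for key, j in table.junctions.items():
        by_gene.setdefault(j.gene_id, []).append(key)
    sets: dict[tuple, list[tuple]] = {}
    for gene_id, keys in by_gene.items():
        for key in keys:
            j = table.junctions[key]
            out = [
                k
                for k in keys
                if _is_neighbour(
                    j.interval, table.junctions[k].interval, annotation, max_dist
                )
            ]
            sets[key] = sorted(out)
    return sets


def competing_junctions(
    seed_key: tuple,
    table: JunctionTable,
    max_dist: int = DEFAULT_MAX_DIST,
) -> set[tuple]:
    """Greedy closure of junctions sharing a donor/acceptor boundary chain.

    Starting from the seed, repeatedly absorb any detected junction in the
    +/- max_dist window around the seed that shares a start or end coordinate
    with a current member, until a fixed point; the seed itself is excluded
    from the returned competitor set.
    """
    seed = table.junctions.get(seed_key)
    if seed is None:
        return set()
    window = [
        key
        for key, j in table.junctions.items()
        if j.gene_id == seed.gene_id
        and j.interval.chrom == seed.interval.chrom
        and seed.interval.gap_to(j.interval) <= max_dist
    ]
    closure = {seed_key}
    changed = True
    while changed:
        changed = False
        bounds = set()
        for key in closure:
            iv = table.junctions[key].interval
            bounds.add(("s", iv.start))
            bounds.add(("e", iv.end))
        for key in window:
            if key in closure:
                continue
            iv = table.junctions[key].interval
            if ("s", iv.start) in bounds or ("e", iv.end) in bounds:
                closure.add(key)
                changed = True
    return closure - {seed_key}


def neighbour_introns(
    intron_id: str,
    annotation: Annotation,
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[str]:
    """Introns whose exact-match junctions are neighbours of this intron's.

    Applies the same (i)-(iii) rules with the intron's own interval as the
    original junction and every other derived intron of the gene as candidate.
    """
    intron = annotation.intron_by_id(intron_id)
    out = []
    for other in annotation.introns(intron.gene_id):
        if other.id == intron_id:
            continue
        if _is_neighbour(intron.interval, other.interval, annotation, max_dist):
            out.append(other.id)
    return sorted(out)
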