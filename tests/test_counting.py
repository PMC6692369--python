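import re

import numpy as np
import pytest

from juncture.counting import (
    JunctionTable,
    classify_motif,
    count_strictly_intronic,
    extract_junction_reads,
    n_segments,
    segment_boundaries,
)

# Cassette gene GX: annotated introns [200,300), [400,500), [200,500) on chr1.


def junction_read(pos0, left, gap, right, qname="r"):
    return (qname, "chr1", pos0, f"{left}M{gap}N{right}M")


class TestOverhangFilter:
    def test_annotated_junction_overhang_below_3_rejected(self, cassette_annotation, sam_writer):
        # 2M100N98M over annotated [200,300): overhang 2 < 3
        sam = sam_writer([junction_read(198, 2, 100, 98)])
        table = extract_junction_reads(sam, cassette_annotation)
        assert table.total() == 0

    def test_annotated_junction_overhang_3_accepted(self, cassette_annotation, sam_writer):
        sam = sam_writer([junction_read(197, 3, 100, 97)])
        table = extract_junction_reads(sam, cassette_annotation)
        assert table.counts(("chr1", 200, 300)) == (1, 0)

    def test_novel_junction_needs_overhang_6(self, cassette_annotation, sam_writer):
        # [250, 350) is not a derived intron but lies inside GX's span
        rejected = sam_writer([("r1", "chr1", 245, "5M100N95M")], "a.sam")
        accepted = sam_writer([("r2", "chr1", 244, "6M100N94M")], "b.sam")
        assert extract_junction_reads(rejected, cassette_annotation).total() == 0
        table = extract_junction_reads(accepted, cassette_annotation)
        assert table.counts(("chr1", 250, 350)) == (1, 0)
        assert table.junctions[("chr1", 250, 350)].status == "novel"

    def test_raising_thresholds_never_increases_counts(self, cassette_annotation, sam_writer):
        rng = np.random.default_rng(0)
        records = []
        for i in range(200):
            left = int(rng.integers(1, 50))
            records.append(junction_read(200 - left, left, 100, 50 - left, f"r{i}"))
        sam = sam_writer(records)
        totals = []
        for oh in (1, 3, 5, 10, 20):
            t = extract_junction_reads(sam, cassette_annotation,
                                       min_overhang_annotated=oh)
            totals.append(t.total())
        assert totals == sorted(totals, reverse=True)


class TestGapEnumeration:
    def test_multi_gap_read_counts_once_per_gap(self, cassette_annotation, sam_writer):
        # spans both inclusion introns: 10M100N100M100N10M from 190
        sam = sam_writer([("r", "chr1", 190, "10M100N100M100N10M")])
        table = extract_junction_reads(sam, cassette_annotation)
        assert table.counts(("chr1", 200, 300)) == (1, 0)
        assert table.counts(("chr1", 400, 500)) == (1, 0)

    def test_indels_do_not_contribute_to_overhang(self, cassette_annotation, sam_writer):
        # 10M3I2M100N98M: flanking M block left of the gap is 2 nt -> rejected
        sam = sam_writer([("r", "chr1", 188, "10M3I2M100N98M")])
        assert extract_junction_reads(sam, cassette_annotation).total() == 0

    def test_order_independence(self, cassette_annotation, sam_writer):
        rng = np.random.default_rng(1)
        records = [junction_read(200 - 10, 10, 100, 40, f"r{i}") for i in range(20)]
        records += [junction_read(400 - 20, 20, 100, 30, f"s{i}") for i in range(10)]
        shuffled = list(records)
        rng.shuffle(shuffled)
        t1 = extract_junction_reads(sam_writer(records, "o1.sam"), cassette_annotation)
        t2 = extract_junction_reads(sam_writer(shuffled, "o2.sam"), cassette_annotation)
        assert t1.count_a == t2.count_a

    def test_gap_outside_any_gene_discarded_and_logged(self, cassette_annotation, sam_writer):
        sam = sam_writer([("r", "chr1", 5000, "10M100N10M")])
        table = extract_junction_reads(sam, cassette_annotation)
        assert table.total() == 0
        assert table.discarded_outside_genes == 1


def brute_force_gap_counts(records, annotation, min_annot=3, min_novel=6):
    """Independent oracle: enumerate N gaps by string-parsing CIGARs."""
    counts = {}
    for _, chrom, pos, cigar in records:
        ops = re.findall(r"(\d+)([MIDNSHP=X])", cigar)
        ref = pos
        blocks = []  # (op, reflen, refstart)
        for n_s, op in ops:
            n = int(n_s)
            blocks.append((op, n, ref))
            if op in "MDN=X":
                ref += n
        for k, (op, n, start) in enumerate(blocks):
            if op != "N":
                continue
            left = next((b[1] for b in reversed(blocks[:k]) if b[0] in "M=X"), 0)
            right = next((b[1] for b in blocks[k + 1:] if b[0] in "M=X"), 0)
            overhang = min(left, right)
            annotated = annotation.intron_at(chrom, start, start + n) is not None
            if not annotated and annotation.assign_gene(chrom, start, start + n) is None:
                continue
            if overhang >= (min_annot if annotated else min_novel):
                key = (chrom, start, start + n)
                counts[key] = counts.get(key, 0) + 1
    return counts


def test_extraction_matches_string_parsing_oracle(cassette_annotation, sam_writer):
    rng = np.random.default_rng(7)
    records = []
    for i in range(50):
        left = int(rng.integers(1, 20))
        gap_start = int(rng.choice([200, 400, 250]))
        gap = {200: 100, 400: 100, 250: 100}[gap_start]
        right = int(rng.integers(1, 20))
        records.append((f"r{i}", "chr1", gap_start - left, f"{left}M{gap}N{right}M"))
    sam = sam_writer(records)
    table = extract_junction_reads(sam, cassette_annotation)
    assert table.count_a == brute_force_gap_counts(records, cassette_annotation)


class TestSegmentation:
    @pytest.mark.parametrize(
        "length,expected", [(50, 2), (400, 2), (999, 2), (1000, 2), (1500, 3), (2500, 5)]
    )
    def test_segment_count_formula(self, length, expected):
        assert n_segments(length) == expected

    def test_equal_width_with_remainder_in_last(self):
        bounds = segment_boundaries(0, 2503)
        assert len(bounds) == 6  # 5 segments
        widths = [b - a for a, b in zip(bounds, bounds[1:])]
        assert widths == [500, 500, 500, 500, 503]

    def test_intron_400_has_two_200nt_segments(self):
        assert segment_boundaries(1000, 1400) == (1000, 1200, 1400)


class TestStrictlyIntronic:
    def test_read_crossing_exon_boundary_not_counted(self, cassette_annotation, sam_writer):
        # half exon, half intron around the 5'SS at 200
        sam = sam_writer([("r", "chr1", 180, "40M")])
        segs = count_strictly_intronic(sam, cassette_annotation)
        assert all(s.total("A") == 0 for s in segs.values())

    def test_fully_intronic_read_counted_in_midpoint_segment(self, cassette_annotation, sam_writer):
        sam = sam_writer([("r", "chr1", 210, "30M")])  # midpoint 225 in [200,250)
        segs = count_strictly_intronic(sam, cassette_annotation)
        sc = segs["GX:200-300"]
        assert sc.counts_a == [1, 0]

    def test_nested_intron_counts_for_every_container(self, cassette_annotation, sam_writer):
        # read inside [200,300) is also inside the skip intron [200,500)
        sam = sam_writer([("r", "chr1", 210, "30M")])
        segs = count_strictly_intronic(sam, cassette_annotation)
        assert segs["GX:200-500"].total("A") == 1

    def test_junction_reads_excluded(self, cassette_annotation, sam_writer):
        sam = sam_writer([("r", "chr1", 190, "10M100N10M")])
        segs = count_strictly_intronic(sam, cassette_annotation)
        assert all(s.total("A") == 0 for s in segs.values())

    def test_segment_sums_equal_intron_totals(self, cassette_annotation, sam_writer):
        rng = np.random.default_rng(3)
        records = [
            ("r%d" % i, "chr1", int(rng.integers(200, 270)), "30M") for i in range(40)
        ]
        sam = sam_writer(records)
        segs = count_strictly_intronic(sam, cassette_annotation)
        sc = segs["GX:200-300"]
        assert sum(sc.counts_a) == sc.total("A") == 40


class TestMotif:
    @pytest.mark.parametrize(
        "strand,donor,acceptor,expected",
        [
            ("+", "GT", "AG", "canonical"),
            ("-", "CT", "AC", "canonical"),
            ("+", "GC", "AG", "non_canonical"),
            ("-", "GT", "AG", "non_canonical"),
            ("+", None, "AG", "unknown"),
        ],
    )
    def test_motif_classification(self, strand, donor, acceptor, expected):
        assert classify_motif(strand, donor, acceptor) == expected
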