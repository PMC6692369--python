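import pysam
import pytest
from scipy.stats import hypergeom

from juncture.annotation import Annotation, GenomicInterval, Transcript


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p by hypergeometric enumeration.

    Independent of any exact-test routine: walks every table with the
    observed margins and sums the probabilities not exceeding the observed
    table's (probability-mass ordering).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def iv(chrom, start, end, strand="+"):
    return GenomicInterval(chrom, start, end, strand)


@pytest.fixture
def cassette_annotation():
    """One '+' gene with a cassette exon: inclusion + skipping transcripts.

    Introns: I1=[200,300) and I2=[400,500) (inclusion), I3=[200,500) (skip).
    """
    t_inc = Transcript(
        "GX.inc", "GX", (iv("chr1", 100, 200), iv("chr1", 300, 400), iv("chr1", 500, 600))
    )
    t_skip = Transcript("GX.skip", "GX", (iv("chr1", 100, 200), iv("chr1", 500, 600)))
    return Annotation([t_inc, t_skip])


@pytest.fixture
def nested_transcript_annotation():
    """A gene whose short transcript breaks neighbour condition (i)/(ii).

    T_long has introns [1100,1200) and [1300,1400); T_short contains only the
    second intron but its span [1200,1500) does not subsume the first.
    """
    t_long = Transcript(
        "GY.long",
        "GY",
        (iv("chr1", 1000, 1100), iv("chr1", 1200, 1300), iv("chr1", 1400, 1500)),
    )
    t_short = Transcript(
        "GY.short", "GY", (iv("chr1", 1200, 1300), iv("chr1", 1400, 1500))
    )
    return Annotation([t_long, t_short])


@pytest.fixture
def distant_junction_annotation():
    """Single-transcript gene whose two introns are 6100 nt apart."""
    t = Transcript(
        "GZ.t1",
        "GZ",
        (iv("chr2", 0, 100), iv("chr2", 200, 6300), iv("chr2", 6400, 6500)),
    )
    return Annotation([t])


@pytest.fixture
def toy_gtf_text():
    """GTF for the cassette gene plus a second gene sharing a donor with two
    acceptors (two distinct derived introns from one donor)."""
    lines = []

    def exon(chrom, s0, e0, strand, gene, tx):
        attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
        lines.append(
            f"{chrom}\ttest\texon\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attrs}"
        )

    exon("chr1", 100, 200, "+", "GX", "GX.inc")
    exon("chr1", 300, 400, "+", "GX", "GX.inc")
    exon("chr1", 500, 600, "+", "GX", "GX.inc")
    exon("chr1", 100, 200, "+", "GX", "GX.skip")
    exon("chr1", 500, 600, "+", "GX", "GX.skip")
    # shared donor at 2200, acceptors at 2400 / 2500
    exon("chr3", 2000, 2200, "-", "GA", "GA.t1")
    exon("chr3", 2400, 2600, "-", "GA", "GA.t1")
    exon("chr3", 2000, 2200, "-", "GA", "GA.t2")
    exon("chr3", 2500, 2600, "-", "GA", "GA.t2")
    return "\n".join(lines) + "\n"


def write_sam(path, records, chrom_lengths=None):
    """Write minimal single-end SAM records: (qname, chrom, pos0, cigar)."""
    chrom_lengths = chrom_lengths or {"chr1": 100000, "chr2": 100000, "chr3": 100000}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_lengths.items())],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, chrom, pos, cigar in records:
            seg = pysam.AlignedSegment(header=header)
            seg.query_name = qname
            seg.reference_name = chrom
            seg.reference_start = pos
            seg.cigarstring = cigar
            seg.flag = 0
            seg.mapping_quality = 255
            out.write(seg)
    return str(path)


@pytest.fixture
def sam_writer(tmp_path):
    def _write(records, name="reads.sam", chrom_lengths=None):
        return write_sam(tmp_path / name, records, chrom_lengths)

    return _write
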