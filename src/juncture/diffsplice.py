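"""Differential junction usage: Fisher test, PSI, calling and classification.

The differential statistic is Fisher's exact test on the 2x2 table

    rows:    (junction reads, summed neighbour-junction reads)
    columns: (condition A, condition B)

which normalises each junction against the local splicing activity of its
gene. Percent spliced in follows

    PSI = mean( J / (J_sameStart + J),  J / (J_sameEnd + J) )

where J_sameStart / J_sameEnd sum the neighbours sharing the junction's start
or end boundary; a term whose denominator is zero is dropped, and PSI is
undefined if both are. A junction is called differential when p < 0.001,
|dPSI| > 0.15 (strict) and at least 7 reads support it in one condition.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .counting import JunctionTable

__all__ = [
    "Thresholds",
    "PsiInputs",
    "SplicingCall",
    "fisher_two_sided",
    "psi",
    "call_differential",
    "classify_event",
]


@dataclass(frozen=True)
class Thresholds:
    """Calling thresholds; p and dPSI are strict, min_reads is inclusive."""

    p_value: float = 0.001
    dpsi: float = 0.15
    min_reads: int = 7


@dataclass(frozen=True)
class PsiInputs:
    j: int
    j_same_start: int
    j_same_end: int

    def __post_init__(self) -> None:
        if min(self.j, self.j_same_start, self.j_same_end) < 0:
            raise ValueError("PSI inputs must be non-negative")


@dataclass
class SplicingCall:
    junction_key: tuple
    gene_id: str
    status: str
    strand: str
    p_value: float
    psi_a: float | None
    psi_b: float | None
    dpsi: float | None
    count_a: int
    count_b: int
    differential: bool
    reason: str = ""
    category: str = ""

    @property
    def max_reads(self) -> int:
        return max(self.count_a, self.count_b)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Probability-mass ordering: the p-value sums hypergeometric probabilities
    of all tables with the observed margins whose probability does not exceed
    the observed one. A zero margin is a degenerate table carrying no
    evidence and returns 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("Fisher table entries must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(min(1.0, stats.fisher_exact([[a, b], [c, d]]).pvalue))


def psi(inputs: PsiInputs) -> float | None:
    """PSI as the mean of the two boundary-shared ratios; None if undefined."""
    terms = []
    for same in (inputs.j_same_start, inputs.j_same_end):
        denom = same + inputs.j
        if denom > 0:
            terms.append(inputs.j / denom)
    if not terms:
        return None
    return sum(terms) / len(terms)


def _boundary_sums(key, neighbours, table: JunctionTable, condition: str):
    """Neighbour counts split by shared start / shared end boundary."""
    j = table.junctions[key]
    same_start = same_end = 0
    for nk in neighbours:
        n = table.junctions[nk]
        cnt = table.counts(nk)[0 if condition == "A" else 1]
        if n.interval.start == j.interval.start:
            same_start += cnt
        if n.interval.end == j.interval.end:
            same_end += cnt
    return same_start, same_end


def call_differential(
    table: JunctionTable,
    neighbour_sets: dict[tuple, list[tuple]],
    thresholds: Thresholds = Thresholds(),
) -> list[SplicingCall]:
    """One SplicingCall per junction, sorted by coordinate.

    Junctions with undefined PSI in either condition are carried through with
    differential=False and a reason code rather than dropped, so reports stay
    complete.
    """
    calls = []
    for key in sorted(table.junctions):
        j = table.junctions[key]
        a, b = table.counts(key)
        neighbours = neighbour_sets.get(key, [])
        c = sum(table.counts(nk)[0] for nk in neighbours)
        d = sum(table.counts(nk)[1] for nk in neighbours)
        p = fisher_two_sided(a, b, c, d)
        psis = {}
        for cond, count in (("A", a), ("B", b)):
            ss, se = _boundary_sums(key, neighbours, table, cond)
            psis[cond] = psi(PsiInputs(count, ss, se))
        psi_a, psi_b = psis["A"], psis["B"]
        if psi_a is None or psi_b is None:
            calls.append(
                SplicingCall(
                    key, j.gene_id, j.status, j.interval.strand, p,
                    psi_a, psi_b, None, a, b, False, reason="psi_undefined",
                )
            )
            continue
        dpsi = abs(psi_a - psi_b)
        differential = (
            p < thresholds.p_value
            and dpsi > thresholds.dpsi
            and max(a, b) >= thresholds.min_reads
        )
        calls.append(
            SplicingCall(
                key, j.gene_id, j.status, j.interval.strand, p,
                psi_a, psi_b, dpsi, a, b, differential,
            )
        )
    return calls


def classify_event(
    call: SplicingCall,
    competitors: set[tuple],
    table: JunctionTable,
) -> str:
    """Competition type of a junction given its competing-junction closure.

    No competitors -> no_competitor. One competitor sharing the donor-side
    boundary (interval start on '+', end on '-') -> Alt3SS; sharing the
    acceptor side -> Alt5SS. A three-junction closure matching two inclusion
    junctions plus their spanning skip junction -> CEx. Everything else is
    complex.
    """
    if not competitors:
        return "no_competitor"
    seed = table.junctions[call.junction_key].interval
    strand = call.strand
    if len(competitors) == 1:
        (ck,) = competitors
        comp = table.junctions[ck].interval
        shares_start = comp.start == seed.start
        shares_end = comp.end == seed.end
        if shares_start != shares_end:
            donor_side_shared = shares_start if strand == "+" else shares_end
            return "Alt3SS" if donor_side_shared else "Alt5SS"
        return "complex"
    closure = [seed] + [table.junctions[k].interval for k in competitors]
    if len(closure) == 3 and _is_cassette(closure):
        return "CEx"
    return "complex"


def _is_cassette(ivs) -> bool:
    """Closure {(d, a1), (d2, a), (d, a)} with a1 <= d2: cassette geometry."""
    from itertools import permutations

    for skip, inc1, inc2 in permutations(ivs):
        if (
            inc1.start == skip.start
            and inc2.end == skip.end
            and inc1.end <= inc2.start
            and inc1.end > skip.start
            and inc2.start < skip.end
        ):
            return True
    return False
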