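"""Branch-site assignment, 5'SS-BS distances, matched sampling, KS test and
the B-complex span arithmetic.

Short introns constrain the physical distance between the 5' splice site and
the branch-site adenosine inside the pre-catalytic (B) spliceosome: the 5'SS
region pairs with U6 in a 17-nt extended helix and the BS region with U2 in a
14-nt helix, the two helices sitting ~15 nm apart (~21 nt of extended RNA).
Spanning both helices plus the gap therefore needs ~52 intron nucleotides —
the arithmetic reproduced here, together with the splicing-construct rule
that shortening an intron between the 5'SS and the BS conserves the
BS-to-3'SS block.

Distance analysis compares 5'SS-BS distances of retained introns against a
length-matched background (decile binning, sampling with replacement at a
fixed oversampling factor) using the two-sided two-sample
Kolmogorov-Smirnov (Smirnov-Kolmogorov) test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Intron

__all__ = [
    "BranchSiteRecord",
    "GeometryModel",
    "DistanceResult",
    "assign_branch_site",
    "ss5_bs_distance",
    "length_matched_sample",
    "ks_two_sample",
    "extended_span_nt",
    "min_span_nt",
    "construct_distance",
    "branch_sites_from_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BranchSiteRecord:
    """A candidate branch adenosine with lariat-sequencing support."""

    intron_id: str
    bs_pos: int  # 0-based genomic position of the BS adenosine
    lariat_mismatch_count: int
    confidence: str = "high"  # high | moderate (pooled in analysis)

    def __post_init__(self) -> None:
        if self.lariat_mismatch_count < 1:
            raise ValueError("lariat_mismatch_count must be a positive integer")


@dataclass(frozen=True)
class GeometryModel:
    """B-complex geometry: helix lengths, inter-helix gap and RNA rise."""

    helix_5ss_nt: int = 17
    helix_bs_nt: int = 14
    gap_nm: float = 15.0
    rise_nm_per_nt: float = 0.7

    def __post_init__(self) -> None:
        if min(self.helix_5ss_nt, self.helix_bs_nt) < 0 or self.gap_nm < 0:
            raise ValueError("geometry lengths must be non-negative")


@dataclass
class DistanceResult:
    retained_distances: list[int]
    matched_background_distances: list[int]
    ks_d: float
    ks_p: float
    oversampling: int


def assign_branch_site(
    intron: Intron, candidates: list[BranchSiteRecord]
) -> BranchSiteRecord | None:
    """Pick one branch site per intron: the most lariat-supported candidate.

    Ties go to the candidate closest to the 3'SS (strand-aware), then to the
    lowest genomic coordinate, so the choice is deterministic regardless of
    input order.
    """
    iv = intron.interval
    for c in candidates:
        if not iv.start <= c.bs_pos < iv.end:
            raise ValueError(f"branch site {c.bs_pos} outside intron {intron.id}")
    if not candidates:
        return None

    def dist_to_3ss(c: BranchSiteRecord) -> int:
        return iv.end - 1 - c.bs_pos if iv.strand == "+" else c.bs_pos - iv.start

    return min(
        candidates,
        key=lambda c: (-c.lariat_mismatch_count, dist_to_3ss(c), c.bs_pos),
    )


def ss5_bs_distance(intron: Intron, bs: BranchSiteRecord) -> int:
    """Intron nucleotides strictly 5' of the BS adenosine (strand-aware)."""
    iv = intron.interval
    if not iv.start <= bs.bs_pos < iv.end:
        raise ValueError(f"branch site {bs.bs_pos} outside intron {intron.id}")
    if iv.strand == "+":
        return bs.bs_pos - iv.start
    return iv.end - 1 - bs.bs_pos


def length_matched_sample(
    background_lengths: np.ndarray,
    retained_lengths: np.ndarray,
    oversampling: int = 5,
    seed: int = 0,
    n_bins: int = 10,
) -> np.ndarray:
    """Indices into the background matching the retained length distribution.

    Retained lengths are cut at their deciles; each retained intron draws
    `oversampling` background introns with replacement from its own bin. An
    empty bin falls back to the nearest non-empty one (logged).
    """
    background_lengths = np.asarray(background_lengths)
    retained_lengths = np.asarray(retained_lengths)
    if len(retained_lengths) == 0 or len(background_lengths) == 0:
        return np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    edges = np.quantile(retained_lengths, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    # right-inclusive top edge so the max retained length lands in the last bin
    bg_bins = np.clip(np.searchsorted(edges, background_lengths, side="right") - 1,
                      0, len(edges) - 2)
    ret_bins = np.clip(np.searchsorted(edges, retained_lengths, side="right") - 1,
                       0, len(edges) - 2)
    in_range = (background_lengths >= edges[0]) & (background_lengths <= edges[-1])
    members: dict[int, np.ndarray] = {}
    for b in range(len(edges) - 1):
        members[b] = np.flatnonzero(in_range & (bg_bins == b))
    non_empty = [b for b, idx in members.items() if len(idx)]
    if not non_empty:
        # background entirely outside the retained range: use everything
        members = {0: np.arange(len(background_lengths))}
        non_empty = [0]
        ret_bins = np.zeros_like(ret_bins)
        logger.warning("no background intron within the retained length range")
    picks = []
    for b in ret_bins:
        if len(members.get(b, ())) == 0:
            nearest = min(non_empty, key=lambda x: abs(x - b))
            logger.warning("empty length bin %d; falling back to bin %d", b, nearest)
            b = nearest
        picks.append(rng.choice(members[b], size=oversampling, replace=True))
    return np.concatenate(picks)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def extended_span_nt(model: GeometryModel = GeometryModel()) -> int:
    """RNA nucleotides spanning the inter-helix gap in extended conformation."""
    if model.rise_nm_per_nt <= 0:
        raise ValueError("rise_nm_per_nt must be positive")
    return round(model.gap_nm / model.rise_nm_per_nt)


def min_span_nt(model: GeometryModel = GeometryModel()) -> int:
    """Minimum intron nucleotides between 5'SS and BS: both helices + gap."""
    return model.helix_5ss_nt + extended_span_nt(model) + model.helix_bs_nt


def construct_distance(
    ref_intron_len: int, ref_distance: int, new_intron_len: int
) -> int:
    """5'SS-BS distance of a truncated/extended splicing construct.

    Length changes are confined to the stretch between the 5'SS and the BS,
    so the BS-to-3'SS block (ref_intron_len - ref_distance) is conserved and
    the new distance is new_intron_len minus that block.
    """
    conserved = ref_intron_len - ref_distance
    if new_intron_len <= conserved:
        raise ValueError(
            f"new intron length {new_intron_len} cannot conserve the "
            f"{conserved}-nt BS-to-3'SS block"
        )
    return new_intron_len - conserved


def branch_sites_from_table(table: pd.DataFrame) -> dict[str, list[BranchSiteRecord]]:
    """Group a BS TSV table (as DataFrame) into per-intron candidate lists."""
    out: dict[str, list[BranchSiteRecord]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(row.intron_id, []).append(
            BranchSiteRecord(
                row.intron_id,
                int(row.bs_pos),
                int(row.lariat_mismatch_count),
                str(row.confidence),
            )
        )
    return out
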