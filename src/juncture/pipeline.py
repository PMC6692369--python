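"""End-to-end orchestration: simulate/load -> count -> call -> IR -> BS -> report.

The pipeline is deterministic under a fixed seed and writes every
intermediate as a headered TSV so each stage can be re-loaded and checked
independently. Configuration is a flat mapping (or YAML file) with either a
``simulate`` block or an ``inputs`` block naming the GTF, the two SAM files
and optionally a branch-site table.
"""
from __future__ import annotations

import dataclasses
import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import branchsite as bs
from . import counting, diffsplice, neighbours, retention, simulate
from .annotation import Annotation, load_annotation, write_gtf

__all__ = [
    "ConfigError",
    "PipelineParams",
    "PipelineResult",
    "run_pipeline",
    "summarize_events",
    "LENGTH_CLASSES",
]

logger = logging.getLogger(__name__)

LENGTH_CLASSES = (
    ("<200", 0, 200),
    ("200-1kb", 200, 1000),
    ("1-5kb", 1000, 5000),
    (">5kb", 5000, float("inf")),
)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass(frozen=True)
class PipelineParams:
    """Analysis parameters; defaults are the published operating point."""

    min_overhang_annotated: int = 3
    min_overhang_novel: int = 6
    neighbour_dist: int = 5000
    p_thresh: float = 0.001
    dpsi_thresh: float = 0.15
    min_reads: int = 7
    ir_fold: float = 2.0
    ir_p: float = 0.001
    oversample: int = 5
    bs_length_cap: int = 250


@dataclass
class PipelineResult:
    annotation: Annotation
    junction_table: counting.JunctionTable
    calls: list
    competitor_sets: dict
    ir_records: dict
    bs_assignments: dict
    distance_result: bs.DistanceResult | None
    geometry: pd.DataFrame
    summary: pd.DataFrame
    outdir: str | None = None


def _load_config(config) -> dict:
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    return config


def _prepare_inputs(config: dict, outdir: str | None):
    """Resolve the annotation, SAM paths and BS table from the config."""
    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        seed = int(sim_kwargs.pop("seed", 0))
        known = {f.name for f in dataclasses.fields(simulate.SimulationConfig)}
        unknown = set(sim_kwargs) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        sim_config = simulate.SimulationConfig(seed=seed, **sim_kwargs)
        annotation = simulate.simulate_annotation(sim_config)
        workdir = outdir or tempfile.mkdtemp(prefix="juncture_sim_")
        os.makedirs(workdir, exist_ok=True)
        gtf_path = os.path.join(workdir, "simulated.gtf")
        write_gtf(annotation, gtf_path)
        sam_paths = {}
        for cond in ("A", "B"):
            reads = simulate.simulate_alignments(annotation, sim_config, cond)
            path = os.path.join(workdir, f"simulated_{cond}.sam")
            simulate.write_sam(reads, annotation, path)
            sam_paths[cond] = path
        bs_table = simulate.simulate_branch_sites(
            annotation, simulate.BranchSiteDetectionModel(), seed=seed + 1
        )
        bs_table.to_csv(os.path.join(workdir, "branch_sites.tsv"), sep="\t",
                        index=False)
        return annotation, sam_paths, bs_table, seed
    if "inputs" not in config:
        raise ConfigError("config needs a 'simulate' or 'inputs' block")
    inputs = config["inputs"]
    for key in ("gtf", "sam_a", "sam_b"):
        if key not in inputs:
            raise ConfigError(f"missing required input key: '{key}'")
    annotation = load_annotation(inputs["gtf"])
    sam_paths = {"A": inputs["sam_a"], "B": inputs["sam_b"]}
    bs_table = None
    if inputs.get("bs_table"):
        bs_table = pd.read_csv(inputs["bs_table"], sep="\t")
    return annotation, sam_paths, bs_table, int(config.get("seed", 0))


def run_pipeline(config, outdir: str | None = None) -> PipelineResult:
    """Run every stage and (optionally) write all TSV outputs to ``outdir``."""
    config = _load_config(config)
    outdir = outdir or config.get("outdir")
    params = PipelineParams(**config.get("params", {}))
    annotation, sam_paths, bs_table, seed = _prepare_inputs(config, outdir)

    table = counting.JunctionTable()
    segments: dict[str, counting.SegmentCounts] = {}
    for cond in ("A", "B"):
        counting.extract_junction_reads(
            sam_paths[cond], annotation, cond,
            params.min_overhang_annotated, params.min_overhang_novel,
            table=table,
        )
        counting.count_strictly_intronic(
            sam_paths[cond], annotation, cond, segments=segments
        )
    logger.info("junctions: %d detected, %d read observations",
                len(table.junctions), table.total())

    neighbour_sets = neighbours.build_neighbour_sets(
        annotation, table, params.neighbour_dist
    )
    thresholds = diffsplice.Thresholds(params.p_thresh, params.dpsi_thresh,
                                       params.min_reads)
    calls = diffsplice.call_differential(table, neighbour_sets, thresholds)
    competitor_sets = {
        c.junction_key: neighbours.competing_junctions(
            c.junction_key, table, params.neighbour_dist
        )
        for c in calls
    }
    for c in calls:
        c.category = diffsplice.classify_event(
            c, competitor_sets[c.junction_key], table
        )
    logger.info("differential junctions: %d", sum(c.differential for c in calls))

    neighbour_intron_sets = {
        intron.id: neighbours.neighbour_introns(
            intron.id, annotation, params.neighbour_dist
        )
        for intron in annotation.introns()
    }
    ir_records = retention.build_intron_records(
        annotation, segments, neighbour_intron_sets
    )
    calls_by_key = {c.junction_key: c for c in calls}
    ir_thresholds = retention.IrThresholds(params.ir_fold, params.ir_p,
                                           params.p_thresh)
    for intron in annotation.introns():
        rec = ir_records[intron.id]
        retention.ir_value(rec)
        retention.differential_ir(rec)
        iv = intron.interval
        retention.call_retention(
            rec, calls_by_key, competitor_sets,
            (iv.chrom, iv.start, iv.end), ir_thresholds,
        )
    n_retained = sum(r.retained for r in ir_records.values())
    logger.info("retained introns: %d", n_retained)

    bs_assignments: dict[str, bs.BranchSiteRecord] = {}
    distance_result = None
    if bs_table is not None and len(bs_table):
        candidates = bs.branch_sites_from_table(bs_table)
        for intron_id, cands in candidates.items():
            try:
                intron = annotation.intron_by_id(intron_id)
            except KeyError:
                continue
            chosen = bs.assign_branch_site(intron, cands)
            if chosen is not None:
                bs_assignments[intron_id] = chosen
        distance_result = _distance_analysis(
            annotation, ir_records, bs_assignments, params, seed
        )

    geometry = geometry_table()
    summary = summarize_events(calls, ir_records, competitor_sets, annotation)

    result = PipelineResult(
        annotation, table, calls, competitor_sets, ir_records,
        bs_assignments, distance_result, geometry, summary, outdir,
    )
    if outdir:
        _write_outputs(result, segments, outdir)
    return result


def _distance_analysis(annotation, ir_records, bs_assignments, params, seed):
    """Fig-1d-style contrast: retained vs length-matched unaffected introns."""
    cap = params.bs_length_cap
    retained, background = [], []
    for intron in annotation.introns():
        if intron.id not in bs_assignments or intron.length >= cap:
            continue
        d = bs.ss5_bs_distance(intron, bs_assignments[intron.id])
        rec = ir_records.get(intron.id)
        if rec is not None and rec.retained:
            retained.append((intron.length, d))
        else:
            background.append((intron.length, d))
    if len(retained) < 3 or len(background) < 3:
        logger.info("too few introns with branch sites for distance analysis")
        return None
    ret_len = np.array([l for l, _ in retained])
    bg_len = np.array([l for l, _ in background])
    idx = bs.length_matched_sample(bg_len, ret_len, params.oversample, seed)
    matched = [background[i][1] for i in idx]
    ret_d = [d for _, d in retained]
    d_stat, p = bs.ks_two_sample(ret_d, matched)
    return bs.DistanceResult(ret_d, matched, d_stat, p, params.oversample)


def geometry_table(model: bs.GeometryModel = bs.GeometryModel()) -> pd.DataFrame:
    """The B-complex span arithmetic as a labelled table."""
    rows = [
        ("helix_5ss_nt", model.helix_5ss_nt),
        ("helix_bs_nt", model.helix_bs_nt),
        ("gap_nm", model.gap_nm),
        ("extended_span_nt", bs.extended_span_nt(model)),
        ("min_5ss_bs_span_nt", bs.min_span_nt(model)),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value"])


def summarize_events(calls, ir_records, competitor_sets=None,
                     annotation=None) -> pd.DataFrame:
    """Event-type tallies and retained-intron length-class tallies.

    Differential junctions sharing one competing-junction closure are one
    event (a cassette exon contributes up to three differential junctions but
    is counted once); retained introns are the RI events.
    """
    competitor_sets = competitor_sets or {}
    retained = [r for r in ir_records.values() if r.retained]
    retained_keys = {
        r.supporting_junction for r in retained if r.supporting_junction
    }
    seen_closures = set()
    category_counts = {k: 0 for k in ("Alt5SS", "Alt3SS", "CEx", "complex",
                                      "no_competitor", "RI")}
    for c in calls:
        # retained-intron junctions are reported under RI, not double-counted
        if not c.differential or c.junction_key in retained_keys:
            continue
        closure = frozenset(
            competitor_sets.get(c.junction_key, set()) | {c.junction_key}
        )
        if closure in seen_closures:
            continue
        seen_closures.add(closure)
        category_counts[c.category] = category_counts.get(c.category, 0) + 1
    category_counts["RI"] = len(retained)
    total = sum(category_counts.values())
    rows = [
        ("event", name, count, count / total if total else 0.0)
        for name, count in category_counts.items()
    ]
    length_counts = {name: 0 for name, _, _ in LENGTH_CLASSES}
    for r in retained:
        for name, lo, hi in LENGTH_CLASSES:
            if lo <= r.length < hi:
                length_counts[name] += 1
                break
    n_ret = len(retained)
    rows += [
        ("retained_intron_length", name, count, count / n_ret if n_ret else 0.0)
        for name, count in length_counts.items()
    ]
    return pd.DataFrame(rows, columns=["group", "name", "count", "proportion"])


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        chrom, start, end = c.junction_key
        rows.append(
            dict(
                chrom=chrom, start=start, end=end, strand=c.strand,
                gene_id=c.gene_id, status=c.status, p_value=c.p_value,
                psi_a=c.psi_a, psi_b=c.psi_b, dpsi=c.dpsi,
                count_a=c.count_a, count_b=c.count_b,
                differential=c.differential, category=c.category,
                reason=c.reason,
            )
        )
    return pd.DataFrame(rows)


def ir_to_frame(ir_records) -> pd.DataFrame:
    rows = []
    for r in ir_records.values():
        rows.append(
            dict(
                intron_id=r.intron_id, length=r.length, n_segments=r.n_segments,
                robust_ir_a=r.robust_ir_a, robust_ir_b=r.robust_ir_b,
                fold_change=r.fold_change, p_ir=r.p_ir,
                supporting_junction=(
                    "" if r.supporting_junction is None
                    else "{}:{}-{}".format(*r.supporting_junction)
                ),
                retained=r.retained, direction=r.direction, reason=r.reason,
            )
        )
    return pd.DataFrame(rows)


def junctions_to_frame(table: counting.JunctionTable) -> pd.DataFrame:
    rows = []
    for key in sorted(table.junctions):
        j = table.junctions[key]
        a, b = table.counts(key)
        rows.append(
            dict(
                chrom=key[0], start=key[1], end=key[2],
                strand=j.interval.strand, status=j.status, motif=j.motif,
                count_a=a, count_b=b, gene_id=j.gene_id,
            )
        )
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, segments, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)

    def write(df, name):
        df.to_csv(os.path.join(outdir, name), sep="\t", index=False)

    write(junctions_to_frame(result.junction_table), "junctions.tsv")
    write(calls_to_frame(result.calls), "calls.tsv")
    write(ir_to_frame(result.ir_records), "intron_retention.tsv")
    seg_rows = []
    for sc in segments.values():
        for i in range(sc.n_segments):
            seg_rows.append(
                dict(
                    intron_id=sc.intron_id, segment=i,
                    start=sc.boundaries[i], end=sc.boundaries[i + 1],
                    count_a=sc.counts_a[i], count_b=sc.counts_b[i],
                )
            )
    write(pd.DataFrame(seg_rows), "segment_counts.tsv")
    if result.distance_result is not None:
        dr = result.distance_result
        dist_rows = [dict(group="retained", distance=d)
                     for d in dr.retained_distances]
        dist_rows += [dict(group="background", distance=d)
                      for d in dr.matched_background_distances]
        write(pd.DataFrame(dist_rows), "bs_distances.tsv")
        write(
            pd.DataFrame(
                [dict(ks_D=dr.ks_d, ks_p=dr.ks_p, oversampling=dr.oversampling,
                      n_retained=len(dr.retained_distances),
                      n_background=len(dr.matched_background_distances))]
            ),
            "bs_distance_test.tsv",
        )
    write(result.geometry, "geometry.tsv")
    write(result.summary, "summary.tsv")
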