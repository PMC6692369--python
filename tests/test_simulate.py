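import numpy as np
import pytest

from juncture.annotation import write_gtf
from juncture.counting import count_strictly_intronic, extract_junction_reads
from juncture.simulate import (
    BranchSiteDetectionModel,
    SimulationConfig,
    cassette_skip_intron,
    event_type,
    ri_intron,
    simulate_alignments,
    simulate_annotation,
    simulate_branch_sites,
    write_sam,
    _junction_rates,
)


def only(event):
    mix = {k: 0.0 for k in ("CEx", "Alt5SS", "Alt3SS", "RI", "constitutive")}
    mix[event] = 1.0
    return mix


class TestAnnotationSimulation:
    def test_fixed_seed_gives_byte_identical_gtf(self):
        config = SimulationConfig(n_genes=30, seed=11)
        g1 = write_gtf(simulate_annotation(config))
        g2 = write_gtf(simulate_annotation(config))
        assert g1 == g2

    def test_all_cassette_genes_have_three_introns(self):
        config = SimulationConfig(n_genes=10, event_mix=only("CEx"), seed=2)
        ann = simulate_annotation(config)
        assert len(ann.genes) == 10
        for gene_id in ann.genes:
            assert len(ann.introns(gene_id)) == 3
            skip = cassette_skip_intron(ann, gene_id)
            assert len(skip.transcript_ids) == 1

    def test_degenerate_ri_length_model(self):
        config = SimulationConfig(
            n_genes=8, event_mix=only("RI"), ri_intron_length=(80, 80), seed=3
        )
        ann = simulate_annotation(config)
        for gene_id in ann.genes:
            assert ri_intron(ann, gene_id).length == 80

    def test_empty_config_gives_empty_annotation(self):
        ann = simulate_annotation(SimulationConfig(n_genes=0))
        assert ann.genes == {}

    def test_event_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(event_mix={"CEx": 0.5})

    def test_strands_alternate_and_types_follow_mix(self):
        config = SimulationConfig(n_genes=40, seed=5)
        ann = simulate_annotation(config)
        strands = {g.span.strand for g in ann.genes.values()}
        assert strands == {"+", "-"}
        types = {event_type(gid) for gid in ann.genes}
        assert types <= {"CEx", "Alt5SS", "Alt3SS", "RI", "constitutive"}


class TestReadSimulation:
    def test_full_inclusion_gives_zero_skip_reads(self):
        config = SimulationConfig(
            n_genes=10, event_mix=only("CEx"), psi_by_condition=(1.0, 1.0), seed=4
        )
        ann = simulate_annotation(config)
        reads = simulate_alignments(ann, config, "A")
        skip_intervals = {
            (cassette_skip_intron(ann, g).interval.start,
             cassette_skip_intron(ann, g).interval.end)
            for g in ann.genes
        }
        for r in reads:
            if "N" not in r.cigar:
                continue
            left, rest = r.cigar.split("M", 1)
            gap = int(rest.split("N")[0])
            gap_start = r.pos + int(left)
            assert (gap_start, gap_start + gap) not in skip_intervals

    def test_zero_retention_gives_zero_intronic_reads(self):
        config = SimulationConfig(
            n_genes=10, event_mix=only("RI"), ir_by_condition=(0.0, 0.0),
            baseline_retention=0.0, seed=6,
        )
        ann = simulate_annotation(config)
        reads = simulate_alignments(ann, config, "A")
        assert all("N" in r.cigar for r in reads)

    def test_read_length_below_two_rejected(self):
        config = SimulationConfig(n_genes=1, read_length=1)
        ann = simulate_annotation(config)
        with pytest.raises(ValueError, match="read_length"):
            simulate_alignments(ann, config, "A")

    def test_determinism_under_seed(self):
        config = SimulationConfig(n_genes=15, seed=7)
        ann = simulate_annotation(config)
        assert simulate_alignments(ann, config, "A") == simulate_alignments(
            ann, config, "A"
        )
        assert simulate_alignments(ann, config, "A") != simulate_alignments(
            ann, config, "B"
        )

    def test_every_record_parseable_and_inside_its_gene(self, tmp_path):
        config = SimulationConfig(n_genes=25, seed=8)
        ann = simulate_annotation(config)
        reads = simulate_alignments(ann, config, "A")
        sam = write_sam(reads, ann, str(tmp_path / "a.sam"))
        table = extract_junction_reads(sam, ann, "A", min_overhang_annotated=0)
        assert table.discarded_outside_genes == 0
        assert all(j.status == "annotated" for j in table.junctions.values())
        segs = count_strictly_intronic(sam, ann, "A")
        n_intronic = sum(1 for r in reads if "N" not in r.cigar)
        # every gap-free read is strictly intronic by construction
        assert sum(s.total("A") for s in segs.values()) >= n_intronic

    def test_counts_match_poisson_expectations(self, tmp_path):
        config = SimulationConfig(n_genes=150, depth=50, seed=9)
        ann = simulate_annotation(config)
        reads = simulate_alignments(ann, config, "A")
        observed = {}
        for r in reads:
            if "N" not in r.cigar:
                continue
            left, rest = r.cigar.split("M", 1)
            gap = int(rest.split("N")[0])
            start = r.pos + int(left)
            observed[(start, start + gap)] = observed.get((start, start + gap), 0) + 1
        rates = _junction_rates(ann, config, 0)
        introns = {i.id: i for i in ann.introns()}
        ok = total = 0
        for intron_id, lam in rates.items():
            if lam < 5:
                continue
            iv = introns[intron_id].interval
            obs = observed.get((iv.start, iv.end), 0)
            total += 1
            ok += abs(obs - lam) <= 3 * np.sqrt(lam)
        assert total > 100
        assert ok / total >= 0.93


class TestBranchSiteSimulation:
    def test_full_detection_annotates_every_intron(self):
        config = SimulationConfig(n_genes=20, seed=10)
        ann = simulate_annotation(config)
        model = BranchSiteDetectionModel(short_rate_250=1.0, short_rate_100=1.0)
        table = simulate_branch_sites(ann, model, seed=1)
        assert set(table.intron_id) == {i.id for i in ann.introns()}

    def test_zero_detection_gives_empty_table(self):
        config = SimulationConfig(n_genes=20, seed=10)
        ann = simulate_annotation(config)
        model = BranchSiteDetectionModel(short_rate_250=0.0, short_rate_100=0.0)
        assert len(simulate_branch_sites(ann, model, seed=1)) == 0

    def test_empty_annotation_gives_empty_table(self):
        ann = simulate_annotation(SimulationConfig(n_genes=0))
        assert len(simulate_branch_sites(ann, seed=1)) == 0

    def test_overall_detection_rate_near_target(self):
        config = SimulationConfig(n_genes=800, seed=12)
        ann = simulate_annotation(config)
        model = BranchSiteDetectionModel()
        table = simulate_branch_sites(ann, model, seed=13)
        n_introns = len(ann.introns())
        assert n_introns >= 1500
        frac = table.intron_id.nunique() / n_introns
        assert abs(frac - model.overall_rate) <= 0.05

    def test_short_introns_detected_less_often(self):
        model = BranchSiteDetectionModel()
        assert (
            model.detection_probability(80)
            < model.detection_probability(250)
            < model.detection_probability(2000)
        )
        assert model.detection_probability(100) == pytest.approx(0.27, abs=1e-9)
        assert model.detection_probability(250) == pytest.approx(0.45, abs=1e-9)

    def test_branch_sites_lie_inside_their_introns(self):
        config = SimulationConfig(n_genes=60, seed=14)
        ann = simulate_annotation(config)
        table = simulate_branch_sites(ann, seed=15)
        for row in table.itertuples(index=False):
            iv = ann.intron_by_id(row.intron_id).interval
            assert iv.start <= row.bs_pos < iv.end
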