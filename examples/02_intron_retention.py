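"""Quantify intron retention on a retention-only cohort.

Every gene carries one short intron whose unspliced fraction rises from 0.2
(condition A) to 0.8 (condition B) — a 4-fold IR change. Retention calls need
two lines of evidence: a differentially used junction without competitors,
and a >= 2-fold change in the segment-median IR with Fisher p < 0.001 on the
intron-vs-neighbour read counts.
"""
import tempfile

from juncture.pipeline import ir_to_frame, run_pipeline

config = {
    "simulate": {
        "n_genes": 50,
        "seed": 7,
        "depth": 100,
        "event_mix": {"CEx": 0.0, "Alt5SS": 0.0, "Alt3SS": 0.0,
                      "RI": 1.0, "constitutive": 0.0},
        "ir_by_condition": [0.2, 0.8],
    }
}

result = run_pipeline(config, outdir=tempfile.mkdtemp(prefix="juncture_"))
ir = ir_to_frame(result.ir_records)
retained = ir[ir.retained]
print(f"{len(ir)} introns quantified, {len(retained)} called retained\n")
print(retained[["intron_id", "length", "robust_ir_a", "robust_ir_b",
                "fold_change", "p_ir", "direction"]].head(8).to_string(index=False))
print(
    "\nfold_change should cluster near the simulated 4-fold; direction 'B' "
    "marks retention increasing in condition B. Flanking constitutive "
    "introns serve as the within-gene coverage denominator and are not "
    "called."
)
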