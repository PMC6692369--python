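"""Simulate a two-condition cohort with a cassette-exon inclusion shift and
call differential splicing.

A 60-gene cohort is drawn with inclusion PSI 0.25 in condition A and 0.75 in
condition B for alternative events. The pipeline extracts junction reads,
tests each junction against its neighbour junctions with Fisher's exact
test, computes PSI from boundary-sharing junction counts and classifies the
competition type of every differential junction.
"""
import tempfile

from juncture.pipeline import calls_to_frame, run_pipeline

config = {
    "simulate": {
        "n_genes": 60,
        "seed": 42,
        "depth": 80,
        "psi_by_condition": [0.25, 0.75],
    }
}

result = run_pipeline(config, outdir=tempfile.mkdtemp(prefix="juncture_"))

calls = calls_to_frame(result.calls)
diff = calls[calls.differential]
print(f"{len(calls)} junctions tested, {len(diff)} differential\n")
print(diff[["chrom", "start", "end", "p_value", "psi_a", "psi_b",
            "dpsi", "category"]].head(8).to_string(index=False))
print("\nEvent summary (each competing-junction closure counted once):")
print(result.summary.to_string(index=False))
print(
    "\ndPSI near 0.5 on cassette junctions reflects the simulated inclusion "
    "shift; RI rows are retained introns called from intronic coverage."
)
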