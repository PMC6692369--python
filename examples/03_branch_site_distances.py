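"""Compare 5'SS-to-branch-site distances of retained vs unaffected introns.

Retained short introns (<250 nt) are contrasted against a length-matched
background sampled at 5x with replacement from unaffected introns carrying a
branch-site annotation, using the two-sided two-sample Kolmogorov-Smirnov
test. Branch-site annotation is simulated with the length-dependent
detection bias seen in lariat-sequencing surveys (short introns are
annotated less often).
"""
import tempfile

import numpy as np

from juncture.pipeline import run_pipeline

config = {
    "simulate": {
        "n_genes": 200,
        "seed": 11,
        "depth": 100,
        "ir_by_condition": [0.2, 0.8],
    }
}

result = run_pipeline(config, outdir=tempfile.mkdtemp(prefix="juncture_"))
dr = result.distance_result
if dr is None:
    print("too few branch-site-annotated introns in this draw")
else:
    ret = np.array(dr.retained_distances)
    bg = np.array(dr.matched_background_distances)
    print(f"retained introns with BS annotation: {len(ret)}")
    print(f"matched background (oversampling {dr.oversampling}x): {len(bg)}")
    print(f"median 5'SS-BS distance: retained {np.median(ret):.0f} nt, "
          f"background {np.median(bg):.0f} nt")
    print(f"KS D = {dr.ks_d:.3f}, p = {dr.ks_p:.3g}")
    print(
        "\nThe simulator places branch sites 18-44 nt upstream of the 3'SS "
        "regardless of retention status, so distances differ only through "
        "intron length; with length matching the two groups should be "
        "similar (p typically > 0.01) — the analysis machinery, not a "
        "biological contrast, is what this example exercises."
    )
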