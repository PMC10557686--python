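#!/usr/bin/env python
"""Single-molecule co-dependency scan: promoter anchor vs nine neighbors.

One candidate actuates with per-fiber correlation 0.8 to the promoter; the
other eight are independent with the same marginal.  The scan should rank
the coupled element first by score with q << 0.05.
"""

from pathlib import Path

import fiberhap as fh
from fiberhap import scenarios

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 21

model = scenarios.enhancer_codependency_model(couple_corr=0.8, n_independent=8)
fibers = fh.simulate_fibers(model, 2_000, 300, seed=SEED)
anchor = fh.Peak(model.elements[0].interval, "promoter")
candidates = [fh.Peak(e.interval, e.element_id) for e in model.elements[1:]]
scan = fh.codependency_scan(fibers, anchor, candidates, min_precision=0.95)

with open(OUT / "codependency_scan.tsv", "w") as out:
    out.write("peak_b\tn_span\tprop_a\tprop_b\tobserved\texpected\tscore\tp_value\tq_value\n")
    for r in sorted(scan, key=lambda r: -r.score):
        out.write(
            f"{r.peak_b}\t{r.n_span}\t{r.prop_a:.3f}\t{r.prop_b:.3f}\t{r.observed:.3f}\t"
            f"{r.expected:.3f}\t{r.score:+.3f}\t{r.p_value:.3e}\t{r.q_value:.3e}\n"
        )

best = max(scan, key=lambda r: r.score)
others = [r.score for r in scan if r.peak_b != best.peak_b]
print(
    f"top-ranked candidate: {best.peak_b} "
    f"(score {best.score:+.3f} = observed {best.observed:.3f} - expected {best.expected:.3f}, "
    f"q = {best.q_value:.2e}, {best.n_span} doubly-spanning fibers)"
)
print(f"independent candidates score between {min(others):+.3f} and {max(others):+.3f}")
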