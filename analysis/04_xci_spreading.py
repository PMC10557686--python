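#!/usr/bin/env python
"""Partial region silencing: detection and silenced-cell-fraction recovery.

Simulates a contiguous 200-peak region whose H2 copy is epigenetically
silenced in a fraction f of cells (the XCI-spreading situation on a
derivative chromosome), against 2,000 balanced background peaks.  For each
f the Mann-Whitney region test and the silenced-fraction estimator f-hat are
run; the table shows that f-hat tracks f down to the few-percent regime.
"""

from pathlib import Path

import fiberhap as fh
from fiberhap import scenarios

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 22
FRACTIONS = (0.03, 0.05, 0.10, 0.20, 0.40)

rows = []
for f_true in FRACTIONS:
    model = scenarios.xci_spreading_model(f_true, 200, 2_000)
    fibers = fh.simulate_fibers(model, 10_000, 50, seed=SEED)
    peaks = [fh.Peak(e.interval, e.element_id) for e in model.elements]
    (res,), _ = fh.genome_imbalance_report(
        fibers, peaks, {"silenced_region": scenarios.xci_region(model)},
        min_precision=0.90,
    )
    rows.append((f_true, res))
    print(
        f"f = {f_true:.2f}: median delta {res.median_delta_region:+.1f} points, "
        f"MWU p = {res.p_value:.2e}, f-hat = {res.silenced_fraction_estimate:.3f} "
        f"({res.n_peaks_region} region peaks vs {res.n_peaks_background} background)"
    )

with open(OUT / "xci_recovery.tsv", "w") as out:
    out.write("f_true\tn_peaks_region\tn_peaks_background\tmedian_delta\tmwu_p\tf_hat\n")
    for f_true, r in rows:
        out.write(
            f"{f_true}\t{r.n_peaks_region}\t{r.n_peaks_background}\t"
            f"{r.median_delta_region:.2f}\t{r.p_value:.3e}\t"
            f"{r.silenced_fraction_estimate:.4f}\n"
        )
print("wrote results/xci_recovery.tsv")
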