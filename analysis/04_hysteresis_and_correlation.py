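"""Hysteresis of the toggle switch: branches, balance, and the
ultrasensitivity-hysteresis correlation.

1. On/off dose-response branches for the balanced nonlinear toggle
   (distinct over a finite dose window) and for the same loop with all
   links linear (identical branches: no hysteresis without nonlinearity).
2. Balance scan: bistability requires the two loop links roughly
   matched in strength.
3. Across sampled toggle sets (inhibitory-nonlinear context), the
   fold-increase in apparent nH correlates strongly with the
   bistability-window width.

Writes results/hysteresis/{branches.csv,balance_scan.csv,sweep.csv}.

Usage: python analysis/04_hysteresis_and_correlation.py [n_sets] [seed]
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from morphotoggle import ModelClass, hysteresis_curves
from morphotoggle.examples import toggle_fgf_level, toggle_nonlinear
from morphotoggle.parameter_sweep import (ParameterDraw, balance_scan,
                                          correlate_dnh_window,
                                          records_to_frame,
                                          run_context_sweep)

OUT = Path(__file__).resolve().parents[1] / "results" / "hysteresis"

if __name__ == "__main__":
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 300
    seed = int(sys.argv[2]) if len(sys.argv) > 2 else 7
    OUT.mkdir(parents=True, exist_ok=True)
    F = toggle_fgf_level()

    rows = []
    for label, params in (("nonlinear", toggle_nonlinear()),):
        res = hysteresis_curves(ModelClass.CIPF, params, fgf_level=F)
        for d, off, on in zip(res.off_curve.doses, res.off_curve.responses,
                              res.on_curve.responses):
            rows.append({"model": label, "dose": d, "off": off, "on": on})
        print(f"{label}: window {res.window_lo:.3g}-{res.window_hi:.3g} "
              f"({res.window_decades:.2f} decades)")
    pd.DataFrame(rows).to_csv(OUT / "branches.csv", index=False)

    template = ParameterDraw(toggle_nonlinear(), F, 0.76, 0.3)
    scan = balance_scan(template, np.linspace(0.55, 0.97, 7),
                        np.linspace(0.55, 0.97, 7), axis="strength")
    scan.to_csv(OUT / "balance_scan.csv", index=False)
    frac = scan["bistable"].mean()
    print(f"balance scan: {frac:.0%} of strength combinations bistable")

    records = run_context_sweep("CIPF", 3, n, seed)
    records_to_frame(records).to_csv(OUT / "sweep.csv", index=False)
    r = correlate_dnh_window(records)
    print(f"context 3, n={len(records)}: Pearson r(nH ratio, window) = "
          f"{r:.3f}")
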