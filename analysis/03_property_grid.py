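"""Parameter-space sweep reproducing the qualitative property grid.

For each model class (STI, SUI, CFF, CIPF) and each linearity context
(1 all linear, 2 core nonlinear, 3 inhibitory nonlinear, 4 all
nonlinear), samples parameter sets and scores how FGF changes the BMP
dose response.  Expected pattern: STI decreases the maximum everywhere;
EC50 increases are widespread for SUI/CFF/CIPF; apparent-nH increases
occur only for CFF (nonlinear-inhibition contexts) and CIPF (all
contexts); hysteresis occurs only for CIPF with nonlinear links.

Writes results/property_grid/{records.csv,grid.csv}.

Usage: python analysis/03_property_grid.py [n_per_cell] [seed]
"""
import sys
from pathlib import Path

from morphotoggle.parameter_sweep import (records_to_frame,
                                          run_context_sweep, summarize_grid)

OUT = Path(__file__).resolve().parents[1] / "results" / "property_grid"

if __name__ == "__main__":
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 150
    seed = int(sys.argv[2]) if len(sys.argv) > 2 else 7
    OUT.mkdir(parents=True, exist_ok=True)
    records = []
    for cls in ("STI", "SUI", "CFF", "CIPF"):
        for ctx in (1, 2, 3, 4):
            records += run_context_sweep(cls, ctx, n, seed)
            print(f"swept {cls} context {ctx}")
    records_to_frame(records).to_csv(OUT / "records.csv", index=False)
    grid = summarize_grid(records)
    grid.to_csv(OUT / "grid.csv", index=False)
    pivot = grid.pivot_table(index=["property", "model"], columns="context",
                             values="cell", aggfunc="first")
    print(pivot.to_string())
    print(f"wrote {OUT}/records.csv and grid.csv (n={n}/cell, seed={seed})")
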