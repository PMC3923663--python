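"""Enumerate the 81 cross-inhibition topologies and classify them.

Writes results/topologies/{topologies.csv,class_counts.json} and prints
the class split (expected 9 STI / 18 SUI / 18 CFF / 36 CIPF).
"""
from pathlib import Path

from morphotoggle.topology_space import class_counts, export

OUT = Path(__file__).resolve().parents[1] / "results" / "topologies"

if __name__ == "__main__":
    export(OUT)
    counts = class_counts()
    total = sum(counts.values())
    print(f"{total} topologies: " +
          ", ".join(f"{k}={v}" for k, v in counts.items()))
    print(f"wrote {OUT}/topologies.csv and class_counts.json")
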