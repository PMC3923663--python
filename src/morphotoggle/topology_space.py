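"""Enumeration and classification of the 81 cross-inhibition topologies.

With each pathway reduced to ligand -> intermediate -> target and exactly
one inhibitory link per direction (source tier x target tier, 3 x 3 per
link), there are 81 possible wirings.  Each is classified by where its
links act:

* ``CIPF`` -- the two links close a cycle through both pathways
  (cross-inhibitory positive feedback / toggle switch);
* ``CFF``  -- no cycle, but the B->F link feeds forward onto the branch
  that inhibits the BMP target (coherent feedforward);
* ``STI``  -- one-way inhibition landing directly on the target B_T;
* ``SUI``  -- one-way inhibition landing upstream of B_T.

The split is 9 STI, 18 SUI, 18 CFF and 36 CIPF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List

import pandas as pd

from .model_core import ModelClass

__all__ = ["Topology", "classify", "enumerate_topologies",
           "class_counts", "topologies_to_frame"]

_TIERS = (0, 1, 2)


@dataclass(frozen=True)
class Topology:
    """One cross-inhibition wiring.

    ``fb_*`` is the F-side -> B-side link (source tier on the FGF side,
    target tier on the BMP side); ``bf_*`` the B-side -> F-side link.
    """

    fb_source_tier: int
    fb_target_tier: int
    bf_source_tier: int
    bf_target_tier: int

    def __post_init__(self):
        for t in (self.fb_source_tier, self.fb_target_tier,
                  self.bf_source_tier, self.bf_target_tier):
            if t not in _TIERS:
                raise ValueError(f"tier indices must be 0, 1 or 2, got {t}")

    @property
    def topology_id(self) -> int:
        """Stable integer id: lexicographic rank over the four tiers."""
        return (self.fb_source_tier * 27 + self.fb_target_tier * 9
                + self.bf_source_tier * 3 + self.bf_target_tier)

    @property
    def class_label(self) -> ModelClass:
        return classify(self)


def classify(topology: Topology) -> ModelClass:
    """Classify a topology as STI, SUI, CFF or CIPF.

    The pathway edges run downstream (tier 0 -> 1 -> 2), so:

    * a closed cycle through both sides exists iff each inhibitory link's
      source is reachable from the other link's target, i.e.
      ``bf_source >= fb_target`` and ``fb_source >= bf_target``;
    * otherwise the B->F link matters only if it can reach B_T through
      the F->B link: ``bf_target <= fb_source`` while the loop is open
      (``bf_source < fb_target``), giving a coherent feedforward;
    * otherwise the B->F link is inert for B_T and the class is read off
      the F->B landing tier: the target node itself (STI) or upstream
      of it (SUI).
    """
    t = topology
    if t.bf_source_tier >= t.fb_target_tier and \
            t.fb_source_tier >= t.bf_target_tier:
        return ModelClass.CIPF
    if t.bf_target_tier <= t.fb_source_tier and \
            t.bf_source_tier < t.fb_target_tier:
        return ModelClass.CFF
    if t.fb_target_tier == 2:
        return ModelClass.STI
    return ModelClass.SUI


def enumerate_topologies() -> List[Topology]:
    """All 81 topologies in canonical (lexicographic) order."""
    return [Topology(fs, ft, bs, bt)
            for fs in _TIERS for ft in _TIERS
            for bs in _TIERS for bt in _TIERS]


def class_counts(topologies=None) -> dict:
    """Number of topologies per class label."""
    if topologies is None:
        topologies = enumerate_topologies()
    counts = {c.value: 0 for c in (ModelClass.STI, ModelClass.SUI,
                                   ModelClass.CFF, ModelClass.CIPF)}
    for t in topologies:
        counts[classify(t).value] += 1
    return counts


def topologies_to_frame(topologies=None) -> pd.DataFrame:
    """Tidy table (one row per topology) for CSV export."""
    if topologies is None:
        topologies = enumerate_topologies()
    rows = [{
        "id": t.topology_id,
        "fb_source_tier": t.fb_source_tier,
        "fb_target_tier": t.fb_target_tier,
        "bf_source_tier": t.bf_source_tier,
        "bf_target_tier": t.bf_target_tier,
        "class": classify(t).value,
    } for t in topologies]
    return pd.DataFrame(rows)


def export(outdir: str | Path) -> None:
    """Write the topology table (CSV) and class counts (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    topologies_to_frame().to_csv(outdir / "topologies.csv", index=False)
    (outdir / "class_counts.json").write_text(
        json.dumps(class_counts(), indent=2))
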