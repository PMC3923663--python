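"""Parameter-space sweeps over the four model classes and linearity contexts.

Each sweep draws random parameter sets, measures how a fixed FGF input
changes the BMP dose response of B_T (maximal level, EC50, apparent nH)
and, for the toggle switch, the bistability-window width, then condenses
the results into a qualitative property grid.

Sampling (study conditions; see docs/methods.md for rationale):

* rate constants and the ligand half-saturations are log-uniform over
  two decades, 10^-1 to 10^1;
* the FGF input is set so the FGF-side drive is a log-uniform fraction
  rho in [0.05, 0.5] of the saturated BMP-side drive (FGF modulates the
  response; saturating BMP wins);
* inhibitory-link strengths are uniform on [0.5, 0.99] and expressed as
  the realized fractional suppression at the inhibitor's operating
  level, which fixes the link's half-saturation constant;
* the toggle's return link is positioned relative to the suppressed B_I
  range (balance factor gamma) and the B_T readout threshold relative
  to the full B_I range, with per-context positioning: linear-inhibition
  contexts use a deep, saturating configuration, nonlinear-inhibition
  contexts a balanced, discriminating one.

Contexts: 1 all links linear; 2 core nonlinear; 3 inhibitory links
nonlinear; 4 all nonlinear.  "Nonlinear" means Hill exponent 4; the
ligand-binding step itself stays hyperbolic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import (InhibitoryLink, ModelClass, ModelParameters,
                         hill_activation)
from .memory_analysis import measure_window_decades
from .response_analysis import ResponseChange, measure_response_change

__all__ = [
    "LinearityContext",
    "CONTEXTS",
    "SweepRanges",
    "ParameterDraw",
    "SweepRecord",
    "sample_parameters",
    "run_context_sweep",
    "summarize_grid",
    "balance_scan",
    "correlate_dnh_window",
    "PROPERTY_PREDICATES",
]

NONLINEAR_EXPONENT = 4.0


@dataclass(frozen=True)
class LinearityContext:
    id: int
    core_nonlinear: bool
    inhibitory_nonlinear: bool


CONTEXTS: Dict[int, LinearityContext] = {
    1: LinearityContext(1, False, False),
    2: LinearityContext(2, True, False),
    3: LinearityContext(3, False, True),
    4: LinearityContext(4, True, True),
}


@dataclass(frozen=True)
class SweepRanges:
    """Sampling ranges (log-uniform unless noted)."""

    rate: Tuple[float, float] = (0.1, 10.0)
    rho: Tuple[float, float] = (0.05, 0.5)
    strength: Tuple[float, float] = (0.5, 0.99)        # uniform
    gamma_linear: Tuple[float, float] = (0.1, 0.3)
    gamma_nonlinear: Tuple[float, float] = (0.7, 1.5)
    readout_linear: Tuple[float, float] = (0.05, 0.2)
    readout_nonlinear: Tuple[float, float] = (0.5, 2.0)


@dataclass
class ParameterDraw:
    params: ModelParameters
    fgf_level: float
    strength_fb: float
    rho: float


@dataclass
class SweepRecord:
    model_class: str
    context_id: int
    set_id: int
    seed: int
    change: ResponseChange
    window_decades: float


def _lu(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))


def sample_parameters(context: int | LinearityContext, n: int, seed: int,
                      ranges: Optional[SweepRanges] = None,
                      model_class: ModelClass | str = ModelClass.CIPF
                      ) -> List[ParameterDraw]:
    """Draw ``n`` reproducible parameter sets for one class and context."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ctx = CONTEXTS[context] if isinstance(context, int) else context
    rngs = ranges or SweepRanges()
    mc = ModelClass(model_class)
    rng = np.random.default_rng(seed)
    cn = NONLINEAR_EXPONENT if ctx.core_nonlinear else 1.0
    ninh = NONLINEAR_EXPONENT if ctx.inhibitory_nonlinear else 1.0
    gamma_rng = (rngs.gamma_nonlinear if ctx.inhibitory_nonlinear
                 else rngs.gamma_linear)
    readout_rng = (rngs.readout_nonlinear if ctx.inhibitory_nonlinear
                   else rngs.readout_linear)

    draws = []
    for _ in range(n):
        kc1 = _lu(rng, *rngs.rate); kc3 = _lu(rng, *rngs.rate)
        kc5 = _lu(rng, *rngs.rate)
        K_BI = _lu(rng, *rngs.rate); K_FI = _lu(rng, *rngs.rate)
        K_BT = _lu(rng, *rngs.rate)
        K_tb = _lu(rng, *rngs.rate); K_tf = _lu(rng, *rngs.rate)
        A = kc1 / K_BI
        aF_max = kc3 / K_FI

        rho = _lu(rng, *rngs.rho)
        h = min(rho * A / aF_max, 0.95)
        fgf_level = K_tf * (h / (1.0 - h)) ** (1.0 / cn)
        aF = aF_max * h

        sf = rng.uniform(*rngs.strength)
        kf = aF * ((1.0 - sf) / sf) ** (1.0 / ninh)
        if mc is ModelClass.CIPF:
            gamma = _lu(rng, *gamma_rng)
            kb = gamma * (1.0 - sf) * A
        else:
            sb = rng.uniform(*rngs.strength)
            kb = A * ((1.0 - sb) / sb) ** (1.0 / ninh)
        K_tbt = _lu(rng, *readout_rng) * A

        params = ModelParameters(
            kc1=kc1, kc3=kc3, kc5=kc5,
            K_tb=K_tb, K_tf=K_tf, K_tbt=K_tbt,
            K_BI=K_BI, K_FI=K_FI, K_BT=K_BT,
            n1=1.0, n2=cn, n3=cn,
            fb_link=InhibitoryLink(p=1.0, k=kf, n=ninh),
            bf_link=InhibitoryLink(p=1.0, k=kb, n=ninh),
        )
        draws.append(ParameterDraw(params, fgf_level, sf, rho))
    return draws


def run_context_sweep(model_class, context: int, n: int, seed: int,
                      ranges: Optional[SweepRanges] = None
                      ) -> List[SweepRecord]:
    """One ResponseChange (plus window width for CIPF) per sampled set.

    Failed measurements (degenerate fits) are excluded; more than 20%
    failures aborts with diagnostics.
    """
    mc = ModelClass(model_class)
    draws = sample_parameters(context, n, seed, ranges, mc)
    records, failures = [], 0
    for i, draw in enumerate(draws):
        out = measure_response_change(mc, draw.params, draw.fgf_level)
        if out is None:
            failures += 1
            continue
        change, _, _ = out
        window = (measure_window_decades(draw.params, draw.fgf_level)
                  if mc is ModelClass.CIPF else 0.0)
        records.append(SweepRecord(mc.value, context, i, seed, change,
                                   window))
    if failures > 0.2 * n:
        raise RuntimeError(
            f"{failures}/{n} measurements failed for {mc.value} "
            f"context {context} (seed {seed})")
    return records


# ---------------------------------------------------------------------------
# Property grid
# ---------------------------------------------------------------------------

PROPERTY_PREDICATES: Dict[str, Callable[[SweepRecord], bool]] = {
    "max_decrease": lambda r: r.change.max_ratio < 0.9,
    "ec50_increase": lambda r: r.change.ec50_ratio > 1.1,
    "nh_increase": lambda r: r.change.nh_ratio > 1.1,
    "hysteresis": lambda r: r.window_decades > 0.0,
}


def _cell_label(freq: float) -> str:
    if freq <= 0.0:
        return "absent"
    if freq < 0.10:
        return "rare"
    return "present"


def summarize_grid(records: Sequence[SweepRecord],
                   predicates: Optional[Dict[str, Callable]] = None,
                   min_records: int = 50) -> pd.DataFrame:
    """Frequency-based qualitative grid: one row per
    (property, model, context) with the frequency and the cell label
    (present / rare / absent).  Undersampled cells are flagged."""
    preds = predicates or PROPERTY_PREDICATES
    rows = []
    df_index = {}
    for r in records:
        df_index.setdefault((r.model_class, r.context_id), []).append(r)
    for (model, ctx), recs in sorted(df_index.items()):
        for prop, pred in preds.items():
            freq = float(np.mean([pred(r) for r in recs]))
            rows.append({
                "property": prop, "model": model, "context": ctx,
                "frequency": freq, "cell": _cell_label(freq),
                "n": len(recs), "undersampled": len(recs) < min_records,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Balance scans (toggle loop strength / nonlinearity matching)
# ---------------------------------------------------------------------------

def balance_scan(template: ParameterDraw,
                 fb_values: Sequence[float], bf_values: Sequence[float],
                 axis: str = "strength") -> pd.DataFrame:
    """Scan the two CIPF loop links against each other.

    ``axis='strength'`` scans realized suppressions (the half-saturation
    constants follow); ``axis='exponent'`` scans the two Hill exponents.
    Per grid point the bistability flag and nH ratio are recorded.
    """
    if axis not in ("strength", "exponent"):
        raise ValueError("axis must be 'strength' or 'exponent'")
    base = template.params
    F = template.fgf_level
    A = base.bmp_gain
    aF = base.fgf_gain * float(hill_activation(F, base.K_tf, base.n2))
    rows = []
    for fv in fb_values:
        for bv in bf_values:
            if axis == "strength":
                nf, nb = base.fb_link.n, base.bf_link.n
                kf = aF * ((1.0 - fv) / fv) ** (1.0 / nf)
                kb = A * ((1.0 - bv) / bv) ** (1.0 / nb)
            else:
                nf, nb = float(fv), float(bv)
                kf, kb = base.fb_link.k, base.bf_link.k
            p = base.with_(fb_link=InhibitoryLink(1.0, kf, nf),
                           bf_link=InhibitoryLink(1.0, kb, nb))
            out = measure_response_change(ModelClass.CIPF, p, F)
            window = measure_window_decades(p, F)
            rows.append({
                "fb_value": fv, "bf_value": bv,
                "bistable": window > 0.0,
                "window_decades": window,
                "nh_ratio": out[0].nh_ratio if out else np.nan,
            })
    return pd.DataFrame(rows)


def correlate_dnh_window(records: Sequence[SweepRecord]) -> float:
    """Pearson correlation between the nH fold-increase and the
    bistability-window width across CIPF sweep records (zero windows
    included)."""
    if len(records) < 30:
        raise ValueError("need at least 30 records")
    nhr = np.array([r.change.nh_ratio for r in records])
    win = np.array([r.window_decades for r in records])
    if win.std() == 0 or nhr.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(nhr, win)[0, 1])


def records_to_frame(records: Sequence[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "model": r.model_class, "context": r.context_id,
        "set_id": r.set_id, "seed": r.seed,
        "max_ratio": r.change.max_ratio,
        "ec50_ratio": r.change.ec50_ratio,
        "nh_ratio": r.change.nh_ratio,
        "window_decades": r.window_decades,
    } for r in records])
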