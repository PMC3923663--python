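"""Hysteresis and cellular-memory protocols.

Hysteresis: dose-response branches measured from the 'off' state (FGF
equilibrated, no BMP history) and the 'on' state (pre-stimulated with
saturating BMP) differ over the bistable dose window.  Memory is
classified as none / hysteretic / irreversible by asking whether the
on-state target returns to baseline once BMP is removed: the toggle
switch is at most hysteretic (no BMP drive means no B_I), whereas
auto-regulatory positive feedback can latch irreversibly.

The washout protocol emulates the cell-culture experiment: a strong BMP
pre-stimulus is washed out, the effective dose decays exponentially with
time constant ``residual_tau`` (persistent receptor-level signaling), a
new dose is applied, and the target is read out at a fixed time.  A
receptor inhibitor added at washout sets the residual signal to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import ModelClass, ModelParameters, build_rhs
from .response_analysis import (DoseResponse, compute_dose_response,
                                default_dose_grid, _halfmax_dose, _wide_grid)
from .steady_state import find_all_steady_states, integrate_to_steady

__all__ = [
    "HysteresisResult",
    "WashoutProtocol",
    "MemoryClass",
    "hysteresis_curves",
    "measure_window_decades",
    "classify_memory",
    "simulate_washout",
]

#: relative branch difference above which doses count as bistable
BRANCH_DIFF_REL = 0.01


@dataclass
class HysteresisResult:
    off_curve: DoseResponse
    on_curve: DoseResponse
    window_lo: float
    window_hi: float
    window_size: float          # window_hi - window_lo (dose units; 0 if none)
    window_decades: float       # log10(window_hi / window_lo); 0 if none


class MemoryClass(str, __import__("enum").Enum):
    NONE = "none"
    HYSTERETIC = "hysteretic"
    IRREVERSIBLE = "irreversible"


@dataclass
class WashoutProtocol:
    prestim_dose: float
    prestim_duration: float
    residual_tau: float
    reapplied_doses: np.ndarray
    readout_time: float
    inhibitor_applied: bool = False

    def __post_init__(self):
        if self.prestim_duration <= 0 or self.readout_time <= 0:
            raise ValueError("durations must be positive")
        if self.residual_tau < 0:
            raise ValueError("residual_tau must be non-negative")
        self.reapplied_doses = np.asarray(self.reapplied_doses, dtype=float)

    @property
    def effective_tau(self) -> float:
        return 0.0 if self.inhibitor_applied else self.residual_tau


def _window_from_branches(doses, off, on):
    scale = max(float(off.max()), float(on.max()), 1e-300)
    differ = np.abs(on - off) > BRANCH_DIFF_REL * scale
    if not differ.any():
        return 0.0, 0.0, 0.0, 0.0
    idx = np.nonzero(differ)[0]
    lo, hi = float(doses[idx[0]]), float(doses[idx[-1]])
    step = float(np.log10(doses[1] / doses[0])) if len(doses) > 1 else 0.0
    return lo, hi, hi - lo, float(np.log10(hi / lo)) + step


def hysteresis_curves(model_class, params: ModelParameters,
                      dose_grid: Optional[np.ndarray] = None,
                      fgf_level: float = 0.0) -> HysteresisResult:
    """Off- and on-branch dose responses and the bistability window.

    The window is the maximal dose interval over which the branches
    differ by more than 1% (relative to the curve maximum).
    """
    if dose_grid is None:
        dose_grid = default_dose_grid(params)
    off = compute_dose_response(model_class, params, dose_grid, fgf_level,
                                init_policy="off")
    on = compute_dose_response(model_class, params, dose_grid, fgf_level,
                               init_policy="on")
    lo, hi, size, decades = _window_from_branches(
        off.doses, off.responses, on.responses)
    return HysteresisResult(off, on, lo, hi, size, decades)


def measure_window_decades(params: ModelParameters,
                           fgf_level: float) -> float:
    """Bistability-window width (log10 decades) for a CIPF parameter set,
    measured on the same transition-anchored dose span the sweep-level
    Hill fits use (see response_analysis.measure_response_change)."""
    wide = _wide_grid(params)
    y1 = compute_dose_response(ModelClass.CIPF, params, wide,
                               fgf_level).responses
    if y1.max() <= 0:
        return 0.0
    top = 10.0 * _halfmax_dose(wide, y1)
    span = np.geomspace(top / 100.0, top, 36)
    res = hysteresis_curves(ModelClass.CIPF, params, span, fgf_level)
    return res.window_decades


def classify_memory(model_class, params: ModelParameters,
                    fgf_level: float = 0.0,
                    saturating_factor: float = 100.0) -> MemoryClass:
    """Classify the target's memory as none, hysteretic or irreversible.

    The system is driven to its 'on' state at a saturating dose, the
    dose is then removed (FGF held constant) and the state relaxed; the
    final target level is compared with the never-stimulated baseline.
    Irreversible means the target stays more than 10x above baseline.
    """
    mc = ModelClass(model_class)
    rhs = build_rhs(mc, params)
    sat = saturating_factor * params.K_tb

    base, _, _ = integrate_to_steady(rhs, [0.0, 0.0, 0.0], 0.0, fgf_level)
    on, _, _ = integrate_to_steady(rhs, [0.0, 0.0, 0.0], sat, fgf_level)
    relaxed, _, _ = integrate_to_steady(rhs, on, 0.0, fgf_level,
                                        t_max=200.0)
    scale = max(float(on[2]), 1e-12)
    baseline = float(base[2])
    final = float(relaxed[2])
    if final > 10.0 * baseline + 1e-6 * scale:
        return MemoryClass.IRREVERSIBLE
    if mc is ModelClass.CIPF:
        window = hysteresis_curves(mc, params,
                                   fgf_level=fgf_level).window_size
        if window > 0:
            return MemoryClass.HYSTERETIC
    return MemoryClass.NONE


def simulate_washout(model_class, params: ModelParameters,
                     protocol: WashoutProtocol,
                     fgf_level: float = 0.0) -> pd.DataFrame:
    """BMP washout experiment in silico.

    Populations pretreated with the pre-stimulus dose ('on') or with
    vehicle ('off') are washed, the effective dose decays as
    ``reapplied + prestim * exp(-t / residual_tau)`` (or drops to the
    reapplied dose immediately when the receptor inhibitor is applied),
    and B_T is read out at ``protocol.readout_time`` after washout.

    Returns a tidy frame with columns (initial_state, reapplied_dose,
    response).
    """
    if protocol.readout_time <= 0:
        raise ValueError("readout must come after washout")
    mc = ModelClass(model_class)
    rhs = build_rhs(mc, params)
    tau = protocol.effective_tau

    inits = {}
    for label, dose in (("on", protocol.prestim_dose), ("off", 0.0)):
        y, _, _ = integrate_to_steady(
            rhs, [0.0, 0.0, 0.0], dose, fgf_level,
            t_max=max(protocol.prestim_duration, 50.0))
        inits[label] = y

    rows = []
    for label, y0 in inits.items():
        prestim = protocol.prestim_dose if label == "on" else 0.0
        for d in protocol.reapplied_doses:
            def f(t, y):
                b_eff = d + (prestim * np.exp(-t / tau) if tau > 0 else 0.0)
                return rhs(np.maximum(y, 0.0), b_eff, fgf_level)
            sol = solve_ivp(f, (0.0, protocol.readout_time), y0,
                            method="LSODA", rtol=1e-8, atol=1e-11)
            rows.append({"initial_state": label,
                         "reapplied_dose": float(d),
                         "response": float(max(sol.y[2, -1], 0.0))})
    return pd.DataFrame(rows)
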