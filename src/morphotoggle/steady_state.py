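"""Steady states of the cross-inhibition models.

The non-feedback classes (STI, SUI, CFF) form a cascade, so their steady
state follows by sequential substitution and is unique.  The toggle
switch (CIPF) couples B_I and F_I; its fixed points are found from the
open-loop characteristic: cutting the B_I -| F_I connection, clamping
the loop input at ``u`` and following it once around the loop gives

    g(u) = aB * inh_fb( aF * inh_bf(u) )

with ``aB = (kc1/K_BI) * hill(B)`` and ``aF = (kc3/K_FI) * hill(F)``.
``g`` is nondecreasing (a composition of two decreasing maps), so the
closed-loop fixed points are the crossings of ``g`` with the identity
and stable/unstable fixed points alternate.  Bistability means three
crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import (ModelClass, ModelParameters, SystemState,
                         build_rhs, hill_activation, inhibition_factor)

__all__ = [
    "SteadyStateResult",
    "OpenLoopCharacteristic",
    "integrate_to_steady",
    "closed_form_bt",
    "open_loop_characteristic",
    "cipf_stable_branches",
    "find_all_steady_states",
]


@dataclass
class SteadyStateResult:
    states: List[SystemState]
    stability_flags: List[bool]
    c_b: float                 # saturated BMP signal driving B_T production
    converged: bool
    residual: float

    @property
    def stable_states(self) -> List[SystemState]:
        return [s for s, ok in zip(self.states, self.stability_flags) if ok]


@dataclass
class OpenLoopCharacteristic:
    u_grid: np.ndarray
    g_values: np.ndarray
    fixed_points: np.ndarray       # crossings of g(u) = u, sorted
    stability: np.ndarray          # bool per fixed point
    bistable: bool


# ---------------------------------------------------------------------------
# Numerical integration to steady state
# ---------------------------------------------------------------------------

def integrate_to_steady(rhs: Callable, init, B: float, F: float,
                        tol: float = 1e-9, t_max: Optional[float] = None,
                        max_doublings: int = 3):
    """Integrate ``dy/dt = rhs(y, B, F)`` until the state is stationary.

    Returns ``(state_array, converged, residual)`` where ``residual`` is
    the max absolute derivative at the final state relative to the state
    scale.  On non-convergence ``t_max`` is doubled up to
    ``max_doublings`` times; failure is reported, never silently
    truncated.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    y0 = np.asarray(init, dtype=float)
    if t_max is None:
        t_max = 50.0

    def f(t, y):
        return rhs(np.maximum(y, 0.0), B, F)

    y = y0
    horizon = float(t_max)
    for _ in range(max_doublings + 1):
        sol = solve_ivp(f, (0.0, horizon), y, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        y = np.maximum(sol.y[:, -1], 0.0)
        scale = max(1.0, float(np.max(np.abs(y))))
        residual = float(np.max(np.abs(rhs(y, B, F)))) / scale
        if residual < tol:
            return y, True, residual
        horizon *= 2.0
    return y, False, residual


# ---------------------------------------------------------------------------
# Closed forms for the cascade classes
# ---------------------------------------------------------------------------

def closed_form_bt(model_class: ModelClass | str, params: ModelParameters,
                   B, F: float):
    """Exact steady-state B_T for STI, SUI or CFF by sequential
    substitution (vectorized over the dose ``B``).  CIPF is rejected:
    its loop has no general closed form.
    """
    mc = ModelClass(model_class)
    p = params
    if mc is ModelClass.CIPF:
        raise ValueError("CIPF has no closed-form steady state")
    if mc is ModelClass.AUTOREG:
        raise ValueError("AUTOREG steady state is not a cascade")
    aB = p.bmp_gain * hill_activation(B, p.K_tb, p.n1)
    aF = p.fgf_gain * hill_activation(F, p.K_tf, p.n2)
    if mc is ModelClass.STI:
        B_I = aB
        F_I = aF
        return (p.kc5 / p.K_BT) * hill_activation(B_I, p.K_tbt, p.n3) \
            * inhibition_factor(F_I, p.fb_link)
    if mc is ModelClass.SUI:
        F_I = aF
        B_I = aB * inhibition_factor(F_I, p.fb_link)
        return (p.kc5 / p.K_BT) * hill_activation(B_I, p.K_tbt, p.n3)
    # CFF: B_I is the free core, it inhibits F_I, and F_I inhibits B_T
    B_I = aB
    F_I = aF * inhibition_factor(B_I, p.bf_link)
    return (p.kc5 / p.K_BT) * hill_activation(B_I, p.K_tbt, p.n3) \
        * inhibition_factor(F_I, p.fb_link)


def closed_form_state(model_class, params: ModelParameters, B: float,
                      F: float) -> SystemState:
    """Full (B_I, F_I, B_T) cascade steady state for STI/SUI/CFF."""
    mc = ModelClass(model_class)
    p = params
    aB = p.bmp_gain * hill_activation(B, p.K_tb, p.n1)
    aF = p.fgf_gain * hill_activation(F, p.K_tf, p.n2)
    if mc is ModelClass.SUI:
        F_I = aF
        B_I = aB * inhibition_factor(F_I, p.fb_link)
    elif mc is ModelClass.CFF:
        B_I = aB
        F_I = aF * inhibition_factor(B_I, p.bf_link)
    else:  # STI
        B_I, F_I = aB, aF
    B_T = float(closed_form_bt(mc, p, B, F))
    return SystemState(float(B_I), float(F_I), B_T)


# ---------------------------------------------------------------------------
# CIPF open-loop characteristic
# ---------------------------------------------------------------------------

def _loop_gains(params: ModelParameters, B: float, F: float):
    aB = params.bmp_gain * float(hill_activation(B, params.K_tb, params.n1))
    aF = params.fgf_gain * float(hill_activation(F, params.K_tf, params.n2))
    return aB, aF


def open_loop_characteristic(params: ModelParameters, B: float, F: float,
                             u_grid: Optional[np.ndarray] = None,
                             n_grid: int = 400) -> OpenLoopCharacteristic:
    """Open-loop characteristic of the CIPF loop at inputs (B, F)."""
    p = params
    aB, aF = _loop_gains(p, B, F)

    def g(u):
        return aB * inhibition_factor(
            aF * inhibition_factor(u, p.bf_link), p.fb_link)

    if aB <= 0.0:
        u = np.linspace(0.0, 1.0, 8)
        return OpenLoopCharacteristic(u, np.zeros_like(u),
                                      np.array([0.0]), np.array([True]),
                                      False)

    if u_grid is None:
        top = aB * (1.0 + 1e-9)
        small = min(p.bf_link.k, aB) * 1e-9
        u_grid = np.unique(np.concatenate([
            [0.0], np.geomspace(small, top, n_grid),
            np.linspace(0.0, top, n_grid // 4),
        ]))
    gv = g(u_grid)
    h = gv - u_grid

    roots: List[float] = [float(u_grid[i]) for i in np.nonzero(h == 0.0)[0]]
    sign = np.sign(h)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(lambda u: g(u) - u,
                            u_grid[i], u_grid[i + 1],
                            xtol=1e-14 * (1 + aB), rtol=1e-13))
    roots = sorted(roots)
    fps: List[float] = []
    for r in roots:
        if not fps or abs(r - fps[-1]) > 1e-8 * (1.0 + abs(r)):
            fps.append(r)
    if len(fps) % 2 == 0:
        # missed a tangency/narrow crossing: retry denser before giving up
        if n_grid < 4000:
            return open_loop_characteristic(p, B, F, None, n_grid * 4)
        raise RuntimeError("open-loop characteristic: even crossing count; "
                           "u_grid does not bracket all crossings")
    stability = np.array([i % 2 == 0 for i in range(len(fps))])
    return OpenLoopCharacteristic(u_grid, gv, np.array(fps), stability,
                                  bistable=len(fps) >= 3)


def cipf_stable_branches(params: ModelParameters, B: float, F: float):
    """Lowest and highest stable B_I of the CIPF loop (equal when
    monostable), plus the bistability flag."""
    ch = open_loop_characteristic(params, B, F)
    stable = ch.fixed_points[ch.stability]
    return float(stable[0]), float(stable[-1]), ch.bistable


def cipf_bt_from_bi(params: ModelParameters, B_I) -> np.ndarray | float:
    p = params
    return (p.kc5 / p.K_BT) * hill_activation(B_I, p.K_tbt, p.n3)


# ---------------------------------------------------------------------------
# Multi-start steady-state search
# ---------------------------------------------------------------------------

def find_all_steady_states(model_class, params: ModelParameters,
                           B: float, F: float,
                           tol: float = 1e-9) -> SteadyStateResult:
    """All stable steady states at fixed inputs (B, F), deduplicated.

    Cascade classes have a unique state (closed form, verified by the
    residual); CIPF states come from the open-loop characteristic.
    """
    mc = ModelClass(model_class)
    p = params
    rhs = build_rhs(mc, p)
    c_b = p.bmp_gain * float(hill_activation(B, p.K_tb, p.n1))

    if mc is ModelClass.CIPF:
        ch = open_loop_characteristic(p, B, F)
        aF = p.fgf_gain * float(hill_activation(F, p.K_tf, p.n2))
        states, flags = [], []
        for bi, st in zip(ch.fixed_points, ch.stability):
            fi = aF * float(inhibition_factor(bi, p.bf_link))
            bt = float(cipf_bt_from_bi(p, bi))
            states.append(SystemState(float(bi), fi, bt))
            flags.append(bool(st))
    elif mc is ModelClass.AUTOREG:
        # multi-start integration: off and strongly-on initial conditions
        lo, ok1, _ = integrate_to_steady(rhs, [0.0, 0.0, 0.0], B, F, tol)
        hi0 = [10.0 * p.bmp_gain + 10.0 * p.autoreg.kc_a / p.K_BI, 0.0, 0.0]
        hi, ok2, _ = integrate_to_steady(rhs, hi0, B, F, tol)
        states = [SystemState(*lo)]
        flags = [True]
        if abs(hi[0] - lo[0]) > 1e-6 * (1.0 + abs(hi[0])):
            states.append(SystemState(*hi))
            flags.append(True)
    else:
        states = [closed_form_state(mc, p, B, F)]
        flags = [True]

    residual = 0.0
    for s in states:
        residual = max(residual, float(np.max(np.abs(
            rhs(s.as_array(), B, F)))) / max(1.0, s.B_I, s.F_I, s.B_T))
    return SteadyStateResult(states, flags, c_b,
                             converged=residual < max(tol, 1e-7),
                             residual=residual)
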