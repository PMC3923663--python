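"""Multiple expression thresholds and 1D tissue border formation.

Two BMP target genes can be driven by two toggle loops sharing the same
morphogen inputs.  Perturbations at the loop level (the strength of
either inhibitory link, or the intermediate's turnover) shift the
target's EC50; perturbations downstream of the loop (target production
or turnover) change only its amplitude.  Distinct EC50s translate into
distinct expression borders within the same pair of opposing morphogen
gradients.

The tissue model is a row of independent cells spanning [0, L] um.  BMP
decays from the right edge and FGF from the left (exponential profiles
with optional background); each cell computes its steady-state B_T from
the local ligand levels.  The expression border is where B_T crosses
half its tissue maximum; for ratio-reading (toggle) cells it coincides
with the signaling "equivalence point" where the BMP- and FGF-side
drives balance, which makes the relative border position invariant
under proportional rescaling of the tissue and both gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .model_core import (InhibitoryLink, ModelClass, ModelParameters,
                         hill_activation)
from .response_analysis import (compute_dose_response, fit_hill,
                                _halfmax_dose, _wide_grid)

__all__ = [
    "GradientProfile",
    "GradientFit",
    "TissuePattern",
    "DualLoopModel",
    "LOOP_LEVEL_PARAMS",
    "DOWNSTREAM_PARAMS",
    "perturb",
    "dual_ec50_analysis",
    "fit_exponential_gradient",
    "threshold_lengthscale",
    "simulate_tissue",
    "equivalence_point",
    "scaling_test",
]


@dataclass(frozen=True)
class GradientProfile:
    """Exponential ligand profile c(x) = A * exp(-d/lambda) + b, where
    ``d`` is the distance from the source edge ('left' or 'right')."""

    A: float
    lam: float
    b: float = 0.0
    source: str = "left"

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("length scale lambda must be positive")
        if self.source not in ("left", "right"):
            raise ValueError("source must be 'left' or 'right'")

    def concentration(self, x, L: float):
        x = np.asarray(x, dtype=float)
        d = x if self.source == "left" else (L - x)
        out = self.A * np.exp(-d / self.lam) + self.b
        return out if out.ndim else float(out)

    def scaled(self, s: float) -> "GradientProfile":
        """Proportionally rescaled profile (lambda -> s * lambda)."""
        return replace(self, lam=self.lam * s)


@dataclass
class GradientFit:
    A: float
    lam: float
    b: float
    ok: bool


@dataclass
class TissuePattern:
    L: float
    x: np.ndarray
    bmp: np.ndarray
    fgf: np.ndarray
    bt_profile: np.ndarray           # off-branch (developmentally naive) B_T
    border_position: Optional[float]
    bt_on: Optional[np.ndarray] = None   # on-branch B_T (CIPF only)


# ---------------------------------------------------------------------------
# Dual-loop EC50 analysis
# ---------------------------------------------------------------------------

#: parameters inside (or feeding) the CIPF loop: changing them re-balances
#: B_I against F_I and therefore shifts the EC50
LOOP_LEVEL_PARAMS = ("fb_k", "bf_k", "K_BI", "kc1")
#: parameters downstream of the loop: pure amplitude knobs for B_T
DOWNSTREAM_PARAMS = ("kc5", "K_BT")


@dataclass
class DualLoopModel:
    """Two target genes driven by CIPF loops sharing unperturbed
    parameters; loop 2 differs by multiplicative deltas."""

    shared: ModelParameters
    fgf_level: float
    loop_deltas: Dict[str, float]
    downstream_deltas: Dict[str, float]


def perturb(params: ModelParameters, name: str,
            factor: float) -> ModelParameters:
    """Multiply one (possibly link-level) parameter by ``factor``."""
    if name == "fb_k":
        return params.with_(fb_link=replace(params.fb_link,
                                            k=params.fb_link.k * factor))
    if name == "bf_k":
        return params.with_(bf_link=replace(params.bf_link,
                                            k=params.bf_link.k * factor))
    if name in ("kc1", "kc3", "kc5", "K_BI", "K_FI", "K_BT", "K_tbt",
                "K_tb", "K_tf"):
        return params.with_(**{name: getattr(params, name) * factor})
    raise KeyError(f"unknown parameter {name!r}")


def _measure_ec50_max(params: ModelParameters, fgf_level: float,
                      span: np.ndarray):
    dr = compute_dose_response(ModelClass.CIPF, params, span, fgf_level)
    fit = fit_hill(dr)
    if not np.isfinite(fit.ec50):
        return None
    return fit.ec50, max_response_asymptotic(params, fgf_level)


def max_response_asymptotic(params: ModelParameters,
                            fgf_level: float) -> float:
    from .response_analysis import max_asymptotic
    return max_asymptotic(ModelClass.CIPF, params, fgf_level)


def dual_ec50_analysis(model: DualLoopModel) -> pd.DataFrame:
    """EC50 and max ratios (target 2 / target 1) per perturbation.

    Loop-level deltas shift the EC50 ratio away from 1; downstream
    deltas leave it at 1 and move only the max ratio.
    """
    base = model.shared
    F = model.fgf_level
    wide = _wide_grid(base)
    y1 = compute_dose_response(ModelClass.CIPF, base, wide, F).responses
    top = 10.0 * _halfmax_dose(wide, y1)
    span = np.geomspace(top / 300.0, 3.0 * top, 48)
    ref = _measure_ec50_max(base, F, span)
    if ref is None:
        raise RuntimeError("Hill fit failed for the reference network")
    ec_ref, max_ref = ref

    rows = []
    for kind, deltas in (("loop", model.loop_deltas),
                         ("downstream", model.downstream_deltas)):
        for name, factor in deltas.items():
            out = _measure_ec50_max(perturb(base, name, factor), F, span)
            if out is None:
                rows.append({"kind": kind, "param": name, "factor": factor,
                             "ec50_ratio": np.nan, "max_ratio": np.nan,
                             "ok": False})
                continue
            ec2, max2 = out
            rows.append({"kind": kind, "param": name, "factor": factor,
                         "ec50_ratio": ec2 / ec_ref,
                         "max_ratio": max2 / max_ref, "ok": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gradient fitting and threshold spacing
# ---------------------------------------------------------------------------

def fit_exponential_gradient(x, c) -> GradientFit:
    """Least-squares fit of c(x) = A * exp(-x/lambda) + b.

    Requires >= 5 points with a decreasing trend; flat (non-identifiable)
    profiles are flagged ``ok=False``.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points")
    span = float(c.max() - c.min())
    if span <= 0.05 * abs(float(c.mean())):
        return GradientFit(0.0, float("nan"), float(c.mean()), False)

    def f(x_, A, lam, b):
        return A * np.exp(-x_ / lam) + b

    xr = float(x.max() - x.min()) or 1.0
    p0 = [span, xr / 2.0, max(float(c.min()), 1e-12)]
    try:
        popt, _ = curve_fit(
            f, x, c, p0=p0,
            bounds=([1e-12, xr / 1000.0, 0.0],
                    [10.0 * float(c.max()), 100.0 * xr, float(c.max())]),
            maxfev=5000)
    except (RuntimeError, ValueError):
        return GradientFit(float("nan"), float("nan"), float("nan"), False)
    A, lam, b = (float(v) for v in popt)
    # identifiability check: the exponential part must matter over the span
    ok = A > 0.05 * (A + b) and lam < 50.0 * xr
    return GradientFit(A, lam, b, ok)


def threshold_lengthscale(c_low: float, c_high: float, dx: float) -> float:
    """Length scale of an exponential gradient on which two response
    thresholds ``c_low < c_high`` sit ``dx`` apart:
    lambda = dx / ln(c_high / c_low)."""
    if not (c_high > c_low > 0.0):
        raise ValueError("need c_high > c_low > 0")
    if dx <= 0:
        raise ValueError("dx must be positive")
    return dx / float(np.log(c_high / c_low))


# ---------------------------------------------------------------------------
# 1D tissue
# ---------------------------------------------------------------------------

def _drives(params: ModelParameters, B, F):
    """Open-loop production drives of B_I and F_I at local ligand levels."""
    aB = params.bmp_gain * hill_activation(B, params.K_tb, params.n1)
    aF = params.fgf_gain * hill_activation(F, params.K_tf, params.n2)
    return aB, aF


def simulate_tissue(params: ModelParameters,
                    bmp_gradient: GradientProfile,
                    fgf_gradient: GradientProfile,
                    L: float, n_cells: int = 200,
                    model_class=ModelClass.CIPF,
                    init_policy: str = "off") -> TissuePattern:
    """Steady-state B_T of a row of independent cells in opposing
    gradients, plus the expression border.

    The border is the position where the followed branch of B_T crosses
    half its tissue maximum (linear interpolation between cells).  For
    bistable (CIPF) profiles the on-branch profile is also returned so
    the spatial hysteresis zone can be read off.
    """
    x = np.linspace(0.0, L, n_cells)
    Bx = bmp_gradient.concentration(x, L)
    Fx = fgf_gradient.concentration(x, L)
    dr_cls = ModelClass(model_class)
    bt = np.empty(n_cells)
    bt_on = np.empty(n_cells) if dr_cls is ModelClass.CIPF else None
    for i in range(n_cells):
        dose = np.array([Bx[i] if Bx[i] > 0 else 1e-12])
        bt[i] = compute_dose_response(dr_cls, params, dose, Fx[i],
                                      init_policy=init_policy).responses[0]
        if bt_on is not None:
            bt_on[i] = compute_dose_response(
                dr_cls, params, dose, Fx[i], init_policy="on").responses[0]
    border = _half_max_crossing(x, bt)
    return TissuePattern(L, x, Bx, Fx, bt, border, bt_on)


def _half_max_crossing(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    thr = 0.5 * float(y.max())
    if y.max() <= 0:
        return None
    above = y >= thr
    if above.all() or not above.any():
        return None
    # first crossing scanning from the low-BT side
    lo_side_high = y[0] >= thr
    for i in range(len(x) - 1):
        if (y[i] >= thr) != (y[i + 1] >= thr):
            f = (thr - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + f * (x[i + 1] - x[i]))
    return None


def equivalence_point(bmp_gradient: GradientProfile,
                      fgf_gradient: GradientProfile,
                      params: ModelParameters, L: float) -> float:
    """Position where the two pathway intermediates balance each other.

    Balance means equal inhibitory pressure of the (off-branch) steady
    intermediates on their opposing links: B_I(x)/k_bf = F_I(x)/k_fb.
    For a sharp toggle this is where the loop flips, i.e. the expression
    border.  Raises if the pressures do not cross in [0, L].
    """
    from .steady_state import cipf_stable_branches
    from .model_core import inhibition_factor

    def diff(x):
        B = max(float(bmp_gradient.concentration(x, L)), 1e-300)
        F = float(fgf_gradient.concentration(x, L))
        bi, _, _ = cipf_stable_branches(params, B, F)
        aF = params.fgf_gain * float(hill_activation(F, params.K_tf,
                                                     params.n2))
        fi = aF * float(inhibition_factor(bi, params.bf_link))
        return bi / params.bf_link.k - fi / params.fb_link.k

    xs = np.linspace(0.0, L, 256)
    vals = np.array([diff(x) for x in xs])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) == 0:
        exact = np.nonzero(vals == 0.0)[0]
        if len(exact):
            return float(xs[exact[0]])
        raise ValueError("pathway drives do not cross within the tissue")
    i = idx[0]
    lo, hi = float(xs[i]), float(xs[i + 1])
    for _ in range(60):  # bisection: robust to the jump discontinuity
        mid = 0.5 * (lo + hi)
        if np.sign(diff(mid)) == np.sign(diff(lo)):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def scaling_test(params: ModelParameters,
                 bmp_gradient: GradientProfile,
                 fgf_gradient: GradientProfile,
                 L: float, scales: Sequence[float],
                 n_cells: int = 200,
                 proportional: bool = True) -> pd.DataFrame:
    """Relative border position across tissue scales.

    ``proportional=True`` rescales both gradients' length scales with
    the tissue (border position should scale: x/L constant for pure
    exponentials); ``False`` rescales only the tissue length (negative
    control: x/L shifts)."""
    if bmp_gradient.b != 0 or fgf_gradient.b != 0:
        raise ValueError("scaling test requires pure exponentials (b = 0)")
    rows = []
    for s in scales:
        Ls = L * s
        bg = bmp_gradient.scaled(s) if proportional else bmp_gradient
        fg = fgf_gradient.scaled(s) if proportional else fgf_gradient
        pat = simulate_tissue(params, bg, fg, Ls, n_cells)
        rows.append({"scale": s, "L": Ls,
                     "border": pat.border_position,
                     "relative_border": (pat.border_position / Ls
                                         if pat.border_position is not None
                                         else np.nan)})
    df = pd.DataFrame(rows)
    ref = df.loc[df["scale"] == 1.0, "relative_border"]
    if len(ref):
        df["deviation"] = (df["relative_border"] - float(ref.iloc[0])).abs()
    return df
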