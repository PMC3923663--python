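"""Dose-response generation and characterization (max, EC50, apparent nH).

The BMP dose response of the target B_T is computed at steady state over
a log-spaced dose grid, with or without a fixed FGF input, and condensed
into three properties by fitting the Hill equation

    y(d) = ymax * d^nH / (ec50^nH + d^nH).

Maximal levels are measured asymptotically (at a dose of 1e4 x K_tb)
rather than from the fit.  For hysteretic (CIPF) parameter sets the
``off`` branch is the curve followed when cells start FGF-equilibrated
without BMP, the ``on`` branch when they start at saturating BMP.

Fitting protocol: apparent Hill coefficients depend on the dose span
used.  `fit_hill` fits whatever grid it is given; the sweep-level
`measure_response_change` emulates the experimental assay by fitting on
a 36-point log grid spanning two decades up to ~10x the half-max dose
of the with-FGF curve, with nH bounded to [0.05, 6] (steeper transitions
are treated as switch-like and belong to the hysteresis analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .model_core import ModelClass, ModelParameters, hill_activation
from .steady_state import (cipf_bt_from_bi, cipf_stable_branches,
                           closed_form_bt)

__all__ = [
    "DoseResponse",
    "HillFitResult",
    "ResponseChange",
    "default_dose_grid",
    "compute_dose_response",
    "fit_hill",
    "max_asymptotic",
    "response_change",
    "measure_response_change",
    "NH_FIT_MAX",
]

#: Upper bound on the fitted apparent Hill coefficient.  The steepest
#: graded response this system is characterized by is nH ~ 5; anything
#: steeper is a switch-like (bistable) transition.
NH_FIT_MAX = 6.0
NH_FIT_MIN = 0.05


@dataclass
class DoseResponse:
    doses: np.ndarray
    responses: np.ndarray
    fgf_level: float
    init_policy: str = "off"     # "off" or "on"

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.responses < 0):
            raise ValueError("responses must be non-negative")


@dataclass
class HillFitResult:
    ymax: float
    ec50: float
    nH: float
    rss: float
    ok: bool


@dataclass
class ResponseChange:
    """Property ratios (with FGF) / (without FGF)."""
    max_ratio: float
    ec50_ratio: float
    nh_ratio: float


def default_dose_grid(params: ModelParameters, n: int = 40) -> np.ndarray:
    """40 log-spaced BMP doses over [K_tb/100, 100*K_tb]."""
    return np.geomspace(params.K_tb / 100.0, params.K_tb * 100.0, n)


def compute_dose_response(model_class, params: ModelParameters,
                          dose_grid: Optional[np.ndarray] = None,
                          fgf_level: float = 0.0,
                          init_policy: str = "off") -> DoseResponse:
    """Steady-state B_T over a dose grid.

    For the cascade classes the steady state is unique and the policy is
    irrelevant.  For CIPF, ``off`` follows the lowest stable branch and
    ``on`` the highest (equivalently: continuation from the zero-BMP and
    saturating-BMP ends of the grid).
    """
    mc = ModelClass(model_class)
    if dose_grid is None:
        dose_grid = default_dose_grid(params)
    dose_grid = np.asarray(dose_grid, dtype=float)
    if init_policy not in ("off", "on"):
        raise ValueError("init_policy must be 'off' or 'on'")

    if mc is ModelClass.CIPF:
        bt = np.empty_like(dose_grid)
        for i, d in enumerate(dose_grid):
            lo, hi, _ = cipf_stable_branches(params, d, fgf_level)
            bt[i] = cipf_bt_from_bi(params, lo if init_policy == "off" else hi)
    else:
        bt = np.asarray(closed_form_bt(mc, params, dose_grid, fgf_level),
                        dtype=float)
    return DoseResponse(dose_grid, bt, fgf_level, init_policy)


def _halfmax_dose(d: np.ndarray, y: np.ndarray) -> float:
    """Dose at which the response first crosses half its maximum
    (log-linear interpolation)."""
    ym = float(y.max())
    i = int(np.argmax(y >= ym / 2.0))
    if i == 0:
        return float(d[0])
    f = (ym / 2.0 - y[i - 1]) / (y[i] - y[i - 1])
    return float(d[i - 1] * (d[i] / d[i - 1]) ** f)


def _hill(d, ymax, ec50, nH):
    return ymax * d ** nH / (ec50 ** nH + d ** nH)


def fit_hill(dr: DoseResponse | tuple, nh_max: float = NH_FIT_MAX
             ) -> HillFitResult:
    """Bounded least-squares Hill fit of a dose response.

    Starts at (max response, half-max crossing, nH in {1, 3, 0.8*max});
    the restart with the lowest residual wins.  Degenerate (flat) curves
    are flagged ``ok=False`` and not fit; fits whose relative RSS
    exceeds 5% are returned with ``ok=False``.
    """
    if isinstance(dr, DoseResponse):
        d, y = dr.doses, dr.responses
    else:
        d, y = np.asarray(dr[0], float), np.asarray(dr[1], float)
    if len(d) < 6:
        raise ValueError("need at least 6 dose points")
    ymax0 = float(y.max())
    if ymax0 <= 0 or y.min() > 0.9 * ymax0:
        return HillFitResult(ymax0, float("nan"), float("nan"),
                             float("inf"), False)
    ec0 = min(max(_halfmax_dose(d, y), d[0]), d[-1])
    best = None
    for n0 in (1.0, 3.0, 0.8 * nh_max):
        try:
            popt, _ = curve_fit(
                _hill, d, y, p0=[ymax0, ec0, n0],
                bounds=([1e-300, d[0], NH_FIT_MIN],
                        [10.0 * ymax0, d[-1], nh_max]),
                maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((_hill(d, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return HillFitResult(ymax0, float("nan"), float("nan"),
                             float("inf"), False)
    (ymax, ec50, nH), rss = best
    rel = np.sqrt(rss / len(d)) / ymax0
    return HillFitResult(float(ymax), float(ec50), float(nH), rss,
                         ok=bool(rel <= 0.05))


def max_asymptotic(model_class, params: ModelParameters,
                   fgf_level: float = 0.0,
                   init_policy: str = "off") -> float:
    """Steady B_T at an extremely high BMP dose (1e4 x K_tb)."""
    mc = ModelClass(model_class)
    d = 1e4 * params.K_tb
    if mc is ModelClass.CIPF:
        lo, hi, _ = cipf_stable_branches(params, d, fgf_level)
        return float(cipf_bt_from_bi(params,
                                     lo if init_policy == "off" else hi))
    return float(closed_form_bt(mc, params, d, fgf_level))


def response_change(model_class, params: ModelParameters,
                    fgf_level: float,
                    dose_grid: Optional[np.ndarray] = None
                    ) -> ResponseChange:
    """Property ratios on a common (default) dose grid.

    Raises if either Hill fit fails to converge.
    """
    dr0 = compute_dose_response(model_class, params, dose_grid, 0.0)
    dr1 = compute_dose_response(model_class, params, dose_grid, fgf_level)
    f0, f1 = fit_hill(dr0), fit_hill(dr1)
    if not (np.isfinite(f0.nH) and np.isfinite(f1.nH)):
        raise RuntimeError("Hill fit failed for one of the conditions")
    m0 = max_asymptotic(model_class, params, 0.0)
    m1 = max_asymptotic(model_class, params, fgf_level)
    return ResponseChange(m1 / m0, f1.ec50 / f0.ec50, f1.nH / f0.nH)


# ---------------------------------------------------------------------------
# Assay-emulating measurement used by the parameter sweeps
# ---------------------------------------------------------------------------

def _wide_grid(params: ModelParameters, n: int = 60) -> np.ndarray:
    return np.geomspace(params.K_tb / 1000.0, params.K_tb * 1000.0, n)


def measure_response_change(model_class, params: ModelParameters,
                            fgf_level: float):
    """Measure (max, EC50, nH) ratios the way the experiments do.

    The dose span for fitting is anchored to the transition of the
    with-FGF off-branch curve (top dose ~10x its half-max dose, two
    decades down), each condition fit on that same span.  Returns
    ``(ResponseChange, fit_without, fit_with)`` or ``None`` when a fit
    is degenerate.
    """
    mc = ModelClass(model_class)
    wide = _wide_grid(params)
    y1 = compute_dose_response(mc, params, wide, fgf_level).responses
    y0 = compute_dose_response(mc, params, wide, 0.0).responses
    if y1.max() <= 0 or y0.max() <= 0:
        return None
    top = 10.0 * _halfmax_dose(wide, y1)
    span = np.geomspace(top / 100.0, top, 36)
    f0 = fit_hill(compute_dose_response(mc, params, span, 0.0))
    f1 = fit_hill(compute_dose_response(mc, params, span, fgf_level))
    if not (np.isfinite(f0.nH) and np.isfinite(f1.nH)):
        return None
    m0 = max_asymptotic(mc, params, 0.0)
    m1 = max_asymptotic(mc, params, fgf_level)
    change = ResponseChange(m1 / m0, f1.ec50 / f0.ec50, f1.nH / f0.nH)
    return change, f0, f1
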