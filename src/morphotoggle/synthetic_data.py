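"""Synthetic datasets emulating the study's measurements.

RT-qPCR style dose responses are noisy Hill curves (multiplicative
lognormal noise on normalized fold changes), washout datasets wrap the
washout simulation, and spatial gradient profiles are exponentials with
an unknown background.  Defaults mirror the measured system: EC50 values
of 1.5 (no FGF) or 8.3 ng/ml (with FGF), apparent nH of 1.0 or 3.7, BMP
doses spanning 0-64 ng/ml and a 290 um gradient length scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .memory_analysis import WashoutProtocol, simulate_washout
from .model_core import ModelClass, ModelParameters

__all__ = [
    "NoiseModel",
    "QpcrDataset",
    "DEFAULT_DOSES_NG_ML",
    "gen_dose_response",
    "gen_washout_dataset",
    "gen_gradient_profile",
]

#: two-fold BMP4 dilution series, 0.5-64 ng/ml
DEFAULT_DOSES_NG_ML = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0])

#: defaults measured for the Msx1 response (EC50 in ng/ml BMP4)
MSX1_NO_FGF = (1.0, 1.5, 1.0)     # (ymax, ec50, nH)
MSX1_WITH_FGF = (1.0, 8.3, 3.7)
GRADIENT_LENGTH_SCALE_UM = 290.0


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise: y_obs = y * exp(N(0, sigma^2))."""

    sigma: float = 0.1

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(y, dtype=float).copy()
        return y * np.exp(rng.normal(0.0, self.sigma, size=np.shape(y)))


@dataclass
class QpcrDataset:
    """Replicated fold-change measurements over a dose series."""

    data: pd.DataFrame          # columns: condition, dose, replicate, value
    condition: str
    seed: int

    def doses(self) -> np.ndarray:
        return np.sort(self.data["dose"].unique())

    def mean_response(self) -> Tuple[np.ndarray, np.ndarray]:
        g = self.data.groupby("dose")["value"].mean().sort_index()
        return g.index.to_numpy(), g.to_numpy()


def _hill(d, ymax, ec50, nH):
    d = np.asarray(d, dtype=float)
    return ymax * d ** nH / (ec50 ** nH + d ** nH)


def gen_dose_response(true_params: Tuple[float, float, float] = MSX1_WITH_FGF,
                      doses: np.ndarray = DEFAULT_DOSES_NG_ML,
                      reps: int = 3,
                      noise: NoiseModel = NoiseModel(),
                      seed: int = 0,
                      condition: str = "withFGF") -> QpcrDataset:
    """Noisy Hill-curve dose response, ``reps`` replicates per dose."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    ymax, ec50, nH = true_params
    clean = _hill(doses, ymax, ec50, nH)
    rows = []
    for rep in range(reps):
        vals = noise.apply(clean, rng)
        for d, v in zip(doses, vals):
            rows.append({"condition": condition, "dose": d,
                         "replicate": rep, "value": v, "seed": seed})
    return QpcrDataset(pd.DataFrame(rows), condition, seed)


def gen_washout_dataset(params: ModelParameters,
                        protocol: WashoutProtocol,
                        noise: NoiseModel = NoiseModel(),
                        seed: int = 0,
                        fgf_level: float = 0.0) -> pd.DataFrame:
    """Washout simulation outputs for on/off-pretreated populations with
    multiplicative measurement noise.  Columns: condition (initial
    state), dose (reapplied), replicate, value, seed."""
    rng = np.random.default_rng(seed)
    table = simulate_washout(ModelClass.CIPF, params, protocol, fgf_level)
    rows = []
    for _, r in table.iterrows():
        v = noise.apply(np.array([r["response"]]), rng)[0]
        rows.append({"condition": r["initial_state"],
                     "dose": r["reapplied_dose"],
                     "replicate": 0, "value": float(v), "seed": seed})
    return pd.DataFrame(rows)


def gen_gradient_profile(A: float = 10.0,
                         lam: float = GRADIENT_LENGTH_SCALE_UM,
                         b: float = 1.0,
                         n_points: int = 20,
                         x_max: Optional[float] = None,
                         noise: NoiseModel = NoiseModel(sigma=0.05),
                         seed: int = 0) -> pd.DataFrame:
    """Noisy samples of an exponential gradient with background.

    Columns: x (um), concentration.  Reproducible from the seed.
    """
    if n_points < 5:
        raise ValueError("need at least 5 points")
    rng = np.random.default_rng(seed)
    if x_max is None:
        x_max = 3.0 * lam
    x = np.linspace(0.0, x_max, n_points)
    c = A * np.exp(-x / lam) + b
    return pd.DataFrame({"x": x, "concentration": noise.apply(c, rng),
                         "seed": seed})
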