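"""Core single-cell models of BMP-FGF cross inhibition.

Two three-tier signaling pathways are reduced to ordinary differential
equations: an extracellular morphogen (BMP or FGF), an intracellular
intermediate (``B_I`` / ``F_I``), and a transcriptional target
(``B_T`` / ``F_T``).  All activating interactions are Hill functions;
inhibitory cross-links multiply production by a factor

    1 - p * x^n / (k^n + x^n)

with strength ``p`` (maximal fractional suppression), half-saturation
``k`` and exponent ``n``.  At ``p = 1`` this is the divisive form
``1 / (1 + (x/k)^n)``, which is the default used throughout the model
classes (the inhibition is then parameterized purely by its
half-saturation constant, as in receptor-level competitive inhibition).

Four representative classes of cross inhibition are implemented:

* ``STI``  -- simple target inhibition: F_I inhibits B_T.
* ``SUI``  -- simple upstream inhibition: F_I inhibits B_I.
* ``CFF``  -- coherent feedforward: F_I inhibits B_T and B_I inhibits F_I.
* ``CIPF`` -- cross-inhibitory positive feedback ("toggle switch"):
  F_I inhibits B_I and B_I inhibits F_I.

An auto-regulatory contrast model (``AUTOREG``) adds a positive
self-activation on B_I to the core pathway; unlike CIPF it can latch
irreversibly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace, asdict
from typing import Callable, Optional

import numpy as np

__all__ = [
    "ModelClass",
    "Tier",
    "PathwayNode",
    "InhibitoryLink",
    "SelfActivation",
    "ModelParameters",
    "SystemState",
    "hill_activation",
    "inhibition_factor",
    "build_rhs",
    "build_topology_rhs",
    "nondimensionalize",
]


class ModelClass(str, enum.Enum):
    STI = "STI"
    SUI = "SUI"
    CFF = "CFF"
    CIPF = "CIPF"
    AUTOREG = "AUTOREG"


class Tier(enum.IntEnum):
    LIGAND = 0
    INTERMEDIATE = 1
    TARGET = 2


@dataclass(frozen=True)
class PathwayNode:
    """One node of a pathway: which side it belongs to and its tier."""

    side: str  # "BMP" or "FGF"
    tier: Tier

    def __post_init__(self):
        if self.side not in ("BMP", "FGF"):
            raise ValueError(f"side must be 'BMP' or 'FGF', got {self.side!r}")
        if int(self.tier) not in (0, 1, 2):
            raise ValueError(f"tier must be 0, 1 or 2, got {self.tier}")


@dataclass(frozen=True)
class InhibitoryLink:
    """A cross-pathway inhibitory link.

    ``p`` is the maximal fractional suppression in [0, 1] (p = 1 gives the
    divisive form), ``k`` the half-saturation of the inhibitor and ``n``
    its Hill exponent.  ``source``/``target`` are optional node
    annotations used by the general topology builder.
    """

    p: float
    k: float
    n: float
    source: Optional[PathwayNode] = None
    target: Optional[PathwayNode] = None

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"strength p must lie in [0, 1], got {self.p}")
        if self.k <= 0:
            raise ValueError(f"half-saturation k must be positive, got {self.k}")
        if self.n < 1:
            raise ValueError(f"Hill exponent n must be >= 1, got {self.n}")
        if self.source is not None and self.target is not None:
            if self.source.side == self.target.side:
                raise ValueError("inhibitory links must cross pathways")


@dataclass(frozen=True)
class SelfActivation:
    """Auto-regulatory positive feedback on B_I (AUTOREG contrast model)."""

    kc_a: float
    K_a: float
    n_a: float

    def __post_init__(self):
        if self.kc_a < 0 or self.K_a <= 0 or self.n_a < 1:
            raise ValueError("invalid self-activation parameters")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the reduced three-tier ODE system.

    kc1, kc3, kc5      maximal production rates of B_I, F_I, B_T
    K_tb, K_tf, K_tbt  half-saturation constants of activation
                       (B -> B_I, F -> F_I, B_I -> B_T)
    K_BI, K_FI, K_BT   first-order degradation rates
    n1, n2, n3         Hill exponents of the activating steps
    fb_link            the F-side -> B-side inhibition
    bf_link            the B-side -> F-side inhibition
    autoreg            optional self-activation on B_I (AUTOREG only)
    """

    kc1: float
    kc3: float
    kc5: float
    K_tb: float
    K_tf: float
    K_tbt: float
    K_BI: float
    K_FI: float
    K_BT: float
    n1: float
    n2: float
    n3: float
    fb_link: InhibitoryLink
    bf_link: InhibitoryLink
    autoreg: Optional[SelfActivation] = None

    def __post_init__(self):
        for name in ("kc1", "kc3", "kc5", "K_tb", "K_tf", "K_tbt",
                     "K_BI", "K_FI", "K_BT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n1", "n2", "n3"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    # -- convenience -------------------------------------------------
    @property
    def bmp_gain(self) -> float:
        """Saturated B_I level kc1/K_BI (the BMP-side drive scale)."""
        return self.kc1 / self.K_BI

    @property
    def fgf_gain(self) -> float:
        """Saturated F_I level kc3/K_FI."""
        return self.kc3 / self.K_FI

    def to_flat_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("fb_link", "bf_link", "autoreg")}
        for prefix, link in (("fb", self.fb_link), ("bf", self.bf_link)):
            d[f"{prefix}_p"] = link.p
            d[f"{prefix}_k"] = link.k
            d[f"{prefix}_n"] = link.n
        if self.autoreg is not None:
            d["kc_a"] = self.autoreg.kc_a
            d["K_a"] = self.autoreg.K_a
            d["n_a"] = self.autoreg.n_a
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        fb = InhibitoryLink(p=d.pop("fb_p"), k=d.pop("fb_k"), n=d.pop("fb_n"))
        bf = InhibitoryLink(p=d.pop("bf_p"), k=d.pop("bf_k"), n=d.pop("bf_n"))
        auto = None
        if "kc_a" in d:
            auto = SelfActivation(kc_a=d.pop("kc_a"), K_a=d.pop("K_a"),
                                  n_a=d.pop("n_a"))
        return cls(fb_link=fb, bf_link=bf, autoreg=auto, **d)

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


@dataclass
class SystemState:
    """Concentrations of the intracellular species (all >= 0)."""

    B_I: float
    F_I: float
    B_T: float
    F_T: Optional[float] = None

    def as_array(self) -> np.ndarray:
        vals = [self.B_I, self.F_I, self.B_T]
        if self.F_T is not None:
            vals.append(self.F_T)
        return np.asarray(vals, dtype=float)

    @classmethod
    def zero(cls, with_ft: bool = False) -> "SystemState":
        return cls(0.0, 0.0, 0.0, 0.0 if with_ft else None)


# ---------------------------------------------------------------------------
# Elementary interaction terms
# ---------------------------------------------------------------------------

def hill_activation(x, k: float, n: float):
    """Hill activation x^n / (k^n + x^n); 0 at x = 0, 1/2 at x = k.

    Vectorized over ``x``.  Raises on non-positive ``k`` or ``n < 1``.
    """
    if k <= 0:
        raise ValueError(f"half-saturation k must be positive, got {k}")
    if n < 1:
        raise ValueError(f"Hill exponent n must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentration must be non-negative")
    # compute via (k/x)^n to avoid overflow for large x^n
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, k / np.where(x > 0, x, 1.0), np.inf)
        out = 1.0 / (1.0 + ratio ** n)
    out = np.where(x > 0, out, 0.0)
    return out if out.ndim else float(out)


def inhibition_factor(x, link: InhibitoryLink):
    """Multiplicative inhibition 1 - p * hill(x; k, n), in [1 - p, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    out = 1.0 - link.p * np.asarray(hill_activation(x, link.k, link.n))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Representative model right-hand sides
# ---------------------------------------------------------------------------

def build_rhs(model_class: ModelClass | str,
              params: ModelParameters) -> Callable:
    """Return ``rhs(state_vector, B, F) -> derivative_vector`` for a class.

    The state vector is ``[B_I, F_I, B_T]``.  The inhibitory links are
    attached according to the class:

    ==== =====================  =====================
    STI  F_I -| B_T
    SUI  F_I -| B_I
    CFF  F_I -| B_T             B_I -| F_I
    CIPF F_I -| B_I             B_I -| F_I
    ==== =====================  =====================

    AUTOREG is the BMP core pathway with a self-activation on B_I
    (``params.autoreg`` must be set); it carries no cross links.
    """
    mc = ModelClass(model_class)
    p = params
    fb, bf = p.fb_link, p.bf_link

    if mc is ModelClass.AUTOREG and p.autoreg is None:
        raise ValueError("AUTOREG requires params.autoreg")

    inhibits_bi = mc in (ModelClass.SUI, ModelClass.CIPF)
    inhibits_bt = mc in (ModelClass.STI, ModelClass.CFF)
    inhibits_fi = mc in (ModelClass.CFF, ModelClass.CIPF)

    def rhs(y, B, F):
        B_I, F_I, B_T = y[0], y[1], y[2]
        prod_bi = p.kc1 * hill_activation(B, p.K_tb, p.n1)
        if inhibits_bi:
            prod_bi *= inhibition_factor(F_I, fb)
        if mc is ModelClass.AUTOREG:
            a = p.autoreg
            prod_bi += a.kc_a * hill_activation(B_I, a.K_a, a.n_a)
        prod_fi = p.kc3 * hill_activation(F, p.K_tf, p.n2)
        if inhibits_fi:
            prod_fi *= inhibition_factor(B_I, bf)
        prod_bt = p.kc5 * hill_activation(B_I, p.K_tbt, p.n3)
        if inhibits_bt:
            prod_bt *= inhibition_factor(F_I, fb)
        return np.array([
            prod_bi - p.K_BI * B_I,
            prod_fi - p.K_FI * F_I,
            prod_bt - p.K_BT * B_T,
        ])

    return rhs


# ---------------------------------------------------------------------------
# General topology right-hand side (six-node system)
# ---------------------------------------------------------------------------

def build_topology_rhs(topology, params: ModelParameters) -> Callable:
    """Return ``rhs(y, B, F)`` for an arbitrary two-link cross-inhibition
    topology over the full six-node system.

    ``topology`` provides the four tier indices
    (``fb_source_tier``, ``fb_target_tier``, ``bf_source_tier``,
    ``bf_target_tier``); see :mod:`morphotoggle.topology_space`.
    The state vector is ``[B_I, F_I, B_T, F_T]``.  Ligand-tier targets
    scale the ligand concentration entering the activation Hill term;
    ligand-tier sources use the ligand concentration as the inhibitor
    input.  The F-side target F_T mirrors B_T's parameters.
    """
    p = params
    fb, bf = p.fb_link, p.bf_link
    fst, ftt = int(topology.fb_source_tier), int(topology.fb_target_tier)
    bst, btt = int(topology.bf_source_tier), int(topology.bf_target_tier)

    def rhs(y, B, F):
        B_I, F_I, B_T, F_T = y[0], y[1], y[2], y[3]
        f_side = (F, F_I, F_T)
        b_side = (B, B_I, B_T)
        fb_factor = inhibition_factor(f_side[fst], fb)  # acts on B side
        bf_factor = inhibition_factor(b_side[bst], bf)  # acts on F side

        B_eff = B * (fb_factor if ftt == 0 else 1.0)
        F_eff = F * (bf_factor if btt == 0 else 1.0)

        prod_bi = p.kc1 * hill_activation(B_eff, p.K_tb, p.n1)
        if ftt == 1:
            prod_bi *= fb_factor
        prod_fi = p.kc3 * hill_activation(F_eff, p.K_tf, p.n2)
        if btt == 1:
            prod_fi *= bf_factor
        prod_bt = p.kc5 * hill_activation(B_I, p.K_tbt, p.n3)
        if ftt == 2:
            prod_bt *= fb_factor
        prod_ft = p.kc5 * hill_activation(F_I, p.K_tbt, p.n3)
        if btt == 2:
            prod_ft *= bf_factor

        return np.array([
            prod_bi - p.K_BI * B_I,
            prod_fi - p.K_FI * F_I,
            prod_bt - p.K_BT * B_T,
            prod_ft - p.K_BT * F_T,
        ])

    return rhs


# ---------------------------------------------------------------------------
# Non-dimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize(params: ModelParameters) -> ModelParameters:
    """Rescale species by their production/degradation ratio and time by
    1/K_BT.

    Each intermediate is scaled to its saturated level (B_I by kc1/K_BI,
    F_I by kc3/K_FI, B_T by kc5/K_BT), which maps the half-saturation
    constants downstream of the intermediates accordingly.  The shape of
    the B_T dose response (EC50 on the dose axis, apparent nH) is
    preserved; the maximal level is divided by kc5/K_BT.
    """
    p = params
    sB = p.kc1 / p.K_BI   # B_I scale
    sF = p.kc3 / p.K_FI   # F_I scale
    sT = p.kc5 / p.K_BT   # B_T scale
    tau = p.K_BT          # time scale

    fb = replace(p.fb_link, k=p.fb_link.k / sF)  # F_I is the inhibitor
    bf = replace(p.bf_link, k=p.bf_link.k / sB)  # B_I is the inhibitor
    auto = None
    if p.autoreg is not None:
        auto = replace(p.autoreg, kc_a=p.autoreg.kc_a / (sB * tau),
                       K_a=p.autoreg.K_a / sB)
    return replace(
        p,
        kc1=p.K_BI / tau, K_BI=p.K_BI / tau,
        kc3=p.K_FI / tau, K_FI=p.K_FI / tau,
        kc5=1.0, K_BT=1.0,
        K_tbt=p.K_tbt / sB,
        fb_link=fb, bf_link=bf, autoreg=auto,
    )
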