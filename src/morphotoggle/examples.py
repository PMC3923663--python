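"""Representative parameter sets used by the analysis scripts and tests.

All sets are nondimensional (unit rates; species scaled to their
saturated levels) and use divisive inhibitory links (strength p = 1).
"""

from __future__ import annotations

from .model_core import (InhibitoryLink, ModelParameters, SelfActivation)

__all__ = [
    "toggle_nonlinear",
    "toggle_linear_deep",
    "toggle_fgf_level",
    "autoreg_strong",
    "UNIT_KWARGS",
]

UNIT_KWARGS = dict(kc1=1.0, kc3=1.0, kc5=1.0,
                   K_tb=1.0, K_tf=1.0,
                   K_BI=1.0, K_FI=1.0, K_BT=1.0)

#: FGF input placing the FGF-side drive at 0.3 of the saturated BMP drive
#: (hyperbolic FGF activation: hill(F) = 0.3 at F = 3/7)
TOGGLE_FGF_LEVEL = 3.0 / 7.0


def toggle_fgf_level() -> float:
    return TOGGLE_FGF_LEVEL


def toggle_nonlinear(strength: float = 0.76,
                     balance: float = 1.0) -> ModelParameters:
    """Balanced CIPF with nonlinear inhibitory links (context 3): clearly
    bistable over an interior dose window at the default FGF level."""
    aF = 0.3
    kf = aF * ((1.0 - strength) / strength) ** 0.25
    kb = balance * (1.0 - strength) * 1.0
    return ModelParameters(
        n1=1.0, n2=1.0, n3=1.0, K_tbt=1.0,
        fb_link=InhibitoryLink(p=1.0, k=kf, n=4.0),
        bf_link=InhibitoryLink(p=1.0, k=kb, n=4.0),
        **UNIT_KWARGS)


def toggle_linear_deep(strength: float = 0.98) -> ModelParameters:
    """All-linear CIPF in the deep-release regime (context 1): monostable
    but visibly ultrasensitized by FGF (apparent nH ~ 2-3)."""
    aF = 0.3
    kf = aF * (1.0 - strength) / strength
    kb = 0.2 * (1.0 - strength)
    return ModelParameters(
        n1=1.0, n2=1.0, n3=1.0, K_tbt=0.05,
        fb_link=InhibitoryLink(p=1.0, k=kf, n=1.0),
        bf_link=InhibitoryLink(p=1.0, k=kb, n=1.0),
        **UNIT_KWARGS)


def autoreg_strong(kc_a: float = 1.5, K_a: float = 0.5,
                   n_a: float = 4.0) -> ModelParameters:
    """Auto-regulatory contrast model with feedback strong enough to be
    bistable at zero BMP input (irreversible once switched on)."""
    inert = InhibitoryLink(p=0.0, k=1.0, n=1.0)
    return ModelParameters(
        n1=1.0, n2=1.0, n3=1.0, K_tbt=0.5,
        fb_link=inert, bf_link=inert,
        autoreg=SelfActivation(kc_a=kc_a, K_a=K_a, n_a=n_a),
        **UNIT_KWARGS)
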