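import numpy as np
import pytest

from morphotoggle.examples import (autoreg_strong, toggle_fgf_level,
                                   toggle_linear_deep, toggle_nonlinear)
from morphotoggle.model_core import InhibitoryLink, ModelParameters


@pytest.fixture
def toggle_params():
    """Balanced nonlinear toggle: bistable over an interior dose window."""
    return toggle_nonlinear()


@pytest.fixture
def linear_toggle_params():
    """Deep all-linear toggle: monostable, ultrasensitized by FGF."""
    return toggle_linear_deep()


@pytest.fixture
def autoreg_params():
    return autoreg_strong()


@pytest.fixture
def fgf_level():
    return toggle_fgf_level()


def random_params(rng, n_core=1.0, n_inh=1.0, p=1.0):
    """Random parameter set with links positioned in their operating
    ranges (used by oracle-equivalence tests)."""
    lu = lambda a, b: float(10 ** rng.uniform(np.log10(a), np.log10(b)))
    kc1, kc3, kc5 = lu(.1, 10), lu(.1, 10), lu(.1, 10)
    K_BI, K_FI, K_BT = lu(.1, 10), lu(.1, 10), lu(.1, 10)
    A, aF = kc1 / K_BI, kc3 / K_FI
    return ModelParameters(
        kc1=kc1, kc3=kc3, kc5=kc5,
        K_tb=lu(.1, 10), K_tf=lu(.1, 10), K_tbt=lu(.2, 2) * A,
        K_BI=K_BI, K_FI=K_FI, K_BT=K_BT,
        n1=1.0, n2=n_core, n3=n_core,
        fb_link=InhibitoryLink(p=p, k=lu(.1, 1) * aF, n=n_inh),
        bf_link=InhibitoryLink(p=p, k=lu(.05, .5) * A, n=n_inh),
    )
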