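import numpy as np
import pytest

from morphotoggle.examples import autoreg_strong, toggle_nonlinear
from morphotoggle.memory_analysis import (MemoryClass, WashoutProtocol,
                                          classify_memory,
                                          hysteresis_curves,
                                          measure_window_decades,
                                          simulate_washout)
from morphotoggle.model_core import InhibitoryLink, ModelClass
from morphotoggle.parameter_sweep import sample_parameters

from conftest import random_params


class TestHysteresisCurves:
    @pytest.mark.parametrize("mc", ["STI", "SUI", "CFF"])
    def test_cascades_have_no_window(self, mc, fgf_level):
        rng = np.random.default_rng(1)
        for _ in range(5):
            p = random_params(rng, n_inh=4.0)
            res = hysteresis_curves(mc, p, fgf_level=10.0 * p.K_tf)
            assert res.window_size == 0.0

    def test_balanced_nonlinear_toggle_has_window(self, toggle_params,
                                                  fgf_level):
        res = hysteresis_curves(ModelClass.CIPF, toggle_params,
                                fgf_level=fgf_level)
        assert res.window_size > 0
        assert res.window_lo < res.window_hi

    def test_no_fgf_no_window(self, toggle_params):
        # without FGF drive the loop degenerates to the core pathway
        res = hysteresis_curves(ModelClass.CIPF, toggle_params,
                                fgf_level=0.0)
        assert res.window_size == 0.0

    def test_branches_identical_outside_window(self, toggle_params,
                                               fgf_level):
        res = hysteresis_curves(ModelClass.CIPF, toggle_params,
                                fgf_level=fgf_level)
        doses = res.off_curve.doses
        outside = (doses < res.window_lo) | (doses > res.window_hi)
        np.testing.assert_allclose(res.off_curve.responses[outside],
                                   res.on_curve.responses[outside],
                                   rtol=1e-6, atol=1e-12)

    def test_window_monotone_in_matched_strength(self, fgf_level):
        widths = []
        for s in (0.65, 0.76, 0.85, 0.92):
            widths.append(measure_window_decades(
                toggle_nonlinear(strength=s), fgf_level))
        assert all(b >= a for a, b in zip(widths, widths[1:]))
        assert widths[-1] > 0


class TestClassifyMemory:
    def test_sampled_toggles_never_irreversible(self, fgf_level):
        draws = sample_parameters(3, 12, seed=3)
        for d in draws:
            label = classify_memory(ModelClass.CIPF, d.params, d.fgf_level)
            assert label is not MemoryClass.IRREVERSIBLE

    def test_strong_autoreg_is_irreversible(self, autoreg_params):
        assert classify_memory(ModelClass.AUTOREG, autoreg_params,
                               0.0) is MemoryClass.IRREVERSIBLE

    def test_no_inhibition_no_memory(self):
        rng = np.random.default_rng(4)
        p = random_params(rng).with_(
            fb_link=InhibitoryLink(0.0, 1.0, 1.0),
            bf_link=InhibitoryLink(0.0, 1.0, 1.0))
        assert classify_memory(ModelClass.CIPF, p,
                               1.0) is MemoryClass.NONE


class TestWashout:
    def _protocol(self, **kw):
        defaults = dict(prestim_dose=100.0, prestim_duration=50.0,
                        residual_tau=50.0,
                        reapplied_doses=np.array([0.0, 0.1, 0.3, 1.0, 5.0]),
                        readout_time=10.0, inhibitor_applied=False)
        defaults.update(kw)
        return WashoutProtocol(**defaults)

    def test_long_residual_short_readout_apparent_irreversibility(
            self, toggle_params, fgf_level):
        tab = simulate_washout(ModelClass.CIPF, toggle_params,
                               self._protocol(), fgf_level)
        on = tab[tab.initial_state == "on"].sort_values("reapplied_dose")
        off = tab[tab.initial_state == "off"].sort_values("reapplied_dose")
        # pre-stimulated cells stay high at every reapplied dose
        assert (on.response.values > 0.8 * on.response.max()).all()
        assert on.response.values[0] > 3.0 * off.response.values[0]

    def test_inhibitor_reveals_hysteresis(self, toggle_params, fgf_level):
        tab = simulate_washout(
            ModelClass.CIPF, toggle_params,
            self._protocol(inhibitor_applied=True, readout_time=300.0),
            fgf_level)
        on = tab[tab.initial_state == "on"].sort_values("reapplied_dose")
        off = tab[tab.initial_state == "off"].sort_values("reapplied_dose")
        # curves meet at the saturating end ...
        assert on.response.values[-1] == pytest.approx(
            off.response.values[-1], rel=0.05)
        # ... and the on-curve returns to baseline at zero reapplied dose
        assert on.response.values[0] == pytest.approx(
            off.response.values[0], rel=0.05, abs=1e-9)

    def test_monostable_curves_coincide(self, fgf_level):
        rng = np.random.default_rng(6)
        p = random_params(rng, n_inh=1.0)   # all-linear: never bistable
        tab = simulate_washout(
            ModelClass.CIPF, p,
            self._protocol(inhibitor_applied=True, readout_time=500.0,
                           reapplied_doses=np.array([0.0, 0.5, 2.0])),
            1.0)
        on = tab[tab.initial_state == "on"].sort_values("reapplied_dose")
        off = tab[tab.initial_state == "off"].sort_values("reapplied_dose")
        np.testing.assert_allclose(on.response.values, off.response.values,
                                   rtol=1e-3, atol=1e-9)

    def test_washout_limit_converges_to_hysteresis_branches(
            self, toggle_params, fgf_level):
        # no residual signal, late readout: the washout outputs are the
        # hysteresis branches themselves
        doses = np.geomspace(toggle_params.K_tb / 10,
                             toggle_params.K_tb * 10, 7)
        tab = simulate_washout(
            ModelClass.CIPF, toggle_params,
            self._protocol(inhibitor_applied=True, readout_time=2000.0,
                           reapplied_doses=doses),
            fgf_level)
        res = hysteresis_curves(ModelClass.CIPF, toggle_params, doses,
                                fgf_level)
        on = tab[tab.initial_state == "on"].sort_values("reapplied_dose")
        off = tab[tab.initial_state == "off"].sort_values("reapplied_dose")
        scale = res.on_curve.responses.max()
        np.testing.assert_allclose(off.response.values,
                                   res.off_curve.responses,
                                   atol=1e-4 * scale)
        np.testing.assert_allclose(on.response.values,
                                   res.on_curve.responses,
                                   atol=1e-4 * scale)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            self._protocol(readout_time=-1.0)
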