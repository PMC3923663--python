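import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphotoggle.model_core import (InhibitoryLink, ModelClass,
                                     ModelParameters, SelfActivation,
                                     build_rhs, build_topology_rhs,
                                     hill_activation, inhibition_factor,
                                     nondimensionalize)
from morphotoggle.response_analysis import compute_dose_response, fit_hill
from morphotoggle.steady_state import integrate_to_steady
from morphotoggle.topology_space import Topology

from conftest import random_params


class TestHillActivation:
    @pytest.mark.parametrize("x,k,n,expected", [
        (2.0, 2.0, 1.0, 0.5),      # half-saturation by definition
        (2.0, 2.0, 7.0, 0.5),
        (0.0, 1.0, 2.0, 0.0),      # zero input
        (3.0, 1.0, 2.0, 0.9),      # 9 / (1 + 9)
    ])
    def test_values(self, x, k, n, expected):
        assert hill_activation(x, k, n) == pytest.approx(expected)

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(1, 8))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_monotone(self, x, k, n):
        y = hill_activation(x, k, n)
        # mathematically < 1, but (k/x)^n can underflow to 0 in floats
        assert 0.0 <= y <= 1.0
        assert hill_activation(x * 1.5, k, n) >= y
        assert hill_activation(x, k * 1.5, n) <= y

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            hill_activation(1.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            hill_activation(1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            hill_activation(-1.0, 1.0, 1.0)


class TestInhibitionFactor:
    def test_no_inhibitor_gives_unity(self):
        link = InhibitoryLink(p=0.7, k=2.0, n=3.0)
        assert inhibition_factor(0.0, link) == 1.0

    def test_asymptote_is_one_minus_p(self):
        link = InhibitoryLink(p=0.88, k=1.0, n=1.0)
        assert inhibition_factor(1e9, link) == pytest.approx(0.12, abs=1e-6)

    def test_half_saturation_value(self):
        link = InhibitoryLink(p=0.88, k=5.0, n=1.0)
        assert inhibition_factor(5.0, link) == pytest.approx(0.56)

    def test_divisive_limit(self):
        # p = 1 is the divisive form 1 / (1 + (x/k)^n)
        link = InhibitoryLink(p=1.0, k=2.0, n=4.0)
        x = 3.0
        assert inhibition_factor(x, link) == pytest.approx(
            1.0 / (1.0 + (x / 2.0) ** 4))

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_antitone(self, x1, x2):
        link = InhibitoryLink(p=0.9, k=1.0, n=2.0)
        lo, hi = sorted([x1, x2])
        assert inhibition_factor(hi, link) <= inhibition_factor(lo, link)

    def test_link_validation(self):
        with pytest.raises(ValueError):
            InhibitoryLink(p=1.2, k=1.0, n=1.0)
        with pytest.raises(ValueError):
            InhibitoryLink(p=0.5, k=-1.0, n=1.0)


class TestBuildRhs:
    def test_origin_is_fixed_point_without_inputs(self, toggle_params):
        rhs = build_rhs(ModelClass.CIPF, toggle_params)
        np.testing.assert_allclose(rhs(np.zeros(3), 0.0, 0.0), 0.0)

    def test_sti_production_only_from_zero_state(self, toggle_params):
        rhs = build_rhs(ModelClass.STI, toggle_params)
        d = rhs(np.zeros(3), 5.0, 0.0)
        expected = toggle_params.kc1 * hill_activation(
            5.0, toggle_params.K_tb, toggle_params.n1)
        assert d[0] == pytest.approx(expected)
        assert d[1] == 0.0 and d[2] == 0.0

    def test_cipf_terms_match_hand_evaluation(self, toggle_params):
        # independent term-by-term evaluation with plain formulas
        p = toggle_params
        rhs = build_rhs(ModelClass.CIPF, p)
        B, F = 0.8, 0.6
        y = np.array([0.3, 0.2, 0.1])
        hb = B ** p.n1 / (p.K_tb ** p.n1 + B ** p.n1)
        hf = F ** p.n2 / (p.K_tf ** p.n2 + F ** p.n2)
        ht = y[0] ** p.n3 / (p.K_tbt ** p.n3 + y[0] ** p.n3)
        inh_fi = 1 - p.fb_link.p * y[1] ** p.fb_link.n / (
            p.fb_link.k ** p.fb_link.n + y[1] ** p.fb_link.n)
        inh_bi = 1 - p.bf_link.p * y[0] ** p.bf_link.n / (
            p.bf_link.k ** p.bf_link.n + y[0] ** p.bf_link.n)
        expected = np.array([
            p.kc1 * hb * inh_fi - p.K_BI * y[0],
            p.kc3 * hf * inh_bi - p.K_FI * y[1],
            p.kc5 * ht - p.K_BT * y[2],
        ])
        np.testing.assert_allclose(rhs(y, B, F), expected, rtol=1e-12)

    def test_unknown_class_rejected(self, toggle_params):
        with pytest.raises(ValueError):
            build_rhs("XYZ", toggle_params)

    def test_autoreg_requires_self_activation(self, toggle_params):
        with pytest.raises(ValueError):
            build_rhs(ModelClass.AUTOREG, toggle_params)

    def test_states_remain_nonnegative(self, toggle_params):
        rhs = build_rhs(ModelClass.CIPF, toggle_params)
        y, ok, _ = integrate_to_steady(rhs, [0.0, 0.5, 0.0], 2.0, 0.5)
        assert ok and np.all(y >= 0)


class TestTopologyRhs:
    def test_representative_cipf_identity(self, toggle_params):
        # (F_I -| B_I, B_I -| F_I) must reproduce the CIPF class model
        topo = Topology(1, 1, 1, 1)
        rhs_t = build_topology_rhs(topo, toggle_params)
        rhs_c = build_rhs(ModelClass.CIPF, toggle_params)
        rng = np.random.default_rng(0)
        for _ in range(5):
            y4 = rng.uniform(0, 2, size=4)
            d4 = rhs_t(y4, 1.3, 0.7)
            d3 = rhs_c(y4[:3], 1.3, 0.7)
            np.testing.assert_allclose(d4[:3], d3, rtol=1e-12)

    def test_inert_bf_link_leaves_bt_sti_like(self, toggle_params):
        # (F_I -| B_T, B_I -| F_T): the B->F link cannot reach B_T
        topo = Topology(1, 2, 1, 2)
        rhs_t = build_topology_rhs(topo, toggle_params)
        rhs_s = build_rhs(ModelClass.STI, toggle_params)
        y, ok, _ = integrate_to_steady(rhs_t, np.zeros(4), 2.0, 0.8)
        ys, ok2, _ = integrate_to_steady(rhs_s, np.zeros(3), 2.0, 0.8)
        assert ok and ok2
        np.testing.assert_allclose(y[2], ys[2], rtol=1e-8)

    def test_downstream_bf_link_removal_preserves_bt(self):
        # B->F link landing downstream of the F->B source is inert for B_T
        rng = np.random.default_rng(3)
        params = random_params(rng, n_inh=2.0)
        topo = Topology(1, 1, 1, 2)       # F_I -| B_I, B_I -| F_T
        rhs_t = build_topology_rhs(topo, params)
        no_bf = params.with_(bf_link=InhibitoryLink(p=0.0, k=1.0, n=1.0))
        rhs_0 = build_topology_rhs(topo, no_bf)
        for dose in (0.2, 2.0):
            y1, _, _ = integrate_to_steady(rhs_t, np.zeros(4), dose, 1.0)
            y0, _, _ = integrate_to_steady(rhs_0, np.zeros(4), dose, 1.0)
            assert y1[2] == pytest.approx(y0[2], rel=1e-8)


class TestClassReductions:
    def test_all_classes_reduce_to_core_without_links(self):
        rng = np.random.default_rng(11)
        params = random_params(rng).with_(
            fb_link=InhibitoryLink(p=0.0, k=1.0, n=1.0),
            bf_link=InhibitoryLink(p=0.0, k=1.0, n=1.0))
        curves = []
        for mc in ("STI", "SUI", "CFF", "CIPF"):
            dr = compute_dose_response(mc, params, fgf_level=1.0)
            curves.append(dr.responses)
        for c in curves[1:]:
            np.testing.assert_allclose(c, curves[0], rtol=1e-9)

    def test_cipf_reduces_to_sui_without_return_link(self, toggle_params,
                                                     fgf_level):
        params = toggle_params.with_(
            bf_link=InhibitoryLink(p=0.0, k=toggle_params.bf_link.k,
                                   n=toggle_params.bf_link.n))
        cipf = compute_dose_response("CIPF", params, fgf_level=fgf_level)
        sui = compute_dose_response("SUI", params, fgf_level=fgf_level)
        np.testing.assert_allclose(cipf.responses, sui.responses, rtol=1e-6)


class TestNondimensionalize:
    def test_already_scaled_bt_equation_unchanged(self, toggle_params):
        # kc5 = K_BT = 1 in the example set: B_T equation is untouched
        nd = nondimensionalize(toggle_params)
        assert nd.kc5 == 1.0 and nd.K_BT == 1.0

    def test_nh_invariant_and_max_rescaled(self):
        rng = np.random.default_rng(5)
        params = random_params(rng, n_inh=4.0).with_(kc5=3.0, K_BT=0.5)
        nd = nondimensionalize(params)
        grid = np.geomspace(params.K_tb / 100, params.K_tb * 100, 40)
        dr = compute_dose_response("CIPF", params, grid, 1.0)
        dr_nd = compute_dose_response("CIPF", nd, grid, 1.0)
        f, f_nd = fit_hill(dr), fit_hill(dr_nd)
        assert f.nH == pytest.approx(f_nd.nH, rel=1e-5)
        assert f.ec50 == pytest.approx(f_nd.ec50, rel=1e-5)
        scale = params.kc5 / params.K_BT
        np.testing.assert_allclose(dr.responses, dr_nd.responses * scale,
                                   rtol=1e-9)


class TestParameterSerialization:
    def test_flat_dict_roundtrip(self, autoreg_params):
        d = autoreg_params.to_flat_dict()
        back = ModelParameters.from_flat_dict(d)
        assert back == autoreg_params
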