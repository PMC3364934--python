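import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from cycloclock.cdk import CDK_STATE_NAMES, CdkParams
from cycloclock.clock import CLOCK_STATE_NAMES, ClockParams, LDSchedule
from cycloclock.coupling import (CouplingParams, assemble_coupled_system,
                                 coupled_init, cyclinE_coupling_rhs,
                                 p21_coupling_rhs, wee1_mrna_rhs,
                                 wee1_protein_synthesis)


class TestWee1Channel:
    def test_zero_everything(self):
        assert wee1_mrna_rhs(0.0, 0.0, CouplingParams()) == 0.0

    def test_half_saturation(self):
        p = CouplingParams(v_sw=0.1)
        assert wee1_mrna_rhs(0.0, p.K_aw, p) == pytest.approx(0.05)

    def test_saturated_minus_degradation(self):
        # v_sw=0.1, Bn >> K_aw, Mw = K_dmw -> 0.1 - 0.5/2 = -0.15
        p = CouplingParams(v_sw=0.1)
        assert wee1_mrna_rhs(0.5, 1e6, p) == pytest.approx(-0.15, rel=1e-4)

    def test_protein_synthesis_examples(self):
        p = CouplingParams()
        assert wee1_protein_synthesis(0.0, p, v_swee1=0.06) == pytest.approx(0.06)
        assert wee1_protein_synthesis(0.0, p, v_swee1=0.0) == 0.0
        assert wee1_protein_synthesis(0.02, p, v_swee1=0.0) == pytest.approx(0.1)

    @given(bn1=st.floats(0, 100), bn2=st.floats(0, 100), mw=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_bn(self, bn1, bn2, mw):
        p = CouplingParams()
        lo, hi = sorted((bn1, bn2))
        assert wee1_mrna_rhs(mw, hi, p) >= wee1_mrna_rhs(mw, lo, p) - 1e-12


class TestP21Channel:
    def test_no_repression(self):
        p = CouplingParams()
        dm, _ = p21_coupling_rhs(0.0, 0.0, p)
        assert dm == pytest.approx(p.v_smp21)

    def test_half_repression(self):
        p = CouplingParams()
        dm, _ = p21_coupling_rhs(0.0, p.K_ip21, p)
        assert dm == pytest.approx(p.v_smp21 / 2)

    def test_protein_contribution(self):
        p = CouplingParams()
        _, contrib = p21_coupling_rhs(0.1, 0.0, p)
        assert contrib == pytest.approx(p.v_s1p21 * 0.1)

    def test_unrepressed_steady_state_value(self):
        # closed form: v_smp21 = V_dmp21 * M / (K_dmp21 + M)
        p = CouplingParams(v_smp21=0.46)
        m_ss = p.K_dmp21 * p.v_smp21 / (p.V_dmp21 - p.v_smp21)
        assert m_ss == pytest.approx(5.75)
        assert p21_coupling_rhs(m_ss, 0.0, p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_rise_to_steady_state(self):
        p = CouplingParams(v_smp21=0.46)
        sol = solve_ivp(lambda t, y: [p21_coupling_rhs(y[0], 0.0, p)[0]],
                        (0, 2000), [0.0], rtol=1e-9, atol=1e-12, dense_output=True)
        m = sol.sol(np.linspace(0, 2000, 500))[0]
        assert np.all(np.diff(m) > -1e-9)          # monotone increase
        assert m[-1] == pytest.approx(5.75, rel=1e-3)

    @given(rn1=st.floats(0, 100), rn2=st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_antimonotone_in_rn(self, rn1, rn2):
        p = CouplingParams()
        lo, hi = sorted((rn1, rn2))
        assert p21_coupling_rhs(0.1, hi, p)[0] <= p21_coupling_rhs(0.1, lo, p)[0] + 1e-12


class TestCyclinEChannel:
    def test_no_repression(self):
        p = CouplingParams(v_sce=0.1)
        assert cyclinE_coupling_rhs(0.0, 0.0, p)[0] == pytest.approx(0.1)

    def test_half_point(self):
        p = CouplingParams(v_sce=0.1)
        assert cyclinE_coupling_rhs(0.0, p.K_ice, p)[0] == pytest.approx(0.05)

    def test_full_repression_limit(self):
        p = CouplingParams(v_sce=0.1)
        assert cyclinE_coupling_rhs(0.0, 1e9, p)[0] == pytest.approx(0.0, abs=1e-12)

    @given(bn1=st.floats(0, 100), bn2=st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_antimonotone_in_bn(self, bn1, bn2):
        p = CouplingParams(v_sce=0.1)
        lo, hi = sorted((bn1, bn2))
        assert cyclinE_coupling_rhs(0.2, hi, p)[0] <= \
            cyclinE_coupling_rhs(0.2, lo, p)[0] + 1e-12


class TestClampedSteadyStates:
    """Each mRNA converges to the unique root of its scalar equation."""

    @pytest.mark.parametrize("channel,driver", [
        ("wee1", 3.0), ("p21", 0.4), ("cyclinE", 0.4)])
    def test_scalar_convergence(self, channel, driver):
        p = CouplingParams(v_sce=0.1)
        fn = {"wee1": lambda m: wee1_mrna_rhs(m, driver, p),
              "p21": lambda m: p21_coupling_rhs(m, driver, p)[0],
              "cyclinE": lambda m: cyclinE_coupling_rhs(m, driver, p)[0]}[channel]
        root = brentq(fn, 0.0, 1e4)
        sol = solve_ivp(lambda t, y: [fn(y[0])], (0, 5000), [0.0],
                        rtol=1e-9, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(root, rel=1e-3, abs=1e-8)


class TestAssembly:
    def test_mu_mode_requires_unit_rates(self):
        with pytest.raises(ValueError, match="mu-mode"):
            CouplingParams(modes=("wee1",), v_sw=0.1, mu=0.01)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown coupling mode"):
            CouplingParams(modes=("weeX",))

    def test_state_vector_layout(self):
        cp = CouplingParams(modes=("wee1", "p21", "cyclinE"),
                            v_sw=1.0, v_smp21=1.0, v_sce=1.0, mu=0.01)
        model = assemble_coupled_system(coupling=cp)
        assert model.state_names == CLOCK_STATE_NAMES + CDK_STATE_NAMES + \
            ("Mw", "Mp21", "Mce")
        assert coupled_init(cp).size == len(model.state_names)

    def test_all_modes_off_is_direct_sum(self):
        """With no coupling channel the rhs equals clock ⊕ Cdk rhs."""
        from cycloclock.cdk import ZERO_INPUTS, cdk_rhs
        from cycloclock.clock import clock_rhs

        cp = CouplingParams(modes=())
        model = assemble_coupled_system(coupling=cp)
        rng = np.random.default_rng(0)
        y = rng.uniform(0.05, 1.0, size=len(model.state_names))
        got = model.rhs(3.0, y, model.default_params)
        want = np.concatenate([
            clock_rhs(y[:5], ClockParams(), 3.0, LDSchedule()),
            cdk_rhs(y[5:], CdkParams(), ZERO_INPUTS, 3.0),
        ])
        assert np.allclose(got, want)

    def test_mu_zero_adds_no_synthesis(self):
        cp = CouplingParams(modes=("wee1",), v_sw=1.0, v_smp21=1.0,
                            v_sce=1.0, mu=0.0)
        assert wee1_mrna_rhs(0.0, 100.0, cp) == pytest.approx(0.0)

    def test_mu_mode_equals_single_mode_at_same_rate(self):
        """mu * 1 µM/h == v_sw: identical trajectories."""
        from cycloclock.core import SimulationConfig, integrate

        cdk = CdkParams()
        cfg = SimulationConfig(t_end=200.0, dt_out=0.5)
        cp_mu = CouplingParams(modes=("wee1",), v_sw=1.0, v_smp21=1.0,
                               v_sce=1.0, mu=0.05)
        cp_direct = CouplingParams(modes=("wee1",), v_sw=0.05)
        t1 = integrate(assemble_coupled_system(cdk, coupling=cp_mu),
                       coupled_init(cp_mu), cfg)
        t2 = integrate(assemble_coupled_system(cdk, coupling=cp_direct),
                       coupled_init(cp_direct), cfg)
        assert np.allclose(t1.states, t2.states, rtol=1e-5, atol=1e-7)
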