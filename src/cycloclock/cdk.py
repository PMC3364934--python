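"""Reduced reference Cdk-network oscillator (13 state variables).

The network follows the canonical module logic: growth factor drives cyclin
D synthesis; cyclin D/Cdk4-6 and cyclin E/Cdk2 inactivate pRB, releasing
E2F; E2F drives cyclin E and cyclin A synthesis; cyclin A/Cdk2 degrades
E2F and inactivates Cdh1, letting cyclin B accumulate; the cyclin B/Cdk1
switch (Wee1/Cdc25 double positive feedback, steep Hill terms) fires a
large mitotic spike that activates Cdc20, which degrades cyclins A and B
and resets the cycle. p21 inhibits Cdk activities through quasi-equilibrium
factors 1/(1 + P/K); Wee1 inhibits Cdk1 strongly and Cdk2 weakly (relative
weight ``rho2``). A stand-in ATR/Chk1 checkpoint species X, activated in
proportion to S-phase Cdk2 activity at rate ``k_aatr``, inhibits Cdc25.

Every derivative is multiplied by the global time-scale factor ``s``, so
the autonomous period obeys T(s) = T_ref / s exactly (uniform rescaling).
Concentrations in µM, time in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ModelSpec, SimulationConfig, find_attractor

__all__ = ["CdkParams", "CDK_STATE_NAMES", "CDK_INIT", "cdk_rhs",
           "CouplingInputs", "cdk_model", "autonomous_period", "gf_threshold"]

CDK_STATE_NAMES = ("Rb", "E2F", "Md", "Me", "Ma", "Cb", "Mb",
                   "W", "C25", "Ch1", "A20", "P", "X")

CDK_INIT = np.array([
    1.0,   # Rb
    0.5,   # E2F
    0.3,   # Md
    0.05,  # Me
    0.05,  # Ma
    0.10,  # Cb
    0.01,  # Mb
    0.0,   # W
    1.0,   # C25
    0.9,   # Ch1
    0.0,   # A20
    0.02,  # P
    0.0,   # X
])


@dataclass(frozen=True)
class CdkParams:
    """Default parameter set of the reduced Cdk network.

    The set was calibrated once (deterministic procedure: start from a
    relaxation regime with steep Goldbeter-Koshland-type switches, then
    adjust until the invariant suite passes) and ships frozen.
    """

    s: float = 1.0            # global time-scale multiplier
    GF: float = 1.0           # µM, growth factor level
    # growth factor -> cyclin D
    v_sd: float = 0.5         # µM/h
    K_agf: float = 0.1        # µM, GF half-saturation
    k_dd: float = 0.4         # 1/h
    k_dd_e: float = 2.0       # 1/(µM h), cyclin D clearance by cyclin E/Cdk2
    # pRB / E2F balance
    v_spRB: float = 0.8       # µM/h, pRB synthesis
    k_dRb: float = 0.3        # 1/h
    V_phRb: float = 1.6       # 1/h, pRB inactivation by cyclin/Cdk
    K_phRb: float = 0.1       # µM
    eta_e: float = 2.5        # cyclin E/Cdk2 weight on pRB phosphorylation
    eta_a: float = 0.3        # cyclin A/Cdk2 weight
    v_sE2F: float = 0.3       # µM/h, max E2F synthesis
    a_e2f: float = 0.1        # basal fraction of E2F synthesis
    K_ae2f: float = 0.1       # µM, E2F autoactivation threshold
    k_dE2F: float = 0.2       # 1/h
    k_dE2F_a: float = 6.0     # 1/(µM h), E2F degradation by cyclin A/Cdk2
    K_IRb: float = 0.06       # µM, E2F inhibition by pRB
    # cyclin E/Cdk2
    v_se: float = 1.2         # µM/h
    k_de0: float = 0.25       # 1/h
    k_de_a: float = 1.5       # 1/(µM h), degradation driven by cyclin A/Cdk2
    # cyclin A/Cdk2
    v_sa: float = 0.35        # µM/h
    k_da0: float = 0.01       # 1/h
    k_da_ch1: float = 1.0     # 1/h (x Cdh1)
    k_da_a20: float = 2.5     # 1/h (x Cdc20)
    # cyclin B pool
    v_cb: float = 0.055       # µM/h, cyclin B synthesis
    k_dcb0: float = 0.01      # 1/h
    k_dcb_ch1: float = 0.02   # 1/h (x Cdh1)
    k_dcb_a20: float = 1.0    # 1/h (x Cdc20), partial teardown at mitosis
    # Cdk1 switch
    k25_0: float = 0.1        # 1/h, basal Cdk1 activation
    k25_1: float = 3.0        # 1/(µM h), Cdc25-mediated activation
    K_ma25: float = 0.12      # µM, cyclin A/Cdk2 requirement for Cdk1 activation
    K_afb: float = 0.2        # µM, Cdk1 threshold of the Cdc25 feedback
    n_fb: int = 4
    k_wee0: float = 0.5       # 1/h, basal Cdk1 inactivation
    k_wee1: float = 10.0      # 1/(µM h), Wee1-mediated inactivation
    beta_w: float = 0.1       # residual Wee1 activity at high Cdk1
    K_ifb: float = 0.2        # µM, Cdk1 threshold of Wee1 inactivation
    # Wee1 protein
    v_swee1: float = 0.06     # µM/h, clock-independent Wee1 synthesis
    k_dw: float = 1.0         # 1/h
    rho2: float = 0.1         # relative Wee1 weight on Cdk2
    K_w2: float = 0.5         # µM
    # Cdc25 protein
    v_spbi: float = 0.12      # µM/h, Cdc25 synthesis
    k_d25: float = 0.12       # 1/h
    # Cdh1 / Cdc20 switches
    V_ach1: float = 0.45      # µM/h
    k_ich1_e: float = 1.0     # 1/(µM h), Cdh1 inactivation by cyclin E/Cdk2
    k_ich1_a: float = 4.0     # 1/(µM h), by cyclin A/Cdk2 (persistent G2)
    k_ich1_b: float = 1.0     # 1/(µM h), by cyclin B/Cdk1
    K_gk: float = 0.01        # Goldbeter-Koshland saturation constant
    k_aa20: float = 1.0       # 1/(µM h), Cdc20 activation by Cdk1
    k_aa20_a: float = 0.3     # 1/(µM h), weak Cdc20 activation by cyclin A/Cdk2
    v_ia20: float = 0.3       # µM/h, Cdc20 inactivation
    # p21
    v_bp21: float = 0.01      # µM/h, basal p21 synthesis
    v_ep21: float = 0.05      # µM/h, E2F-activated p21 synthesis
    k_dp21: float = 1.0       # 1/h
    K_ip1: float = 2.0        # µM, p21 inhibition of Cdk1
    K_ip2: float = 2.0        # µM, p21 inhibition of Cdk2
    # ATR/Chk1 checkpoint stand-in
    k_aatr: float = 0.0       # 1/(µM h), checkpoint activation rate
    k_iatr: float = 0.2       # 1/h
    X_tot: float = 1.0        # µM
    K_ix: float = 0.3         # µM, Cdc25 inhibition by X


@dataclass(frozen=True)
class CouplingInputs:
    """Clock-driven synthesis contributions routed into the Cdk network."""

    wee1_synthesis: float = 0.0    # µM/h, k_sw * Mw
    p21_synthesis: float = 0.0     # µM/h, v_s1p21 * Mp21
    cyclinE_synthesis: float = 0.0  # µM/h, k_ce2 * Mce


ZERO_INPUTS = CouplingInputs()


@dataclass(frozen=True)
class GFSquareWave:
    """Square-wave growth-factor forcing active on [t_start, t_end).

    GF alternates between ``low`` and ``high`` every ``half_period`` hours
    (starting at ``low``); outside the window the baseline ``CdkParams.GF``
    applies.
    """

    t_start: float = 120.0
    t_end: float = np.inf
    low: float = 0.0
    high: float = 1.0
    half_period: float = 12.0
    start_high: bool = False   # first half-period at ``high`` (quiescent start)

    def value(self, t: float, baseline: float) -> float:
        if t < self.t_start or t >= self.t_end:
            return baseline
        k = int(np.floor((t - self.t_start) / self.half_period))
        first, second = (self.high, self.low) if self.start_high \
            else (self.low, self.high)
        return first if k % 2 == 0 else second

    def switch_times(self, t0: float, t1: float) -> np.ndarray:
        edges = [self.t_start]
        k, t = 1, self.t_start + self.half_period
        while t < min(t1, self.t_end) + self.half_period and k < 100000:
            edges.append(t)
            t += self.half_period
            k += 1
        if np.isfinite(self.t_end):
            edges.append(self.t_end)
        edges = np.asarray(edges)
        return edges[(edges > t0) & (edges < t1)]


def _activities(y, p: CdkParams):
    Rb, E2F, Md, Me, Ma, Cb, Mb, W, C25, Ch1, A20, P, X = y
    inh2 = (1.0 + P / p.K_ip2) * (1.0 + p.rho2 * W / p.K_w2)
    me_act = Me / inh2
    ma_act = Ma / inh2
    md_act = Md / inh2
    cdk1 = Mb / (1.0 + P / p.K_ip1)
    e2f_act = E2F * p.K_IRb / (p.K_IRb + Rb)
    return md_act, me_act, ma_act, cdk1, e2f_act


def cdk_rhs(y, p: CdkParams, inputs: CouplingInputs = ZERO_INPUTS, t: float = 0.0,
            gf: float | None = None):
    """Derivatives of the 13-variable network (already multiplied by s)."""
    Rb, E2F, Md, Me, Ma, Cb, Mb, W, C25, Ch1, A20, P, X = y
    md_act, me_act, ma_act, cdk1, e2f_act = _activities(y, p)

    GF = p.GF if gf is None else gf
    gf_term = GF / (p.K_agf + GF) if GF > 0 else 0.0
    dMd = p.v_sd * gf_term - (p.k_dd + p.k_dd_e * me_act) * Md

    phos = p.V_phRb * (Md + p.eta_e * me_act + p.eta_a * ma_act)
    dRb = p.v_spRB - phos * Rb / (p.K_phRb + Rb) - p.k_dRb * Rb
    auto = e2f_act ** 2 / (p.K_ae2f ** 2 + e2f_act ** 2)
    dE2F = p.v_sE2F * (p.a_e2f + (1.0 - p.a_e2f) * auto) \
        - (p.k_dE2F + p.k_dE2F_a * ma_act) * E2F

    dMe = p.v_se * e2f_act + inputs.cyclinE_synthesis \
        - (p.k_de0 + p.k_de_a * ma_act) * Me
    dMa = p.v_sa * e2f_act - (p.k_da0 + p.k_da_ch1 * Ch1 + p.k_da_a20 * A20) * Ma

    deg_b = p.k_dcb0 + p.k_dcb_ch1 * Ch1 + p.k_dcb_a20 * A20
    dCb = p.v_cb - deg_b * Cb

    hill_a = cdk1 ** p.n_fb / (p.K_afb ** p.n_fb + cdk1 ** p.n_fb)
    # mitotic entry requires S/G2 cyclin A/Cdk2 activity (Cdc25 priming)
    ma_gate = ma_act ** 2 / (p.K_ma25 ** 2 + ma_act ** 2)
    v25 = (p.k25_0 + p.k25_1 * C25 * hill_a * p.K_ix / (p.K_ix + X)) * ma_gate
    wee_act = p.beta_w + (1.0 - p.beta_w) * \
        p.K_ifb ** p.n_fb / (p.K_ifb ** p.n_fb + cdk1 ** p.n_fb)
    vwee = p.k_wee0 + p.k_wee1 * W * wee_act
    dMb = v25 * (Cb - Mb) - vwee * Mb - deg_b * Mb

    dW = p.v_swee1 + inputs.wee1_synthesis - p.k_dw * W
    dC25 = p.v_spbi - p.k_d25 * C25

    i_ch1 = p.k_ich1_e * me_act + p.k_ich1_a * ma_act + p.k_ich1_b * cdk1
    dCh1 = p.V_ach1 * (1.0 - Ch1) / (p.K_gk + 1.0 - Ch1) \
        - i_ch1 * Ch1 / (p.K_gk + Ch1)
    dA20 = (p.k_aa20 * cdk1 + p.k_aa20_a * ma_act) \
        * (1.0 - A20) / (p.K_gk + 1.0 - A20) \
        - p.v_ia20 * A20 / (p.K_gk + A20)

    dP = p.v_bp21 + p.v_ep21 * e2f_act + inputs.p21_synthesis - p.k_dp21 * P
    dX = p.k_aatr * ma_act * (p.X_tot - X) - p.k_iatr * X

    dy = np.array([dRb, dE2F, dMd, dMe, dMa, dCb, dMb,
                   dW, dC25, dCh1, dA20, dP, dX])
    return p.s * dy


def _observables():
    def wrap(fn):
        def obs(t, states, params):
            p = params["cdk"]
            return np.array([fn(y, p) for y in states])
        return obs

    return {
        "Cdk1": wrap(lambda y, p: _activities(y, p)[3]),
        "Cdk2": wrap(lambda y, p: _activities(y, p)[1] + _activities(y, p)[2]),
        "CycE_Cdk2": wrap(lambda y, p: _activities(y, p)[1]),
        "CycA_Cdk2": wrap(lambda y, p: _activities(y, p)[2]),
        "CycD_Cdk46": wrap(lambda y, p: _activities(y, p)[0]),
        "E2F_active": wrap(lambda y, p: _activities(y, p)[4]),
    }


def cdk_model(params: CdkParams = CdkParams(),
              gf_schedule: GFSquareWave | None = None) -> ModelSpec:
    """Autonomous Cdk network as a :class:`ModelSpec` (no clock inputs)."""

    def rhs(t, y, pmap):
        p = pmap["cdk"]
        sched = pmap.get("gf")
        gf = sched.value(t, p.GF) if sched is not None else None
        return cdk_rhs(y, p, ZERO_INPUTS, t, gf=gf)

    def discont(pmap, t0, t1):
        sched = pmap.get("gf")
        return sched.switch_times(t0, t1) if sched is not None else np.array([])

    return ModelSpec(
        state_names=CDK_STATE_NAMES,
        rhs=rhs,
        observables=_observables(),
        default_params={"cdk": params, "gf": gf_schedule},
        discontinuities=discont,
        nonnegative=True,
    )


def autonomous_period(params: CdkParams, t_end: float = 1200.0,
                      t_transient: float = 400.0) -> float | None:
    """Free-running Cdk1 period in hours, or None when quiescent.

    Integrates the uncoupled network and applies the attractor test; the
    result carries the exact 1/s scaling of the uniform time rescale.
    """
    cfg = SimulationConfig(t_end=t_end, t_transient=t_transient, dt_out=0.1)
    res = find_attractor(cdk_model(params), CDK_INIT, cfg,
                         reference_observable="Cdk1")
    if res.kind == "steady_state":
        return None
    if res.kind == "limit_cycle":
        return res.period
    raise RuntimeError("attractor search undecided; increase t_end")


def gf_threshold(params: CdkParams, lo: float = 0.0, hi: float = 1.0,
                 tol: float = 1e-3) -> float:
    """Oscillation-onset growth factor level, by bisection on [lo, hi]."""

    def oscillates(gf: float) -> bool:
        try:
            return autonomous_period(replace(params, GF=gf)) is not None
        except RuntimeError:
            # slow damped transients near onset count as non-oscillating
            return False

    if not oscillates(hi):
        raise ValueError("no threshold in range: quiescent at upper bound")
    if oscillates(lo):
        raise ValueError("no threshold in range: oscillatory at lower bound")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if oscillates(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
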