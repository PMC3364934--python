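"""Circadian-controlled mRNA channels coupling the clock to the Cdk network.

Three unidirectional channels link the LD-entrained clock to the cell
cycle: CLOCK-BMAL1 (Bn) activates Wee1 mRNA synthesis (Hill exponent
``n_aw``); REV-ERBα (Rn) represses p21 mRNA synthesis; Bn represses cyclin
E mRNA synthesis. Each mRNA feeds a protein-synthesis contribution into
the Cdk network (k_sw·Mw to Wee1, v_s1p21·Mp21 to p21, k_ce2·Mce to cyclin
E/Cdk2). In multi-coupling (μ) mode every active mRNA synthesis rate is
pinned to 1 µM/h and multiplied by the dimensionless strength μ.

Units bridge: Bn and Rn are in nM (clock side), mRNAs and proteins in µM
(Cdk side); the Hill ratios Bn/K_aw, Rn/K_ip21, Bn/K_ice are dimensionless
so no conversion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cdk import (CDK_INIT, CDK_STATE_NAMES, CdkParams, CouplingInputs,
                  GFSquareWave, _activities, cdk_rhs)
from .clock import CLOCK_INIT, CLOCK_STATE_NAMES, ClockParams, LDSchedule, \
    bn_of_per, clock_rhs
from .core import ModelSpec

__all__ = [
    "CouplingParams",
    "wee1_mrna_rhs",
    "wee1_protein_synthesis",
    "p21_coupling_rhs",
    "cyclinE_coupling_rhs",
    "assemble_coupled_system",
    "coupled_init",
]

MODES = ("wee1", "p21", "cyclinE")


@dataclass(frozen=True)
class CouplingParams:
    """Parameters of the three coupling channels plus the μ scheme."""

    modes: tuple[str, ...] = ()
    # Wee1 channel
    v_sw: float = 0.1         # µM/h, clock-controlled Wee1 mRNA synthesis
    K_aw: float = 2.0         # nM, Bn activation constant
    n_aw: int = 4             # Hill exponent (nmw)
    V_dmw: float = 0.5        # µM/h
    K_dmw: float = 0.5        # µM
    k_sw: float = 5.0         # 1/h, Wee1 translation
    # p21 channel
    v_smp21: float = 0.46     # µM/h, max p21 mRNA synthesis
    K_ip21: float = 0.05      # nM, repression by Rn
    nmp21: int = 1
    V_dmp21: float = 0.5      # µM/h
    K_dmp21: float = 0.5      # µM
    v_s1p21: float = 50.0     # 1/h, p21 translation
    # cyclin E channel
    v_sce: float = 0.1        # µM/h, max cyclin E mRNA synthesis
    K_ice: float = 1.0        # nM, repression by Bn
    nce: int = 4
    V_dmce: float = 0.5       # µM/h
    K_dmce: float = 0.5       # µM
    k_ce2: float = 5.0        # 1/h, cyclin E translation
    # multi-coupling strength (None = single-channel rates apply)
    mu: float | None = None

    def __post_init__(self) -> None:
        for m in self.modes:
            if m not in MODES:
                raise ValueError(f"unknown coupling mode {m!r}")
        if self.mu is not None:
            for name in ("v_sw", "v_smp21", "v_sce"):
                if getattr(self, name) != 1.0:
                    raise ValueError(
                        "mu-mode requires v_sw = v_smp21 = v_sce = 1 µM/h "
                        f"(got {name} = {getattr(self, name)})"
                    )

    @property
    def mu_factor(self) -> float:
        return 1.0 if self.mu is None else self.mu


def wee1_mrna_rhs(Mw: float, Bn: float, p: CouplingParams) -> float:
    """dMw/dt: Bn-activated synthesis minus Michaelian degradation."""
    hill = Bn ** p.n_aw / (p.K_aw ** p.n_aw + Bn ** p.n_aw) if Bn > 0 else 0.0
    return p.mu_factor * p.v_sw * hill - p.V_dmw * Mw / (p.K_dmw + Mw)


def wee1_protein_synthesis(Mw: float, p: CouplingParams,
                           v_swee1: float = 0.0) -> float:
    """Wee1 protein supply: basal rate plus the clock-driven mRNA term."""
    return v_swee1 + p.k_sw * Mw


def p21_coupling_rhs(Mp21: float, Rn: float, p: CouplingParams) -> tuple[float, float]:
    """(dMp21/dt, p21 protein synthesis contribution v_s1p21 * Mp21)."""
    rep = p.K_ip21 ** p.nmp21 / (p.K_ip21 ** p.nmp21 + max(Rn, 0.0) ** p.nmp21)
    dm = p.mu_factor * p.v_smp21 * rep - p.V_dmp21 * Mp21 / (p.K_dmp21 + Mp21)
    return dm, p.v_s1p21 * Mp21


def cyclinE_coupling_rhs(Mce: float, Bn: float, p: CouplingParams) -> tuple[float, float]:
    """(dMce/dt, cyclin E synthesis contribution k_ce2 * Mce)."""
    rep = p.K_ice ** p.nce / (p.K_ice ** p.nce + max(Bn, 0.0) ** p.nce)
    dm = p.mu_factor * p.v_sce * rep - p.V_dmce * Mce / (p.K_dmce + Mce)
    return dm, p.k_ce2 * Mce


def assemble_coupled_system(cdk_params: CdkParams = CdkParams(),
                            clock_params: ClockParams = ClockParams(),
                            coupling: CouplingParams = CouplingParams(),
                            ld: LDSchedule | None = LDSchedule(),
                            gf_schedule: GFSquareWave | None = None) -> ModelSpec:
    """Concatenate clock + Cdk network + active coupling mRNA species.

    The state vector is (clock 5, Cdk network 13, one mRNA per active
    mode); coupling is unidirectional (no cell-cycle feedback on the
    clock). mRNA equations are not scaled by the Cdk time-scale ``s``
    because they are clock-driven.
    """
    mrna_names = tuple(
        {"wee1": "Mw", "p21": "Mp21", "cyclinE": "Mce"}[m]
        for m in MODES if m in coupling.modes
    )
    state_names = CLOCK_STATE_NAMES + CDK_STATE_NAMES + mrna_names
    n_clock, n_cdk = len(CLOCK_STATE_NAMES), len(CDK_STATE_NAMES)

    def split(y):
        return (y[:n_clock], y[n_clock:n_clock + n_cdk], y[n_clock + n_cdk:])

    def rhs(t, y, pmap):
        cp: CouplingParams = pmap["coupling"]
        ck: ClockParams = pmap["clock"]
        cd: CdkParams = pmap["cdk"]
        sched = pmap.get("ld")
        gfs = pmap.get("gf")
        y_clock, y_cdk, y_m = split(y)
        d_clock = clock_rhs(y_clock, ck, t, sched)
        Bn = float(bn_of_per(y_clock[2], ck))
        Rn = float(y_clock[4])

        idx = 0
        d_m = np.zeros(len(y_m))
        inputs = dict(wee1_synthesis=0.0, p21_synthesis=0.0, cyclinE_synthesis=0.0)
        if "wee1" in cp.modes:
            Mw = y_m[idx]
            d_m[idx] = wee1_mrna_rhs(Mw, Bn, cp)
            inputs["wee1_synthesis"] = cp.k_sw * Mw
            idx += 1
        if "p21" in cp.modes:
            Mp21 = y_m[idx]
            d_m[idx], contrib = p21_coupling_rhs(Mp21, Rn, cp)
            inputs["p21_synthesis"] = contrib
            idx += 1
        if "cyclinE" in cp.modes:
            Mce = y_m[idx]
            d_m[idx], contrib = cyclinE_coupling_rhs(Mce, Bn, cp)
            inputs["cyclinE_synthesis"] = contrib
            idx += 1

        gf = gfs.value(t, cd.GF) if gfs is not None else None
        d_cdk = cdk_rhs(y_cdk, cd, CouplingInputs(**inputs), t, gf=gf)
        return np.concatenate([d_clock, d_cdk, d_m])

    def discont(pmap, t0, t1):
        edges = []
        sched = pmap.get("ld")
        gfs = pmap.get("gf")
        if sched is not None:
            edges.append(sched.switch_times(t0, t1))
        if gfs is not None:
            edges.append(gfs.switch_times(t0, t1))
        return np.concatenate(edges) if edges else np.array([])

    def cdk_obs(fn):
        def obs(t, states, pmap):
            p = pmap["cdk"]
            return np.array([fn(y, p) for y in states[:, n_clock:n_clock + n_cdk]])
        return obs

    observables = {
        "Cdk1": cdk_obs(lambda y, p: _activities(y, p)[3]),
        "Cdk2": cdk_obs(lambda y, p: _activities(y, p)[1] + _activities(y, p)[2]),
        "CycE_Cdk2": cdk_obs(lambda y, p: _activities(y, p)[1]),
        "CycA_Cdk2": cdk_obs(lambda y, p: _activities(y, p)[2]),
        "CycD_Cdk46": cdk_obs(lambda y, p: _activities(y, p)[0]),
        "BMAL1": lambda t, s, pmap: bn_of_per(s[:, 2], pmap["clock"]),
        "REVERB": lambda t, s, pmap: s[:, 4],
        "PER": lambda t, s, pmap: s[:, 1] + s[:, 2],
    }
    for name in mrna_names:
        j = state_names.index(name)
        key = {"Mw": "Wee1_mRNA", "Mp21": "p21_mRNA", "Mce": "cycE_mRNA"}[name]
        observables[key] = (lambda jj: lambda t, s, pmap: s[:, jj])(j)

    return ModelSpec(
        state_names=state_names,
        rhs=rhs,
        observables=observables,
        default_params={"clock": clock_params, "cdk": cdk_params,
                        "coupling": coupling, "ld": ld, "gf": gf_schedule},
        discontinuities=discont,
        nonnegative=True,
    )


def coupled_init(coupling: CouplingParams = CouplingParams()) -> np.ndarray:
    """Default initial state for the assembled system (mRNAs start at 0)."""
    n_m = sum(m in coupling.modes for m in MODES)
    return np.concatenate([CLOCK_INIT, CDK_INIT, np.zeros(n_m)])
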