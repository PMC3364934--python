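"""Reduced mammalian circadian oscillator entrained by a light-dark cycle.

The clock is a PER negative-feedback loop (Per mRNA, cytosolic and nuclear
PER protein) with nuclear CLOCK-BMAL1 (Bn) computed algebraically as a pool
repressed by nuclear PER, and REV-ERBα (Rn) induced downstream of Bn
through its mRNA, so the Rn peak lags the Bn peak. Light acts as a square
wave raising the Per transcription rate during the L phase.

Phase convention: t = 0 starts an L phase; all phase reports are t mod 24.
Clock concentrations are in nM, times in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ModelSpec

__all__ = ["ClockParams", "LDSchedule", "ld_drive", "clock_rhs", "bn_of_per",
           "clock_model", "CLOCK_STATE_NAMES"]

CLOCK_STATE_NAMES = ("Per_mRNA", "PER_c", "PER_n", "Rev_mRNA", "Rn")


@dataclass(frozen=True)
class ClockParams:
    """Kinetic constants of the reduced clock (all concentrations nM).

    The default set is calibrated so that the free-running period lies in
    [22, 26] h, the clock locks to 24 h under a 16:8 LD cycle, PER peaks at
    the end of the L phase, Bn peaks during the D phase and Rn lags Bn.
    """

    # Per loop
    v_sP_basal: float = 0.58       # nM/h, basal Per transcription
    v_sP_light_increment: float = 0.3  # nM/h, LD increment (L phase)
    K_IP: float = 1.0              # nM, PER self-repression threshold
    n_P: int = 4                   # Hill exponent of the repression
    v_mP: float = 0.5814           # nM/h, max Per mRNA degradation
    K_mP: float = 0.5              # nM
    k_sP: float = 0.54             # 1/h, PER translation
    v_dP: float = 1.0944           # nM/h, max cytosolic PER degradation
    K_dP: float = 0.13             # nM
    k_in: float = 0.342            # 1/h, nuclear import
    k_out: float = 0.1368          # 1/h, nuclear export
    v_dn: float = 0.66             # nM/h, max nuclear PER degradation
    K_dn: float = 0.1              # nM
    # CLOCK-BMAL1 pool (algebraic)
    B_tot: float = 5.6             # nM
    K_BP: float = 0.3              # nM, Bn repression by nuclear PER
    # REV-ERBa branch
    v_sr: float = 1.368            # nM/h, max Rev mRNA synthesis
    K_ar: float = 3.8              # nM, Bn activation threshold
    n_r: int = 4
    v_mr: float = 0.8208           # nM/h, max Rev mRNA degradation
    K_mr: float = 0.4              # nM
    k_sr: float = 0.8208           # 1/h, REV-ERBa translation
    k_dr: float = 0.54             # 1/h, REV-ERBa degradation
    # carried for interface parity with the source clock parameterization
    K_ib: float = 1.0              # nM
    # Cry-deletion emulation: clamp Bn to a constant elevated value
    bn_clamp: float | None = None


@dataclass(frozen=True)
class LDSchedule:
    """Square-wave light-dark schedule; L starts at ``phase_origin``."""

    L_duration: float = 16.0
    D_duration: float = 8.0
    phase_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.L_duration <= 0 or self.D_duration <= 0:
            raise ValueError("phase durations must be > 0")

    @property
    def period(self) -> float:
        return self.L_duration + self.D_duration

    def is_light(self, t) -> np.ndarray:
        phase = np.mod(np.asarray(t) - self.phase_origin, self.period)
        return phase < self.L_duration

    def switch_times(self, t0: float, t1: float) -> np.ndarray:
        """All L/D transition times in (t0, t1)."""
        edges = []
        k0 = int(np.floor((t0 - self.phase_origin) / self.period)) - 1
        k1 = int(np.ceil((t1 - self.phase_origin) / self.period)) + 1
        for k in range(k0, k1 + 1):
            edges.append(self.phase_origin + k * self.period)
            edges.append(self.phase_origin + k * self.period + self.L_duration)
        edges = np.asarray(edges)
        return edges[(edges > t0) & (edges < t1)]


def ld_drive(t, schedule: LDSchedule | None, params: ClockParams) -> float:
    """Per-synthesis rate: basal plus the light increment during L."""
    if schedule is None:
        return params.v_sP_basal
    return params.v_sP_basal + params.v_sP_light_increment * schedule.is_light(t)


def bn_of_per(per_n, params: ClockParams):
    """Nuclear CLOCK-BMAL1 activity repressed by nuclear PER (algebraic)."""
    if params.bn_clamp is not None:
        return np.full_like(np.asarray(per_n, float), params.bn_clamp)
    return params.B_tot * params.K_BP / (params.K_BP + per_n)


def clock_rhs(state, params: ClockParams, t, schedule: LDSchedule | None = None):
    """Derivatives of (Per mRNA, cytosolic PER, nuclear PER, Rev mRNA, Rn)."""
    Mp, Pc, Pn, Mr, Rn = state
    if min(Mp, Pc, Pn, Mr, Rn) < -1e-6:
        raise ValueError(f"negative clock state at t={t}: {state}")
    p = params
    vs = ld_drive(t, schedule, p)
    hillI = p.K_IP ** p.n_P / (p.K_IP ** p.n_P + max(Pn, 0.0) ** p.n_P)
    Bn = float(bn_of_per(Pn, p))
    dMp = vs * hillI - p.v_mP * Mp / (p.K_mP + Mp)
    dPc = p.k_sP * Mp - p.v_dP * Pc / (p.K_dP + Pc) - p.k_in * Pc + p.k_out * Pn
    dPn = p.k_in * Pc - p.k_out * Pn - p.v_dn * Pn / (p.K_dn + Pn)
    dMr = p.v_sr * Bn ** p.n_r / (p.K_ar ** p.n_r + Bn ** p.n_r) \
        - p.v_mr * Mr / (p.K_mr + Mr)
    dRn = p.k_sr * Mr - p.k_dr * Rn
    return np.array([dMp, dPc, dPn, dMr, dRn])


def clock_model(params: ClockParams = ClockParams(),
                schedule: LDSchedule | None = None) -> ModelSpec:
    """Bundle the clock as a :class:`ModelSpec` (states nM, time h)."""

    def rhs(t, y, p):
        return clock_rhs(y, p["clock"], t, p.get("ld"))

    def obs_bn(t, states, p):
        return bn_of_per(states[:, 2], p["clock"])

    observables = {
        "BMAL1": obs_bn,
        "REVERB": lambda t, s, p: s[:, 4],
        "PER": lambda t, s, p: s[:, 1] + s[:, 2],
        "PER_nuclear": lambda t, s, p: s[:, 2],
    }

    def discont(p, t0, t1):
        sched = p.get("ld")
        return sched.switch_times(t0, t1) if sched is not None else np.array([])

    return ModelSpec(
        state_names=CLOCK_STATE_NAMES,
        rhs=rhs,
        observables=observables,
        default_params={"clock": params, "ld": schedule},
        discontinuities=discont,
        nonnegative=True,
    )


CLOCK_INIT = np.array([1.0, 0.5, 0.6, 0.2, 0.2])
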