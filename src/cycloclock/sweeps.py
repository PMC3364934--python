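"""Orchestration of the computational experiments.

Period calibration via the exact uniform-scaling law, Arnold-tongue scans
over (autonomous period x coupling strength), a birhythmicity probe with
state carry-over, and named scenario presets reproducing the figure-level
protocols (coupling switched on at a given event time, parameter steps,
GF square waves, Cry-deletion emulation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .analysis import ClassifierConfig, DynamicsClass, classify_dynamics, \
    detect_peaks, estimate_period, large_peaks, twin_divergence
from .cdk import CDK_INIT, CdkParams, GFSquareWave, autonomous_period, cdk_model
from .clock import ClockParams, LDSchedule
from .core import SimulationConfig, Trajectory, integrate
from .coupling import CouplingParams, assemble_coupled_system, coupled_init

__all__ = ["calibrate_timescale", "reference_period", "TongueMap",
           "arnold_tongue_scan", "hysteresis_probe", "ScenarioResult",
           "scenario_run", "SCENARIOS"]

_TREF_CACHE: dict[str, float] = {}


def _params_key(params: CdkParams) -> str:
    d = {k: v for k, v in asdict(params).items() if k != "s"}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


def reference_period(params: CdkParams = CdkParams()) -> float:
    """Autonomous period at s = 1 (cached; uses the exact scaling law)."""
    key = _params_key(params)
    if key not in _TREF_CACHE:
        T = autonomous_period(replace(params, s=1.0))
        if T is None:
            raise ValueError("default parameter set is quiescent; cannot calibrate")
        _TREF_CACHE[key] = T
    return _TREF_CACHE[key]


def calibrate_timescale(target_period: float, params: CdkParams = CdkParams(),
                        verify: bool = False, tol: float = 0.01) -> float:
    """Time-scale factor s giving the requested autonomous period.

    Exact under uniform scaling: s = T_ref / target. With ``verify`` a
    confirmation integration is run and a mismatch beyond ``tol`` raises
    (which would indicate a non-uniform scaling bug).
    """
    if target_period <= 0:
        raise ValueError("target_period must be > 0")
    s = reference_period(params) / target_period
    if verify:
        T = autonomous_period(replace(params, s=s))
        if T is None or abs(T - target_period) > tol * target_period:
            raise RuntimeError(
                f"calibration verification failed: got {T}, wanted {target_period}"
            )
    return s


# ---------------------------------------------------------------------------
# Arnold tongue scan
# ---------------------------------------------------------------------------

COUPLING_AXES = {"wee1": "v_sw", "p21": "v_smp21", "cyclinE": "v_sce", "mu": "mu"}


@dataclass
class TongueMap:
    """DynamicsClass labels over (autonomous period x coupling strength)."""

    period_axis: np.ndarray
    coupling_axis: np.ndarray
    labels: np.ndarray            # (n_period, n_coupling) of str
    mode: str
    provenance: dict = field(default_factory=dict)

    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "mode": self.mode,
                "period_axis": self.period_axis.tolist(),
                "coupling_axis": self.coupling_axis.tolist(),
                "labels": self.labels.tolist(),
                "provenance": self.provenance,
            }, fh, indent=2)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("period_h,coupling,label\n")
            for i, T in enumerate(self.period_axis):
                for j, c in enumerate(self.coupling_axis):
                    fh.write(f"{T},{c},{self.labels[i, j]}\n")

    @classmethod
    def from_json(cls, path) -> "TongueMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(period_axis=np.asarray(d["period_axis"]),
                   coupling_axis=np.asarray(d["coupling_axis"]),
                   labels=np.asarray(d["labels"], dtype=object),
                   mode=d["mode"], provenance=d.get("provenance", {}))


def _coupling_for(mode: str, strength: float,
                  base: CouplingParams | None = None) -> CouplingParams:
    base = base or CouplingParams()
    if mode == "mu":
        return replace(base, modes=("wee1", "p21", "cyclinE"),
                       v_sw=1.0, v_smp21=1.0, v_sce=1.0, mu=strength)
    if mode not in COUPLING_AXES:
        raise ValueError(f"unknown coupling mode {mode!r}")
    return replace(base, modes=(mode,), mu=None,
                   **{COUPLING_AXES[mode]: strength})


def _coupled_cdk(cdk: CdkParams, coupling: CouplingParams,
                 basal_wee1: float | None = None) -> CdkParams:
    """Apply replacement semantics for the Wee1 channel.

    The clock-controlled Wee1 mRNA equation replaces the constitutive Wee1
    synthesis of the uncoupled network, so by default the basal rate is set
    to 0 whenever the wee1 channel is active (it is retained when only p21
    or cyclin E couple). Pass ``basal_wee1`` to override (e.g. 0.06 to keep
    the basal rate alongside the clock-driven one).
    """
    if basal_wee1 is not None:
        return replace(cdk, v_swee1=basal_wee1)
    if "wee1" in coupling.modes:
        return replace(cdk, v_swee1=0.0)
    return cdk


def classify_cell(target_period: float, mode: str, strength: float,
                  cdk_params: CdkParams = CdkParams(),
                  clock_params: ClockParams = ClockParams(),
                  t_transient: float = 240.0, t_analysis: float = 720.0,
                  cfg: ClassifierConfig | None = None,
                  check_chaos: bool = True,
                  basal_wee1: float | None = None) -> DynamicsClass:
    """Calibrate, couple, integrate and classify one (period, strength) cell."""
    s = calibrate_timescale(target_period, cdk_params)
    cp = _coupling_for(mode, strength)
    cdk = _coupled_cdk(replace(cdk_params, s=s), cp, basal_wee1)
    model = assemble_coupled_system(cdk, clock_params, cp, LDSchedule())
    sim = SimulationConfig(t_end=t_transient + t_analysis,
                           t_transient=t_transient, dt_out=0.1)
    init = coupled_init(cp)
    traj = integrate(model, init, sim)
    ccfg = cfg or ClassifierConfig(t_transient=t_transient)
    probe = None
    if check_chaos:
        probe = lambda: twin_divergence(model, init, sim)
    return classify_dynamics(traj, ccfg, divergence_probe=probe)


def arnold_tongue_scan(period_grid: Sequence[float],
                       coupling_grid: Sequence[float], mode: str,
                       cdk_params: CdkParams = CdkParams(),
                       clock_params: ClockParams = ClockParams(),
                       t_transient: float = 240.0, t_analysis: float = 720.0,
                       check_chaos: bool = False,
                       basal_wee1: float | None = None,
                       progress: bool = False) -> TongueMap:
    """Classify every cell of the grid; failures yield 'undecided'."""
    period_grid = np.asarray(list(period_grid), dtype=float)
    coupling_grid = np.asarray(list(coupling_grid), dtype=float)
    labels = np.empty((period_grid.size, coupling_grid.size), dtype=object)
    for i, T in enumerate(period_grid):
        for j, c in enumerate(coupling_grid):
            try:
                labels[i, j] = classify_cell(
                    T, mode, c, cdk_params, clock_params,
                    t_transient, t_analysis, check_chaos=check_chaos,
                    basal_wee1=basal_wee1).label
            except Exception:
                labels[i, j] = "undecided"
            if progress:
                print(f"period={T:g} coupling={c:g} -> {labels[i, j]}", flush=True)
    prov = {"mode": mode, "t_transient": t_transient, "t_analysis": t_analysis,
            "cdk": _params_key(cdk_params)}
    return TongueMap(period_axis=period_grid, coupling_axis=coupling_grid,
                     labels=labels, mode=mode, provenance=prov)


def hysteresis_probe(period: float, coupling_values: Sequence[float],
                     mode: str = "p21",
                     cdk_params: CdkParams = CdkParams(),
                     clock_params: ClockParams = ClockParams(),
                     t_transient: float = 240.0, t_analysis: float = 480.0) -> dict:
    """Sweep coupling up then down with state carry-over; report coexistence.

    Returns a dict with per-direction label lists and the coupling values
    where the two directions disagree (candidate birhythmicity windows).
    """
    values = np.asarray(list(coupling_values), dtype=float)
    s = calibrate_timescale(period, cdk_params)
    cdk = replace(cdk_params, s=s)

    def sweep(vals):
        out = []
        state = None
        for v in vals:
            cp = _coupling_for(mode, v)
            model = assemble_coupled_system(_coupled_cdk(cdk, cp), clock_params,
                                            cp, LDSchedule())
            init = coupled_init(cp) if state is None else state
            sim = SimulationConfig(t_end=t_transient + t_analysis,
                                   t_transient=t_transient, dt_out=0.1)
            traj = integrate(model, init, sim)
            state = traj.states[-1]
            out.append(classify_dynamics(
                traj, ClassifierConfig(t_transient=t_transient)).label)
        return out

    up = sweep(values)
    down = sweep(values[::-1])[::-1]
    disagree = [float(v) for v, a, b in zip(values, up, down) if a != b]
    return {"coupling_values": values.tolist(), "up": up, "down": down,
            "coexistence_candidates": disagree}


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    name: str
    trajectory: Trajectory
    dynamics: DynamicsClass
    report: dict


def _wee1_preset(autonomous, v_sw, t_on=120.0, t_end=960.0, t_transient=None,
                 cdk_overrides=None, clock_overrides=None, k_aatr_step=None):
    # the time scale is calibrated on the unperturbed reference cell; the
    # overrides (raised pRB synthesis etc.) are the experiment itself
    s = calibrate_timescale(autonomous, CdkParams())
    cdk = replace(CdkParams(), s=s, **(cdk_overrides or {}))
    clock = replace(ClockParams(), **(clock_overrides or {}))
    cp0 = CouplingParams(modes=("wee1",), v_sw=0.0)
    model = assemble_coupled_system(cdk, clock, cp0, LDSchedule())
    events = [t_on]
    # clock-driven Wee1 transcription replaces the constitutive synthesis
    cdk_on = replace(cdk, v_swee1=0.0)
    schedule = [(t_on, {"coupling": replace(cp0, v_sw=v_sw), "cdk": cdk_on})]
    if k_aatr_step is not None:
        t_chk, k = k_aatr_step
        events.append(t_chk)
        schedule.append((t_chk, {"cdk": replace(cdk_on, k_aatr=k)}))
    sim = SimulationConfig(t_end=t_end, t_transient=t_transient or (t_on + 120),
                           dt_out=0.1, event_times=tuple(events))
    traj = integrate(model, coupled_init(cp0), sim, schedule=schedule)
    return traj, sim


def scenario_fig2(autonomous=20.0, v_sw=0.1, t_end=960.0):
    """Wee1 coupling switched on at t = 120 h at full printed strength."""
    return _wee1_preset(autonomous, v_sw, t_end=t_end, t_transient=360)


def scenario_fig5(variant="A", t_end=1200.0):
    table = {"A": (16.0, 0.02), "B": (38.0, 0.02), "C": (16.0, 0.0012)}
    autonomous, v_sw = table[variant]
    return _wee1_preset(autonomous, v_sw, t_end=t_end, t_transient=360)


def scenario_fig6(variant="A", t_end=1200.0):
    table = {"A": (4.0, 0.05), "B": (30.0, 0.05), "C": (16.0, 0.01),
             "D": (16.0, 0.3)}
    autonomous, v_sw = table[variant]
    return _wee1_preset(autonomous, v_sw, t_end=t_end, t_transient=360)


def scenario_fig7(variant="A", t_end=1200.0):
    table = {"A": (4.0, 0.025), "B": (4.0, 0.005)}
    autonomous, v_sw = table[variant]
    return _wee1_preset(autonomous, v_sw, t_end=t_end, t_transient=360)


def scenario_fig8b(autonomous=34.0, v_before=0.46, v_after=0.49,
                   t_switch=240.0, t_end=1200.0):
    cdk = replace(CdkParams(), s=calibrate_timescale(autonomous))
    cp0 = CouplingParams(modes=("p21",), v_smp21=v_before)
    model = assemble_coupled_system(cdk, ClockParams(), cp0, LDSchedule())
    sim = SimulationConfig(t_end=t_end, t_transient=t_switch + 240, dt_out=0.1,
                           event_times=(t_switch,))
    schedule = [(t_switch, {"coupling": replace(cp0, v_smp21=v_after)})]
    return integrate(model, coupled_init(cp0), sim, schedule=schedule), sim


def scenario_fig10(autonomous=18.0, mu=0.01, t_switch=240.0, t_end=1200.0):
    cdk = replace(CdkParams(), s=calibrate_timescale(autonomous))
    cp0 = _coupling_for("mu", 0.0)
    model = assemble_coupled_system(cdk, ClockParams(), cp0, LDSchedule())
    sim = SimulationConfig(t_end=t_end, t_transient=t_switch + 240, dt_out=0.1,
                           event_times=(t_switch,))
    schedule = [(t_switch, {"coupling": replace(cp0, mu=mu),
                            "cdk": replace(cdk, v_swee1=0.0)})]
    return integrate(model, coupled_init(cp0), sim, schedule=schedule), sim


def scenario_fig11(strength="weak", autonomous=28.0, t_end=1200.0):
    k = {"weak": 0.025, "strong": 0.075}[strength]
    return _wee1_preset(autonomous, 0.1, t_on=120.0, t_end=t_end,
                        t_transient=480, k_aatr_step=(240.0, k))


def scenario_fig12(variant="A", t_end=960.0):
    table = {"A": dict(v_spRB=1.0), "B": dict(v_spRB=2.0),
             "C": dict(v_spbi=0.3)}
    return _wee1_preset(20.0, 0.1, t_on=120.0, t_end=t_end, t_transient=360,
                        cdk_overrides=table[variant])


def scenario_fig13(variant="A", autonomous=16.0, t_end=960.0,
                   wave_end=np.inf):
    """GF square wave (0/1 µM alternating every 12 h), no clock coupling."""
    base_gf = 1.0 if variant == "A" else 0.0
    cdk = replace(CdkParams(), s=calibrate_timescale(autonomous), GF=base_gf)
    # a proliferating cell first sees GF withdrawn; a quiescent cell first
    # sees GF delivered
    gfs = GFSquareWave(t_start=120.0, t_end=wave_end,
                       start_high=(variant == "B"))
    model = cdk_model(cdk, gf_schedule=gfs)
    sim = SimulationConfig(t_end=t_end, t_transient=360, dt_out=0.1)
    return integrate(model, CDK_INIT, sim), sim


def scenario_fig14(autonomous=21.6, mu=0.028, gf_after=0.3,
                   t_switch=240.0, t_end=1440.0):
    cdk = replace(CdkParams(), s=calibrate_timescale(autonomous), v_swee1=0.0)
    cp = _coupling_for("mu", mu)
    cp = replace(cp, modes=("wee1", "cyclinE"))
    model = assemble_coupled_system(cdk, ClockParams(), cp, LDSchedule())
    sim = SimulationConfig(t_end=t_end, t_transient=t_switch + 240, dt_out=0.1,
                           event_times=(t_switch,))
    schedule = [(t_switch, {"cdk": replace(cdk, GF=gf_after)})]
    return integrate(model, coupled_init(cp), sim, schedule=schedule), sim


def scenario_fig15(autonomous=18.0, v_sw=0.05, t_del=120.0, t_end=960.0,
                   bn_high=5.5):
    """Cry-deletion emulation: Bn clamped to a constant elevated value."""
    cdk = replace(CdkParams(), s=calibrate_timescale(autonomous), v_swee1=0.0)
    clock = ClockParams()
    cp = CouplingParams(modes=("wee1",), v_sw=v_sw)
    model = assemble_coupled_system(cdk, clock, cp, LDSchedule())
    sim = SimulationConfig(t_end=t_end, t_transient=360, dt_out=0.1,
                           event_times=(t_del,))
    schedule = [(t_del, {"clock": replace(clock, bn_clamp=bn_high)})]
    return integrate(model, coupled_init(cp), sim, schedule=schedule), sim


SCENARIOS = {
    "fig2": scenario_fig2, "fig5": scenario_fig5, "fig6": scenario_fig6,
    "fig7": scenario_fig7, "fig8b": scenario_fig8b, "fig10": scenario_fig10,
    "fig11": scenario_fig11, "fig12": scenario_fig12, "fig13": scenario_fig13,
    "fig14": scenario_fig14, "fig15": scenario_fig15,
}


def scenario_run(name: str, **overrides) -> ScenarioResult:
    """Execute a named preset and classify the post-event dynamics."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(SCENARIOS)}")
    traj, sim = SCENARIOS[name](**overrides)
    cfg = ClassifierConfig(t_transient=sim.t_transient)
    dyn = classify_dynamics(traj, cfg)
    report = {
        "scenario": name,
        "overrides": {k: repr(v) for k, v in overrides.items()},
        "label": dyn.label,
        "locked_period": dyn.locked_period,
        "interval_cv": dyn.interval_cv,
        "cdk2_per_cdk1": dyn.cdk2_per_cdk1,
        "t_transient": sim.t_transient,
        "t_end": sim.t_end,
    }
    return ScenarioResult(name=name, trajectory=traj, dynamics=dyn,
                          report=report)
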