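"""Generic ODE system abstraction and the shared integration engine.

All models in this package (clock, Cdk network, coupled assemblies) are
expressed as :class:`ModelSpec` objects and integrated with :func:`integrate`,
which handles piecewise parameter schedules (step changes at event times with
continuous state), forcing discontinuities, uniform output sampling and
non-negativity clipping.

Units: time in hours, concentrations in µM (cell-cycle species) or nM
(clock species); see the model modules for the units bridge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelSpec",
    "SimulationConfig",
    "Trajectory",
    "AttractorResult",
    "IntegrationError",
    "integrate",
    "find_attractor",
]


class IntegrationError(RuntimeError):
    """Solver failure (step-size underflow, NaN/Inf in the rhs, ...)."""


@dataclass(frozen=True)
class ModelSpec:
    """An autonomous-or-forced ODE system with named states and observables.

    Parameters
    ----------
    state_names
        Ordered, unique identifiers for the state vector components.
    rhs
        ``rhs(t, y, params) -> dy/dt`` returning a vector of
        ``len(state_names)`` derivatives.
    observables
        Named read-only functions ``f(t, states, params)`` of the
        trajectory; ``t`` is a vector and ``states`` the (time x state)
        matrix. Must not mutate their inputs.
    default_params
        Baseline parameter mapping used when the caller supplies none.
    discontinuities
        Optional ``f(params, t0, t1) -> array`` returning times in
        ``(t0, t1)`` where the forcing is discontinuous (LD or GF square
        wave switches); integration restarts at each of them.
    """

    state_names: tuple[str, ...]
    rhs: Callable[[float, np.ndarray, Mapping], np.ndarray]
    observables: Mapping[str, Callable] = field(default_factory=dict)
    default_params: Mapping = field(default_factory=dict)
    discontinuities: Callable[[Mapping, float, float], np.ndarray] | None = None
    nonnegative: bool = False  # states are concentrations; clip tiny negatives

    def __post_init__(self) -> None:
        if len(set(self.state_names)) != len(self.state_names):
            raise ValueError("state_names must be unique")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, name: str) -> int:
        return self.state_names.index(name)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings shared by every run.

    ``event_times`` lists the times at which the parameter schedule may
    switch (e.g. coupling turned on at t = 120 h).
    """

    t_end: float
    t_transient: float = 0.0
    dt_out: float = 0.1
    rel_tol: float = 1e-7
    abs_tol: float = 1e-9
    event_times: tuple[float, ...] = ()
    method: str = "LSODA"
    max_step: float = np.inf

    def __post_init__(self) -> None:
        if not (0 <= self.t_transient < self.t_end):
            raise ValueError("require 0 <= t_transient < t_end")
        if self.dt_out <= 0:
            raise ValueError("dt_out must be > 0")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("solver tolerances must be > 0")


@dataclass
class Trajectory:
    """Uniformly sampled result of one integration.

    ``states`` is (time x state); ``observable_series`` holds the named
    observable vectors evaluated on the same grid. ``params_used`` records
    the frozen parameter snapshot of each schedule segment as
    ``(t_start, params_dict)`` pairs. ``min_state`` is the per-species
    minimum *before* non-negativity clipping (diagnostic).
    """

    times: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...]
    observable_series: dict[str, np.ndarray]
    params_used: list[tuple[float, dict]]
    min_state: np.ndarray | None = None

    def series(self, name: str) -> np.ndarray:
        """State column or observable series by name."""
        if name in self.observable_series:
            return self.observable_series[name]
        if name in self.state_names:
            return self.states[:, self.state_names.index(name)]
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return list(self.state_names) + list(self.observable_series)

    def after(self, t0: float) -> "Trajectory":
        """Sub-trajectory with times >= t0 (transient discard)."""
        mask = self.times >= t0 - 1e-12
        return Trajectory(
            times=self.times[mask],
            states=self.states[mask],
            state_names=self.state_names,
            observable_series={k: v[mask] for k, v in self.observable_series.items()},
            params_used=self.params_used,
            min_state=self.min_state,
        )

    # -- export ------------------------------------------------------------
    def to_csv(self, path) -> None:
        header = "time_h," + ",".join(self.names)
        cols = [self.times[:, None], self.states]
        cols += [self.observable_series[k][:, None] for k in self.observable_series]
        np.savetxt(path, np.hstack(cols), delimiter=",", header=header, comments="")

    def params_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [{"t_start": t, "params": {k: _jsonable(v) for k, v in p.items()}}
                 for t, p in self.params_used],
                fh, indent=2,
            )

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c != "time_h")
        return cls(
            times=df["time_h"].to_numpy(),
            states=df[list(names)].to_numpy(),
            state_names=names,
            observable_series={},
            params_used=[],
        )


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Mapping):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, (int, float, str, bool)) or v is None:
        return v
    return repr(v)


def _wrap_rhs(model: ModelSpec, params: Mapping):
    def f(t, y):
        dy = np.asarray(model.rhs(t, y, params), dtype=float)
        if not np.all(np.isfinite(dy)):
            bad = int(np.flatnonzero(~np.isfinite(dy))[0])
            raise IntegrationError(
                f"non-finite derivative for state '{model.state_names[bad]}' at t={t:.4g}"
            )
        return dy

    return f


def integrate(
    model: ModelSpec,
    init: Sequence[float],
    config: SimulationConfig,
    schedule: Sequence[tuple[float, Mapping]] | None = None,
) -> Trajectory:
    """Integrate ``model`` from ``init`` under a piecewise parameter schedule.

    ``schedule`` is a sequence of ``(time, overrides)`` pairs; at each time
    (which must appear in ``config.event_times``) the listed parameters are
    step-changed while the state is carried continuously. Forcing
    discontinuities declared by the model are used as additional restart
    points so the stiff solver never steps across a square-wave edge.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (model.n_states,):
        raise ValueError(
            f"init has length {init.size}, model has {model.n_states} states"
        )
    schedule = sorted(schedule or [], key=lambda e: e[0])
    for t_ev, _ in schedule:
        if not any(abs(t_ev - e) < 1e-9 for e in config.event_times):
            raise ValueError(f"schedule time {t_ev} not declared in event_times")

    t_grid = np.arange(0.0, config.t_end + 0.5 * config.dt_out, config.dt_out)
    t_grid = np.minimum(t_grid[t_grid <= config.t_end + 1e-9], config.t_end)
    params = dict(model.default_params)

    # segment boundaries: schedule events only (forcing breaks handled inside)
    bounds = [0.0] + [t for t, _ in schedule if 0.0 < t < config.t_end] + [config.t_end]
    bounds = sorted(set(bounds))

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    params_used: list[tuple[float, dict]] = []
    y = init.copy()
    min_state = init.copy()

    for seg, (t0, t1) in enumerate(zip(bounds[:-1], bounds[1:])):
        for t_ev, overrides in schedule:
            if abs(t_ev - t0) < 1e-9:
                params.update(overrides)
        params_used.append((t0, dict(params)))

        # sub-split at forcing discontinuities
        sub = [t0, t1]
        if model.discontinuities is not None:
            br = np.asarray(model.discontinuities(params, t0, t1), dtype=float)
            sub = sorted(set([t0, t1]) | set(br[(br > t0 + 1e-9) & (br < t1 - 1e-9)]))
        f = _wrap_rhs(model, params)
        for a, b in zip(sub[:-1], sub[1:]):
            mask = (t_grid > a + 1e-9) & (t_grid <= b + 1e-9)
            t_eval = t_grid[mask]
            sol = solve_ivp(
                f, (a, b), y, method=config.method,
                t_eval=t_eval if t_eval.size else None,
                rtol=config.rel_tol, atol=config.abs_tol,
                max_step=config.max_step, dense_output=False,
            )
            if not sol.success:
                raise IntegrationError(
                    f"solver failed in segment {seg} [{a:.4g}, {b:.4g}] h: {sol.message}"
                )
            if t_eval.size:
                times_out.append(t_eval)
                states_out.append(sol.y.T)
                min_state = np.minimum(min_state, sol.y.min(axis=1))
            y = sol.y[:, -1].copy() if sol.y.size else y
            if model.nonnegative:
                # continuous state across the break, clipped tiny negatives
                y[y < 0] = np.where(y[y < 0] > -config.abs_tol, 0.0, y[y < 0])

    times = np.concatenate([[0.0]] + times_out) if times_out else np.array([0.0])
    states = np.vstack([init[None, :]] + states_out) if states_out else init[None, :]
    states = states.copy()
    if model.nonnegative:
        states[states < 0] = 0.0  # clip below -abs_tol to 0 per contract

    obs = {
        name: np.asarray(fn(times, states, params), dtype=float)
        for name, fn in model.observables.items()
    }
    return Trajectory(
        times=times, states=states, state_names=model.state_names,
        observable_series=obs, params_used=params_used, min_state=min_state,
    )


@dataclass
class AttractorResult:
    """Outcome of :func:`find_attractor`.

    ``kind`` is one of ``steady_state`` / ``limit_cycle`` / ``undecided``.
    """

    kind: str
    steady_state: np.ndarray | None = None
    period: float | None = None
    cycle: Trajectory | None = None
    trajectory: Trajectory | None = None


def find_attractor(
    model: ModelSpec,
    init: Sequence[float],
    config: SimulationConfig,
    reference_observable: str | None = None,
    flatness_tol: float = 1e-4,
    window: float = 48.0,
) -> AttractorResult:
    """Decide between a stable steady state and a limit cycle.

    Steady state: the terminal rhs is below ``abs_tol`` (scaled) and every
    observable is flat (peak-to-trough < ``flatness_tol`` x max(1, level))
    over the terminal ``window``. Otherwise a period is estimated from the
    reference observable's peaks; failing both yields ``undecided``.
    """
    from .analysis import detect_peaks, estimate_period

    traj = integrate(model, init, config)
    tail = traj.after(max(config.t_end - window, config.t_transient))
    y_end = traj.states[-1]
    rhs_end = np.asarray(model.rhs(traj.times[-1], y_end, dict(model.default_params)))

    flat = True
    for name in traj.names:
        s = tail.series(name)
        if s.size and np.ptp(s) > flatness_tol * max(1.0, np.abs(s).max()):
            flat = False
            break
    if flat and np.max(np.abs(rhs_end)) < max(config.abs_tol, 1e-8) * max(1.0, np.abs(y_end).max()):
        return AttractorResult(kind="steady_state", steady_state=y_end, trajectory=traj)

    ref = reference_observable
    if ref is None:
        ref = next(iter(traj.observable_series), traj.state_names[0])
    analysed = traj.after(config.t_transient)
    try:
        peaks = detect_peaks(analysed.series(ref), analysed.times, min_prominence=0.05)
        period, cv = estimate_period(peaks)
    except Exception:
        return AttractorResult(kind="undecided", trajectory=traj)
    if cv > 0.05 or not np.isfinite(period):
        return AttractorResult(kind="undecided", trajectory=traj)
    t_last = peaks.peak_times[-1]
    cyc = analysed.after(t_last - period)
    cycle = Trajectory(
        times=cyc.times[cyc.times <= t_last + 1e-9],
        states=cyc.states[cyc.times <= t_last + 1e-9],
        state_names=cyc.state_names,
        observable_series={k: v[cyc.times <= t_last + 1e-9] for k, v in cyc.observable_series.items()},
        params_used=traj.params_used,
    )
    return AttractorResult(kind="limit_cycle", period=period, cycle=cycle, trajectory=traj)
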