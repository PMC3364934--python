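"""Trajectory readouts: peaks, periods, amplitude classes, locking labels.

This module turns raw trajectories into the categorical and quantitative
summaries used throughout the package: peak detection, large/minute
amplitude splitting (the bimodality induced by the bistable Cdk1 switch),
period estimation, stroboscopic (Poincaré) sampling at the forcing period,
the dynamics classifier, and peak phase within the light-dark cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import Trajectory

__all__ = [
    "PeakList",
    "AmplitudeClasses",
    "DynamicsClass",
    "ClassifierConfig",
    "detect_peaks",
    "split_amplitude_classes",
    "estimate_period",
    "stroboscopic_map",
    "classify_dynamics",
    "phase_in_ld",
    "twin_divergence",
    "SyntheticSpec",
    "synthetic_trace",
]

LABELS = (
    "entrained_24",
    "entrained_48",
    "complex_periodic",
    "chaotic",
    "unlocked",
    "endoreplication",
    "tetraploid_pattern",
    "quiescent",
    "undecided",
)


@dataclass
class PeakList:
    """Detected local maxima of one observable series."""

    peak_times: np.ndarray
    peak_heights: np.ndarray
    observable_name: str = ""
    settings: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.peak_times.size

    def subset(self, mask: np.ndarray) -> "PeakList":
        return PeakList(self.peak_times[mask], self.peak_heights[mask],
                        self.observable_name, self.settings)


@dataclass
class AmplitudeClasses:
    """Large/minute split of a peak train at the widest log-amplitude gap."""

    labels: np.ndarray            # "large" | "minute" per peak
    bimodal: bool
    separation: float             # ratio of cluster means (>= 1)

    @property
    def n_large(self) -> int:
        return int(np.sum(self.labels == "large"))


@dataclass
class DynamicsClass:
    """Categorical outcome of the classifier plus supporting metrics."""

    label: str
    locked_period: float | None = None
    locking_ratio: str | None = None
    cdk2_per_cdk1: float | None = None
    strobo_points: int | None = None
    interval_cv: float | None = None
    phase_drift: float | None = None
    undecided: bool = False

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def detect_peaks(series: np.ndarray, times: np.ndarray,
                 min_prominence: float = 0.05, name: str = "") -> PeakList:
    """Local maxima whose prominence exceeds ``min_prominence`` x range.

    The prominence threshold is relative to the peak-to-trough range of the
    series, which makes detection invariant to uniform amplitude rescaling.
    """
    series = np.asarray(series, float)
    times = np.asarray(times, float)
    if series.size == 0:
        raise ValueError("empty series")
    if series.size < 3:
        return PeakList(np.array([]), np.array([]), name,
                        {"min_prominence": min_prominence})
    rng = float(np.ptp(series))
    if rng == 0.0:
        return PeakList(np.array([]), np.array([]), name,
                        {"min_prominence": min_prominence})
    idx, _ = find_peaks(series, prominence=min_prominence * rng)
    return PeakList(times[idx], series[idx], name,
                    {"min_prominence": min_prominence})


def split_amplitude_classes(peaks: PeakList, bimodal_factor: float = 5.0) -> AmplitudeClasses:
    """Two-cluster split at the largest gap in log amplitude.

    Flags ``bimodal`` when the two cluster means differ by at least
    ``bimodal_factor``; otherwise every peak is labeled large.
    """
    h = np.asarray(peaks.peak_heights, float)
    if h.size == 0:
        raise ValueError("need at least one peak")
    if h.size == 1:
        return AmplitudeClasses(np.array(["large"]), False, 1.0)
    floor = max(h.max() * 1e-12, 1e-300)
    logs = np.log(np.maximum(h, floor))
    order = np.argsort(logs)
    gaps = np.diff(logs[order])
    cut = int(np.argmax(gaps))
    lower = order[: cut + 1]
    upper = order[cut + 1:]
    if upper.size == 0:  # all heights identical
        return AmplitudeClasses(np.full(h.size, "large"), False, 1.0)
    sep = float(np.mean(h[upper]) / max(np.mean(h[lower]), floor))
    labels = np.full(h.size, "large", dtype=object)
    if sep >= bimodal_factor:
        labels[lower] = "minute"
        return AmplitudeClasses(labels.astype(str), True, sep)
    return AmplitudeClasses(labels.astype(str), False, sep)


def large_peaks(peaks: PeakList, bimodal_factor: float = 5.0) -> PeakList:
    """Peaks labeled large by :func:`split_amplitude_classes` (all if unimodal)."""
    if len(peaks) == 0:
        return peaks
    classes = split_amplitude_classes(peaks, bimodal_factor)
    return peaks.subset(classes.labels == "large")


def estimate_period(peaks: PeakList) -> tuple[float, float]:
    """Mean successive inter-peak interval and its coefficient of variation."""
    if len(peaks) < 3:
        raise ValueError("insufficient peaks (need >= 3)")
    iv = np.diff(peaks.peak_times)
    mean = float(np.mean(iv))
    cv = float(np.std(iv) / mean) if mean > 0 else np.inf
    return mean, cv


def peak_phase_drift(peaks: PeakList) -> float:
    """Slope deviation |fit - mean interval| of peak times vs index, h/cycle."""
    if len(peaks) < 3:
        return np.inf
    k = np.arange(len(peaks))
    slope = np.polyfit(k, peaks.peak_times, 1)[0]
    mean = float(np.mean(np.diff(peaks.peak_times)))
    return abs(slope - mean)


@dataclass
class StroboscopicMap:
    points: np.ndarray          # (n, 2)
    distinct: int
    merge_eps: float


def stroboscopic_map(traj: Trajectory, T_force: float = 24.0,
                     observables: tuple[str, str] = ("Cdk1", "Cdk2"),
                     t_transient: float = 0.0, merge_eps: float = 1e-3,
                     min_cycles: int = 10) -> StroboscopicMap:
    """Sample an observable pair once per forcing period after the transient.

    Distinct points are counted with a greedy merge at relative L2 distance
    ``merge_eps`` (each coordinate normalized by its observed range).
    """
    t0 = max(t_transient, traj.times[0])
    t_samples = np.arange(t0, traj.times[-1] + 1e-9, T_force)
    if t_samples.size < min_cycles:
        raise ValueError(
            f"trajectory too short: {t_samples.size} strobe samples < {min_cycles}"
        )
    cols, scales = [], []
    for name in observables:
        s = traj.series(name)
        cols.append(np.interp(t_samples, traj.times, s))
        # normalize by the full series range so that a phase-locked orbit
        # sampling a single point does not blow up numerical noise
        scales.append(max(np.ptp(s), 1e-12))
    pts = np.column_stack(cols)
    scale = np.asarray(scales)
    norm = pts / scale
    reps: list[np.ndarray] = []
    for p in norm:
        if not any(np.linalg.norm(p - r) < merge_eps for r in reps):
            reps.append(p)
    return StroboscopicMap(points=pts, distinct=len(reps), merge_eps=merge_eps)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the dynamics classifier.

    Entrainment requires the mean large-peak interval within ``period_tol``
    of the forcing period (or twice it), interval CV below ``cv_tol`` and a
    stationary phase (drift below ``phase_drift_tol`` h per cycle).
    """

    t_transient: float = 240.0
    forcing_period: float = 24.0
    min_prominence: float = 0.05
    bimodal_factor: float = 5.0
    period_tol: float = 0.01
    cv_tol: float = 0.02
    phase_drift_tol: float = 0.05
    strobo_cap: int = 32
    merge_eps: float = 1e-3
    cdk1_name: str = "Cdk1"
    cdk2_name: str = "Cdk2"


def _is_periodic_at(peaks: PeakList, T: float, cfg: ClassifierConfig) -> bool:
    if len(peaks) < 3:
        return False
    mean, cv = estimate_period(peaks)
    return (abs(mean - T) <= cfg.period_tol * T and cv < cfg.cv_tol
            and peak_phase_drift(peaks) < cfg.phase_drift_tol)


def classify_dynamics(traj: Trajectory, cfg: ClassifierConfig = ClassifierConfig(),
                      divergence_probe: Callable[[], bool] | None = None) -> DynamicsClass:
    """Decision cascade over the Cdk1/Cdk2 peak structure of a trajectory.

    Order: quiescent, endoreplication, entrained (1:1 then 2:1), tetraploid
    pattern, complex periodic, then chaotic vs unlocked from the
    stroboscopic point count (chaos additionally requires a positive
    ``divergence_probe`` — the twin-trajectory sensitivity test).
    """
    sub = traj.after(cfg.t_transient)
    if sub.times.size < 10:
        return DynamicsClass(label="undecided", undecided=True)
    T = cfg.forcing_period

    pk1 = detect_peaks(sub.series(cfg.cdk1_name), sub.times, cfg.min_prominence, cfg.cdk1_name)
    pk2 = detect_peaks(sub.series(cfg.cdk2_name), sub.times, cfg.min_prominence, cfg.cdk2_name)

    # Large/minute is decided within each train (bimodality split) and
    # against the joint amplitude scale of both observables, so that a
    # train of uniformly minute Cdk1 peaks (endoreplication) is recognized
    # while the classifier stays invariant to uniform rescaling.
    ref = max([p.peak_heights.max() for p in (pk1, pk2) if len(p)], default=0.0)

    def _large(pk: PeakList) -> PeakList:
        lg = large_peaks(pk, cfg.bimodal_factor)
        if len(lg) and ref > 0:
            lg = lg.subset(lg.peak_heights >= ref / cfg.bimodal_factor)
        return lg

    lg1, lg2 = _large(pk1), _large(pk2)

    # Small forced ripples riding on a steady level are not oscillations:
    # flat when the peak-to-trough range is small relative to the mean.
    def effectively_flat(name: str) -> bool:
        s = sub.series(name)
        return np.ptp(s) <= max(0.25 * np.mean(s), 1e-12)

    if (len(lg1) == 0 or effectively_flat(cfg.cdk1_name)) and \
       (len(lg2) == 0 or effectively_flat(cfg.cdk2_name)):
        return DynamicsClass(label="quiescent")

    # endoreplication: circadian large Cdk2 cycles with Cdk1 minute only
    if len(lg1) == 0 and _is_periodic_at(lg2, T, cfg):
        mean2, cv2 = estimate_period(lg2)
        return DynamicsClass(label="endoreplication", locked_period=mean2,
                             interval_cv=cv2, cdk2_per_cdk1=np.inf)

    for mult, label in ((1, "entrained_24"), (2, "entrained_48")):
        if _is_periodic_at(lg1, mult * T, cfg) and _is_periodic_at(lg2, mult * T, cfg):
            mean1, cv1 = estimate_period(lg1)
            return DynamicsClass(label=label, locked_period=mean1,
                                 locking_ratio=f"1:{mult}", interval_cv=cv1,
                                 phase_drift=peak_phase_drift(lg1),
                                 cdk2_per_cdk1=len(lg2) / len(lg1))

    # tetraploid pattern: periodic with two large Cdk2 peaks per Cdk1 peak
    if len(lg1) >= 3 and len(lg2) >= 3:
        mean1, cv1 = estimate_period(lg1)
        ratio = len(lg2) / len(lg1)
        if cv1 < 2 * cfg.cv_tol and 1.7 <= ratio <= 2.3:
            return DynamicsClass(label="tetraploid_pattern", locked_period=mean1,
                                 interval_cv=cv1, cdk2_per_cdk1=ratio)

    # periodic but not matching any pattern above -> complex periodic
    if len(lg1) >= 3:
        mean1, cv1 = estimate_period(lg1)
        if cv1 < cfg.cv_tol and peak_phase_drift(lg1) < cfg.phase_drift_tol:
            return DynamicsClass(label="complex_periodic", locked_period=mean1,
                                 interval_cv=cv1,
                                 cdk2_per_cdk1=len(lg2) / max(len(lg1), 1))

    try:
        strobe = stroboscopic_map(traj, T, (cfg.cdk1_name, cfg.cdk2_name),
                                  cfg.t_transient, cfg.merge_eps)
    except ValueError:
        return DynamicsClass(label="undecided", undecided=True)
    if strobe.distinct <= cfg.strobo_cap:
        return DynamicsClass(label="complex_periodic", strobo_points=strobe.distinct,
                             cdk2_per_cdk1=len(lg2) / max(len(lg1), 1))
    if divergence_probe is not None and divergence_probe():
        return DynamicsClass(label="chaotic", strobo_points=strobe.distinct)
    return DynamicsClass(label="unlocked", strobo_points=strobe.distinct)


@dataclass
class PhaseSummary:
    phases: np.ndarray
    circular_mean: float
    all_in_late_L: bool


def phase_in_ld(peaks: PeakList, schedule) -> PhaseSummary:
    """Map peak times to [0, 24) with L = [0, L_duration).

    ``all_in_late_L`` reports whether every peak falls in the second half of
    the light phase, [L/2, L).
    """
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    period = schedule.L_duration + schedule.D_duration
    phases = np.mod(peaks.peak_times - schedule.phase_origin, period)
    ang = phases / period * 2 * np.pi
    mean_ang = np.angle(np.mean(np.exp(1j * ang)))
    circ = float(np.mod(mean_ang / (2 * np.pi) * period, period))
    lo, hi = schedule.L_duration / 2, schedule.L_duration
    return PhaseSummary(phases=phases, circular_mean=circ,
                        all_in_late_L=bool(np.all((phases >= lo) & (phases < hi))))


def twin_divergence(model, init, config, offset: float = 1e-6,
                    n_cycles: int = 5, T_force: float = 24.0) -> bool:
    """Sensitive-dependence probe: do twin trajectories diverge exponentially?

    Integrates two copies whose initial states differ by a relative
    ``offset`` and tests whether their separation grows by more than two
    orders of magnitude over ``n_cycles`` forcing periods.
    """
    from .core import SimulationConfig, integrate

    init = np.asarray(init, float)
    pert = init * (1 + offset) + offset * (init == 0)
    horizon = config.t_transient + n_cycles * T_force
    cfg = replace(config, t_end=max(config.t_end, horizon))
    t1 = integrate(model, init, cfg)
    t2 = integrate(model, pert, cfg)
    scale = np.maximum(np.abs(t1.states).max(axis=0), 1e-12)
    d = np.linalg.norm((t1.states - t2.states) / scale, axis=1)
    i0 = np.searchsorted(t1.times, config.t_transient)
    d0 = max(d[i0], offset * 1e-3)
    return bool(d[-1] > 100 * d0)


# ---------------------------------------------------------------------------
# synthetic fixtures for the classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a ground-truth-labeled synthetic Cdk1/Cdk2 trace.

    ``amplitude_ratio`` > 1 interleaves a minute-peak train between the
    large Cdk1 peaks at ``large/ratio`` height; ``jitter`` displaces each
    peak by a uniform fraction of the period (non-accumulating, so the
    phase stays stationary); ``cdk2_per_cdk1`` > 1 adds extra Cdk2 peaks
    per cycle; ``cdk1_scale`` shrinks the whole Cdk1 train (endoreplication
    fixtures).
    """

    period: float = 24.0
    n_cycles: int = 40
    amplitude_ratio: float = 1.0
    jitter: float = 0.0
    seed: int = 0
    cdk2_per_cdk1: int = 1
    cdk1_scale: float = 1.0
    peak_width: float = 1.2
    dt: float = 0.1
    lead_in: float = 260.0


@dataclass
class SyntheticTrace:
    trajectory: Trajectory
    truth_label: str
    truth_cdk1_peaks: np.ndarray
    truth_cdk2_peaks: np.ndarray


def _bump_train(t: np.ndarray, centers: np.ndarray, heights: np.ndarray,
                width: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c, h in zip(centers, heights):
        lo = np.searchsorted(t, c - 6 * width)
        hi = np.searchsorted(t, c + 6 * width)
        out[lo:hi] += h * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return out


def synthetic_trace(spec: SyntheticSpec) -> SyntheticTrace:
    """Deterministic labeled fixture for classifier validation.

    Ground truth by construction (forcing period 24 h): period 24 with one
    large peak per cycle -> entrained_24; period 48 -> entrained_48;
    other periodic single-peak patterns -> complex_periodic;
    ``cdk1_scale`` <= 0.01 with circadian Cdk2 -> endoreplication;
    ``cdk2_per_cdk1`` == 2 -> tetraploid_pattern.
    """
    rng = np.random.default_rng(spec.seed)
    t_end = spec.lead_in + spec.n_cycles * spec.period + 2 * spec.period
    t = np.arange(0.0, t_end, spec.dt)
    base = spec.lead_in + spec.period * np.arange(spec.n_cycles)
    jit = rng.uniform(-spec.jitter, spec.jitter, size=base.size) * spec.period
    c1 = base + jit
    h1 = np.full(c1.size, 1.0)
    if spec.amplitude_ratio > 1.0:
        cm = c1[:-1] + spec.period / 2 + rng.uniform(
            -spec.jitter, spec.jitter, size=c1.size - 1) * spec.period
        c1 = np.concatenate([c1, cm])
        h1 = np.concatenate([h1, np.full(cm.size, 1.0 / spec.amplitude_ratio)])
        order = np.argsort(c1)
        c1, h1 = c1[order], h1[order]
    cdk1 = spec.cdk1_scale * _bump_train(t, c1, h1, spec.peak_width)

    c2 = []
    for b in base:
        for k in range(spec.cdk2_per_cdk1):
            c2.append(b - 3.0 - k * spec.period / (2 * spec.cdk2_per_cdk1))
    c2 = np.sort(np.asarray(c2))
    c2 = c2 + rng.uniform(-spec.jitter, spec.jitter, size=c2.size) * spec.period
    cdk2 = _bump_train(t, c2, np.full(c2.size, 1.5), spec.peak_width)

    if spec.cdk1_scale <= 0.01:
        label = "endoreplication" if np.isclose(spec.period, 24.0) else "complex_periodic"
    elif spec.cdk2_per_cdk1 == 2:
        label = "tetraploid_pattern"
    elif np.isclose(spec.period, 24.0):
        label = "entrained_24"
    elif np.isclose(spec.period, 48.0):
        label = "entrained_48"
    else:
        label = "complex_periodic"

    traj = Trajectory(
        times=t, states=np.zeros((t.size, 0)), state_names=(),
        observable_series={"Cdk1": cdk1, "Cdk2": cdk2}, params_used=[],
    )
    large_mask = h1 >= h1.max() * 0.5
    return SyntheticTrace(trajectory=traj, truth_label=label,
                          truth_cdk1_peaks=c1[large_mask], truth_cdk2_peaks=c2)
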