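# cycloclock

Simulation and entrainment analysis of the mammalian cell cycle coupled to
the circadian clock.

The package implements, in reduced form, a coupled pair of cellular
oscillators and the analysis pipeline around them:

* **clock** — a reduced LD-entrained circadian oscillator (PER negative
  feedback; nuclear CLOCK-BMAL1 as an algebraic pool repressed by PER;
  REV-ERBα induced downstream). Light acts as a 16:8 square wave on *Per*
  transcription. Free-running period 22.3 h; locks to 24 h under LD with
  PER peaking at the end of the light phase and CLOCK-BMAL1 in the dark
  phase.
* **cdk** — a 13-variable cyclin/Cdk network: growth-factor-gated cyclin D,
  a bistable pRB–E2F switch, ordered cyclin E → A → B waves, a
  Wee1/Cdc25-controlled bistable Cdk1 switch that requires cyclin A/Cdk2
  priming, Cdh1/Cdc20 degradation machinery, p21 inhibition, and an
  ATR/Chk1 checkpoint stand-in. A global factor `s` rescales time exactly,
  so any autonomous period can be dialed in.
* **coupling** — three clock-controlled mRNA channels (Wee1 activated by
  CLOCK-BMAL1; p21 repressed by REV-ERBα; cyclin E repressed by
  CLOCK-BMAL1), single-channel or combined under a common strength μ.
  Growth-factor square-wave forcing is also available.
* **analysis** — peak detection, large/minute amplitude splitting, period
  estimation, stroboscopic maps, and a dynamics classifier with labels
  `entrained_24`, `entrained_48`, `complex_periodic`, `chaotic`,
  `unlocked`, `endoreplication`, `tetraploid_pattern`, `quiescent`.
* **sweeps** — period calibration, Arnold-tongue scans over
  (autonomous period × coupling strength), a birhythmicity probe, and
  named scenario presets for the standard protocols (coupling switched on
  at t = 120 h, checkpoint activation, pRB/Cdc25 overexpression, GF square
  waves, Cry-deletion emulation).

## Command line

```sh
cycloclock list-scenarios
cycloclock scenario fig2 --autonomous-period 20 --out runs/fig2
cycloclock calibrate --target-period 28
cycloclock simulate run.toml --out runs/custom
cycloclock classify runs/fig2/fig2.csv --t-transient 240
cycloclock scan --mode wee1 --periods 4:60:4 --couplings 1e-3:1:4 --out tongue
cycloclock clock --t-end 480 --out clock.csv
```

Configuration files are TOML (YAML accepted) with `[clock]`, `[cdk]`,
`[coupling]`, `[ld]`, `[gf]` and `[simulation]` blocks mirroring the
parameter dataclasses; unknown keys are rejected. Trajectories are written
as CSV (`time_h,<states...>,<observables...>`), reports and tongue maps as
JSON, with a frozen config copy and digest per run.

## Layout

```
src/cycloclock/
  core.py      ODE abstraction, integrator, attractor search
  clock.py     circadian oscillator + LD schedule
  cdk.py       Cdk network + GF square wave
  coupling.py  coupling channels and system assembly
  analysis.py  peaks, periods, stroboscopic maps, classifier
  sweeps.py    calibration, tongue scans, scenario presets
  config.py    run configuration parsing/validation
  cli.py       command line interface
tests/         unit, property and acceptance tests
scripts/acceptance.py
```
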