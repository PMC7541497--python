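# ovuclock

A simulator for the circadian regulation of ovulation timing in female
rodents.  It is aimed at chronobiologists and systems physiologists who
want to explore how a weakening of the daily signal from the
suprachiasmatic nucleus (SCN) — a hallmark of aging — turns regular 4-day
estrous cycles into irregular, lengthened, and finally absent ones, and how
circadian clock-period mutations and altered light–dark cycles modulate
that decline.

## Model

Five hormone pools evolve along the hypothalamic–pituitary–gonadal axis
(all times in hours, concentrations in dimensionless model units):

* **GnRH, hypothalamus** — logistic synthesis toward a ceiling `G_Max`,
  release at rate `r_G + R_G(E2) C(t)`, where the daily SCN gate
  `C(t) = A {a_C + b_C sin(ω_C t − 2π ν_C ψ_C/24)}^n` is a sharpened
  sinusoid (period `T`, amplitude `A`) and `R_G` switches between an
  activated and a repressed constant depending on whether the estradiol
  level `τ_E` hours ago exceeds the threshold `E*`.
* **GnRH, pituitary** — receives the released flux, cleared at `c_G`; a
  GnRH surge (GS) is the interval with `G_Pit ≥ G*`.
* **LH, pituitary and blood** — logistic synthesis, release switching on
  `G_Pit ≥ G*`, blood clearance `c_L`; an LH surge (LS) is the interval
  with `L_Blood ≥ L*`.
* **Estradiol** — logistic growth `a_E E2 (1 − E2/E_Max)` interrupted by
  exponential decay `−c_E E2` for `τ_LS` hours after each LS onset.

The ovary holds `N` uncoupled circadian phase oscillators with normally
distributed free-running periods (mean `τ_O`, 3% CV).  Blood LH shifts
each phase through a sinusoidal phase-response curve,
`dφ_j/dt = ω_j + γ sin(φ_j − 2π ν_Z ψ_Z/24) L_Blood`, and each cell
carries a sinusoidal LH sensitivity `S_j`.  The ovulatory signal of the
*i*-th surge is `P_i = ∫ L_Blood S dt` over the `τ_P = 12 h` after onset,
with `S` the population-mean sensitivity; ovulation occurs iff
`P_i ≥ P*`.  Recurring surges entrain the clock population; when the SCN
amplitude drops, weaker surges fail to hold the population together, the
whole-ovary sensitivity rhythm flattens, and `P_i` starts missing the
threshold — the route to irregular cycles.

Default parameters are calibrated (see `docs/methods.md`), not taken from
measurements.

## Worked example

```python
from ovuclock import EngineConfig, cycle_periods, default_parameters, integrate

params = default_parameters()                       # calibrated wild type, A = 2.0
engine = EngineConfig(dt=0.02, t_end=150 * 24.0, t_transient=40 * 24.0, seed=1)
res = integrate(params, engine)

periods = cycle_periods(res.events, engine.t_transient)
print(sorted(set(periods)), len(periods))
print(round(res.events.ls_events[-1].peak, 3))
```

prints

```
[4] 27
0.166
```

— after the 40-day transient the remaining 110 days contain 27 consecutive
estrous cycles, every one 4 days long, and the LH surge peaks at 0.166
model units.  Dropping `A` to 0.74 lowers the surge peak to ≈ 0.159 and
pushes the ovulatory signal against its threshold; below ≈ 0.72 cycles mix
4-day with much longer periods, and below ≈ 0.70 ovulation stops.

The same experiments are available from the shell:

```
ovuclock simulate --out runs/default
ovuclock scan --parameter A --grid 0.6,0.7,0.8,1.0,2.0 --out runs/scanA
ovuclock jetlag --shift -3 --out runs/jl
ovuclock mutant --tau-O 26 --out runs/olong
ovuclock rescue --tau-O 26 --rate-rescale --out runs/olong_rescue
ovuclock calibrate --out runs/calib
```

Each run directory contains tidy CSVs plus a JSON sidecar with the exact
parameters and seeds needed to regenerate it.

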