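# Methods

## Model structure

The model couples a deterministic, switched/delayed hormone subsystem to a
stochastic-only-through-initial-conditions population of ovarian circadian
phase oscillators.

Hormones (hours / dimensionless units):

```
dG_Hypo/dt = a_G (1 − G_Hypo/G_Max) − (r_G + R_G(E2) C(t)) G_Hypo
dG_Pit/dt  = (r_G + R_G(E2) C(t)) G_Hypo − c_G G_Pit
dL_Pit/dt  = a_L (1 − L_Pit/L_Max) − (r_L + R_L(G_Pit)) L_Pit
dL_Blood/dt= (r_L + R_L(G_Pit)) L_Pit − c_L L_Blood
dE2/dt     = −c_E E2                      while t ∈ [t_on, t_on + τ_LS)
           = a_E E2 (1 − E2/E_Max)        otherwise
```

`R_G` equals `R_G_Act` when `E2(t − τ_E) ≥ E*` (inclusive) and `R_G_Rep`
otherwise; `R_L` switches on `G_Pit ≥ G*`.  The SCN gate is
`C(t) = A {a_C + b_C sin(ω_C t − 2π ν_C ψ_C/24)}^n` with `ω_C = 2π/T`,
`ν_C = T/24`; the exponent `n = 10` confines the gate to a ≈ 4-h critical
window each day.  Transfer is mass-consistent: the release flux leaving
the hypothalamic (pituitary) pool is exactly the influx of the pituitary
(blood) pool.

Ovarian clocks: per cell `dφ_j/dt = ω_j + γ sin(φ_j − 2π ν_Z ψ_Z/24)
L_Blood` with `ω_j = 2π/τ_j`, `ν_Z = τ_j/24`; sensitivity
`S_j = a_S + b_S sin(φ_j − 2π ν_S ψ_S/24)`, whole-ovary `S = mean_j S_j`.
Periods are i.i.d. normal(τ_O, 0.03 τ_O); initial phases uniform on
[0, 2π).  There is no inter-cell coupling and no nonlinear modulation of
the LH effect.

Ovulation: `P_i = ∫ L_Blood S dt` over `[t_on, t_on + τ_P]`; ovulation at
`t_on + τ_P` iff `P_i ≥ P*` (inclusive).  Two thresholds are used:
`P* = 4.5e-2` (high, default) and `0.9e-2` (low, a fixed fifth of the high
value, small enough that every surge ovulates).

## How the 4-day cycle arises

After each LH surge, estradiol decays for `τ_LS = 12 h`, falling below
`E*` and switching GnRH release to the repressed branch.  The logistic
regrowth takes ≈ 3 days to re-cross `E*`; `τ_E = 2 h` later the activated
branch is restored, and the next daily SCN gate (several hours later)
dumps the refilled GnRH pool, triggering the GS → LS → estradiol-decay
cascade again.  Because surges can only fire inside the daily gate, cycle
lengths are quantized to whole environmental cycles; the calibration
places the estradiol re-crossing mid-morning of day 4, ≈ 6 h clear of the
gates on either side, which makes the 4-day period robust.

## Calibrated default parameters

No measured rate constants exist for this phenomenological model, so the
defaults are fixed by the staged procedure in
`ovuclock.protocols.calibrate_defaults` (the shipped values in
`ovuclock.params` are its frozen output, rounded):

1. **Structure and scales** (chosen once, by hand): ceilings
   `G_Max = L_Max = E_Max = 1`; gate shape `a_C = 0.55, b_C = 0.45,
   n = 10` so the gate peak equals `A`; `ψ_C = 10 h` (gate peak at 16 h,
   late day); basal release rates `r_G = 0.01, r_L = R_L_Rep = 0.005,
   R_G_Rep = 0.01` small enough that no surge fires outside the activated
   branch; clearances `c_G = 0.5, c_L = 0.5, c_E = 0.15` per hour so
   surges decay within hours and estradiol loses ≈ 83% during the
   half-day post-surge window; thresholds `E* = 0.5, G* = 0.3, L* = 0.08`
   between the repressed-branch and activated-branch excursions;
   `R_G_Act = 0.5` so the GnRH dump saturates near `A = 2` and weakens
   through the 0.6–0.9 range; delays `τ_E = 2 h`, `τ_LS = τ_P = 12 h`
   (rodents ovulate ≈ 12 h after the surge, and estradiol falls for about
   half a day); PRC/sensitivity peaks `ψ_Z = 0, ψ_S = 8 h` placing peak
   sensitivity inside the P-window of an entrained population; coupling
   `γ = 1.5` so an LH surge can correct about one radian of phase per
   cycle at full amplitude.
2. **a_E** from the closed-form logistic passage time: the trough (the
   measured surge-onset estradiol decayed for `τ_LS`) must regain `E*` in
   71.5 h (≈ 3 days), giving `a_E ≈ 0.030`.
3. **R_L_Act** scaled (two fixed-point iterations) so the LH-surge peak at
   `A = 0.74` equals 0.159, giving `R_L_Act ≈ 0.132`.
4. **a_S = b_S** scaled so the minimum ovulatory signal at `A = 0.74`
   sits exactly at the high threshold, giving `a_S = b_S ≈ 0.045`; this
   makes `A ≈ 0.74` the edge of the fully regular band.
5. **Verification**: the default amplitude must yield a sole 4-day period.

The procedure is deterministic under its seed and raises with a
nearest-miss report if an anchor cannot be met.  The rise-time target of
≈ 3 days (rather than 3.5) is a consequence of the geometry above: with a
half-day decay and a surge that fires at ≈ 12.7 h, a slower rise would
push the estradiol re-crossing into or past the day-4 gate and destabilize
the 4-day lock.

With these defaults the wild type cycles regularly for `A ≳ 0.74`, mixes
4-day with long periods around `A ≈ 0.70–0.73`, and stops ovulating below
`A ≈ 0.70` (the analogous published critical values are 0.75 and 0.69;
with a calibrated rather than measured parameter set we treat these as
approximate/directional targets).

## Numerics

Fixed-step classical RK4 (default `dt = 0.01 h`; `dt > 0.1 h` is
refused), hormones and phases advanced jointly.  The release switches and
the estradiol branch are frozen over each step from the step-start state;
`C(t)` is evaluated at the RK4 stage times.  The delayed estradiol is read
from the stored trajectory by linear interpolation, with the history
pre-filled at the initial level over `[−τ_E, 0]`; the delay term is frozen
at its step-start value within a step.  LS onsets are detected online as
upward crossings of `L*` with linearly interpolated onset times; each
onset (re)starts the estradiol decay window (overlapping onsets refresh
it).  GS and estradiol-surge events, and the trapezoidal `P_i` quadrature
at the native step, are extracted from the stored trajectory afterwards.
Step-halving moves LS onsets by < 0.05 h on the default run.  Initial
conditions are deterministic: synthesis pools at 90% of their ceilings,
downstream pools empty, estradiol at 0.10 (rising branch).  Runs are
bit-reproducible under (parameters, dt, seed).  A numba-compiled kernel is
used when numba is importable; the plain-NumPy path is functionally
identical.

## Operational metrics

The published entrainment and synchrony analyses are described only at a
level of intent, so both are re-specified operationally here and labelled
as such in outputs:

* **Entrainment**: a cell is entrained to the recurring LH surge iff, over
  the last 10 surge onsets, the circular SD of its phase sampled at onsets
  is < 0.5 rad *and* its mean observed period is within 0.1 h of
  `T_LS/k`, `k = round(T_LS/τ_obs)` (k = 4 for a 24-h clock under 4-day
  surges).  This is the standard stroboscopic definition of 1:k locking
  and agrees cell-by-cell with brute-force iteration of the stroboscopic
  map in tests.  It requires ≥ 4 surges and a reasonably regular surge
  train; under conditions with irregular surge recurrence the reported
  fraction is conservative (biased low).
* **Synchrony**: the Kuramoto order parameter |mean e^{iφ_j}|.

Condition status is derived from the pooled integer-day period histogram:
`none` (no ovulation), `long` (any period > 10 days), `multi-period`
(≥ 2 distinct periods), `regular-4d` (all periods 4 days; a sole non-4-day
period is reported as `regular-other`).  Periods beyond 10 days are binned
as ">10" in histograms.

## Protocols and chosen problem sizes

Trials differ only in the period/phase realization of the ovary; the same
seed vector is reused across grid values so comparisons are paired.  The
reference protocol uses 5 trials × 400 simulated days with a 40-day
transient discard and N = 200 clocks (≈ 450 pooled cycles).  The test
suite uses 60–150-day runs with N = 100 at `dt = 0.02 h`, sizes chosen to
keep every qualitative regime (regular band, multi-period window,
no-ovulation region) clearly resolved.

Jet-lag applies a ±3-h offset to `ψ_C` during the first 2 consecutive
days of each 7-day block (advance = negative offset).  Whether the
published weekly perturbation alternates sign or uses one sign per
experiment is unclear; both variants are first-class options and the
directional claim (multi-periodicity at larger A) is asserted for the
variant that perturbs more strongly (the 3-h advance, i.e. a −3 h peak
offset).

Mutants set `τ_O` to 26 h (O-long) or 22 h (O-short); rescue sets
`T = τ_O`.  The optional `rate_rescale` flag multiplies `a_G, a_L, a_E` by
`24/T`, emulating hormone production adjusting to the day length.  Without
it the O-short rescue (T = 22 h) mixes 4- and 5-day periods even at high
amplitude — the estradiol rise then barely fits inside four 22-h days —
and the entrainment assay is correspondingly depressed; with the flag both
rescues are fully regular.  The rescue comparisons in the acceptance suite
therefore run with `rate_rescale` on; it is off by default elsewhere.

## What the generator does and does not emulate

The only modelled heterogeneity is the distribution of ovarian clock
periods and initial phases.  Real estrous cycling additionally involves
FSH and progesterone dynamics, pulsatile GnRH release, dose–response
nonlinearity of the LH phase response, inter-cell coupling in the ovary,
and day-to-day physiological noise — none of which are represented.
Passing tests therefore demonstrate properties of this gated-oscillator
mechanism, not quantitative predictions for real animals; in particular
the very long (> 10-day) simulated cycles near the critical amplitude
depend strongly on the high ovulation threshold.

## Known limitations

* Switch times are resolved at step granularity (no root-polishing on the
  switching manifolds); with the default step this contributes ≪ 0.05 h
  of onset error, but very coarse steps would not be meaningful (hence
  the 0.1-h cap).
* The entrainment metric is undefined for < 4 surges and conservative
  when the surge train itself is irregular.
* Critical amplitudes from coarse grids are grid-resolution-limited; the
  fine (0.01-step) scan of the reference protocol is expensive and left
  to offline use.
* The calibration fixes one parameter set; no identifiability analysis is
  attempted, and other sets may satisfy the same anchors.
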