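"""Experiment battery and summary statistics.

Protocols: the default long run, 1-D parameter scans (SCN amplitude ``A``,
estradiol-gated GnRH release ``R_G_Act``, GnRH-gated LH release ``R_L_Act``,
estradiol synthesis ``a_E``), weekly jet-lag of the SCN peak time, ovarian
clock-period mutants (O-long 26 h, O-short 22 h), their rescue by matching
the environmental period to the mutant free-running period, and the
estradiol clamp.  Each condition is repeated over several trials that share
the same seed vector across conditions, so comparisons are paired.

Also houses the staged calibration that produced the shipped default
parameter set.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import EngineConfig, SimResult, cycle_periods, integrate, ls_intervals
from .hormones import estradiol_rise_time
from .ovary import entrainment_fraction
from .params import (
    ConfigError,
    ModelParameters,
    OvulationParams,
    default_parameters,
)
from .scn import build_jetlag_schedule

__all__ = [
    "ProtocolSpec",
    "ConditionResult",
    "ProtocolResult",
    "run_protocol",
    "run_condition",
    "critical_amplitudes",
    "jetlag_protocol",
    "rescue_protocol",
    "clamp_estradiol_protocol",
    "calibrate_defaults",
    "CalibrationError",
    "classify_status",
    "STATUS_ORDER",
]

SCAN_PARAMETERS = ("A", "R_G_Act", "R_L_Act", "a_E")

#: degradation order of condition statuses, best to worst
STATUS_ORDER = ("regular-4d", "regular-other", "multi-period", "long", "none")


class CalibrationError(RuntimeError):
    """Raised when the calibration anchors cannot be satisfied; carries the
    nearest-miss report."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


@dataclass
class ProtocolSpec:
    """Manifest of one protocol run."""

    kind: str = "default"                 # default|scan|jetlag|mutant|rescue|clamp
    scanned_parameter: str = "A"
    grid: Optional[List[float]] = None
    trials: int = 5
    P_star_variant: str = "high"
    mutant_tau_O: Optional[float] = None  # 26 or 22
    T_override: Optional[float] = None
    rate_rescale: bool = False
    jetlag_shift_h: float = 0.0
    jetlag_days_per_week: int = 2
    clamp_level: Optional[float] = None   # None -> clamp at E_star

    def validate(self) -> None:
        if self.kind not in {"default", "scan", "jetlag", "mutant", "rescue", "clamp"}:
            raise ConfigError(f"unknown protocol kind {self.kind!r}")
        if self.kind in {"scan", "jetlag"} and not self.grid:
            raise ConfigError("scan-style protocols need a non-empty grid")
        if self.grid is not None:
            if len(self.grid) == 0:
                raise ConfigError("grid must not be empty")
            if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
                raise ConfigError("grid must be strictly increasing")
        if self.scanned_parameter not in SCAN_PARAMETERS:
            raise ConfigError(f"scanned_parameter must be one of {SCAN_PARAMETERS}")
        if self.trials < 1:
            raise ConfigError("trials must be >= 1")
        if self.P_star_variant not in {"high", "low"}:
            raise ConfigError("P_star_variant must be 'high' or 'low'")


@dataclass
class ConditionResult:
    """Pooled statistics of one (condition, parameter value)."""

    value: float
    period_hist: Dict[object, int]       # day -> count, with ">10" overflow bin
    ls_hist: Dict[object, int]
    status: str
    n_ovulations: int
    entrain_frac: float                  # trial mean; nan if undefined
    sync_mean: float
    ls_peak_mean: float
    ls_peak_sd: float
    periods: List[int] = field(default_factory=list)
    ls_ints: List[int] = field(default_factory=list)
    trial_seeds: List[int] = field(default_factory=list)


@dataclass
class ProtocolResult:
    spec: ProtocolSpec
    conditions: Dict[float, ConditionResult]

    def to_frame(self):
        import pandas as pd

        rows = []
        for val, c in self.conditions.items():
            for day, count in sorted(c.period_hist.items(), key=lambda kv: str(kv[0])):
                rows.append(
                    dict(protocol=self.spec.kind, parameter=self.spec.scanned_parameter,
                         value=val, period_days=day, count=count, status=c.status,
                         entrain_frac=c.entrain_frac, sync=c.sync_mean,
                         ls_peak_mean=c.ls_peak_mean, ls_peak_sd=c.ls_peak_sd)
                )
            if not c.period_hist:
                rows.append(
                    dict(protocol=self.spec.kind, parameter=self.spec.scanned_parameter,
                         value=val, period_days="none", count=0, status=c.status,
                         entrain_frac=c.entrain_frac, sync=c.sync_mean,
                         ls_peak_mean=c.ls_peak_mean, ls_peak_sd=c.ls_peak_sd)
                )
        return pd.DataFrame(rows)


def classify_status(periods: Sequence[int], n_ovulations: int) -> str:
    """Condition status from the pooled period list.

    none: no ovulation in the statistics window; long: any period over 10
    days; multi-period: at least two distinct periods; regular-4d: all
    periods equal 4 days (regular-other for a sole non-4-day period).
    """
    if n_ovulations == 0 or len(periods) == 0:
        return "none"
    distinct = set(periods)
    if any(p > 10 for p in distinct):
        return "long"
    if len(distinct) > 1:
        return "multi-period"
    return "regular-4d" if distinct == {4} else "regular-other"


def _hist(periods: Sequence[int]) -> Dict[object, int]:
    h: Counter = Counter()
    for p in periods:
        h[p if p <= 10 else ">10"] += 1
    return dict(h)


def _condition_params(base: ModelParameters, spec: ProtocolSpec, value: Optional[float],
                      t_end: float) -> ModelParameters:
    p = base.replace(ovulation={"P_star": OvulationParams.variant(spec.P_star_variant).P_star})
    scn_upd: dict = {}
    hor_upd: dict = {}
    ova_upd: dict = {}
    if spec.mutant_tau_O is not None:
        ova_upd["tau_O"] = float(spec.mutant_tau_O)
    if spec.T_override is not None:
        scn_upd["T"] = float(spec.T_override)
    T = scn_upd.get("T", base.scn.T)
    if spec.rate_rescale:
        f = 24.0 / T
        hor_upd["a_G"] = base.hormones.a_G * f
        hor_upd["a_L"] = base.hormones.a_L * f
        hor_upd["a_E"] = base.hormones.a_E * f
    if spec.kind == "jetlag" and spec.jetlag_shift_h != 0.0:
        scn_upd["phase_schedule"] = build_jetlag_schedule(
            spec.jetlag_shift_h, spec.jetlag_days_per_week, 0.0, t_end, T=T
        )
    if value is not None:
        if spec.scanned_parameter == "A":
            scn_upd["A"] = float(value)
        else:
            hor_upd[spec.scanned_parameter] = float(value)
    if scn_upd:
        p = p.replace(scn=scn_upd)
    if hor_upd:
        p = p.replace(hormones=hor_upd)
    if ova_upd:
        p = p.replace(ovary=ova_upd)
    return p


def _trial_stats(res: SimResult, t_transient: float):
    ev = res.events
    periods = cycle_periods(ev, t_transient)
    lsi = ls_intervals(ev, t_transient)
    n_ov = res.events.ovulation_times()
    n_ov = int((n_ov >= t_transient).sum())
    on = ev.ls_onsets
    sel = on >= t_transient
    peaks = [e.peak for e in ev.ls_events if e.onset >= t_transient]
    if sel.sum() >= 4:
        ef = entrainment_fraction(on[sel], ev.ls_phase_snapshots[sel])
    else:
        ef = math.nan
    i0 = int(t_transient / res.engine.dt)
    sync = float(res.trajectory.sync_index[i0:].mean())
    return periods, lsi, n_ov, ef, sync, peaks


def run_condition(
    base: ModelParameters,
    spec: ProtocolSpec,
    engine: EngineConfig,
    value: Optional[float] = None,
    seeds: Optional[Sequence[int]] = None,
) -> ConditionResult:
    """Run all trials of one condition and pool the statistics."""
    if seeds is None:
        seeds = [engine.seed + i for i in range(spec.trials)]
    params = _condition_params(base, spec, value, engine.t_end)
    clamp = None
    if spec.kind == "clamp":
        clamp = spec.clamp_level if spec.clamp_level is not None else params.hormones.E_star

    all_periods: List[int] = []
    all_lsi: List[int] = []
    n_ov = 0
    efs: List[float] = []
    syncs: List[float] = []
    peaks: List[float] = []
    for s in seeds:
        eng = dataclasses.replace(engine, seed=int(s))
        res = integrate(params, eng, clamp_E2=clamp)
        per, lsi, nov, ef, sync, pk = _trial_stats(res, engine.t_transient)
        all_periods += per
        all_lsi += lsi
        n_ov += nov
        efs.append(ef)
        syncs.append(sync)
        peaks += pk
    efs_arr = np.array(efs, dtype=float)
    ef_mean = float(np.nanmean(efs_arr)) if np.any(np.isfinite(efs_arr)) else math.nan
    return ConditionResult(
        value=math.nan if value is None else float(value),
        period_hist=_hist(all_periods),
        ls_hist=_hist(all_lsi),
        status=classify_status(all_periods, n_ov),
        n_ovulations=n_ov,
        entrain_frac=ef_mean,
        sync_mean=float(np.mean(syncs)),
        ls_peak_mean=float(np.mean(peaks)) if peaks else math.nan,
        ls_peak_sd=float(np.std(peaks)) if peaks else math.nan,
        periods=all_periods,
        ls_ints=all_lsi,
        trial_seeds=list(map(int, seeds)),
    )


def run_protocol(
    spec: ProtocolSpec,
    base: Optional[ModelParameters] = None,
    engine: Optional[EngineConfig] = None,
) -> ProtocolResult:
    """Run a protocol over its grid (or the single base condition).

    The same trial-seed vector is reused across grid values so that
    condition-to-condition comparisons are paired; the whole run is
    deterministic under (spec, base, engine).
    """
    spec.validate()
    base = default_parameters() if base is None else base
    engine = EngineConfig() if engine is None else engine
    base.validate()
    engine.validate()
    seeds = [engine.seed + i for i in range(spec.trials)]
    grid = spec.grid if spec.grid is not None else [None]
    conditions: Dict[float, ConditionResult] = {}
    for value in grid:
        cond = run_condition(base, spec, engine, value, seeds)
        conditions[cond.value] = cond
    return ProtocolResult(spec=spec, conditions=conditions)


def critical_amplitudes(result: ProtocolResult) -> Tuple[Optional[float], Optional[float]]:
    """(A_multi, A_none) from an amplitude-scan result.

    A_multi: largest grid amplitude whose pooled histogram contains any
    non-4-day period; A_none: largest grid amplitude with zero ovulations.
    ``None`` means "below grid" (no qualifying amplitude).
    """
    if result.spec.scanned_parameter != "A":
        raise ConfigError("critical_amplitudes applies to amplitude scans")
    A_multi = None
    A_none = None
    for val in sorted(result.conditions):
        c = result.conditions[val]
        if c.n_ovulations == 0:
            A_none = val
        if any(k != 4 for k in c.period_hist):
            A_multi = val
    return A_multi, A_none


def jetlag_protocol(
    shift_h: float,
    base: Optional[ModelParameters] = None,
    engine: Optional[EngineConfig] = None,
    grid: Optional[List[float]] = None,
    trials: int = 5,
    pstar: str = "high",
    days_per_week: int = 2,
) -> ProtocolResult:
    """Amplitude scan with the weekly jet-lag schedule active."""
    spec = ProtocolSpec(kind="jetlag", scanned_parameter="A",
                        grid=grid or [0.8, 1.0, 1.2, 1.6, 2.0], trials=trials,
                        P_star_variant=pstar, jetlag_shift_h=shift_h,
                        jetlag_days_per_week=days_per_week)
    return run_protocol(spec, base, engine)


def rescue_protocol(
    mutant_tau_O: float,
    base: Optional[ModelParameters] = None,
    engine: Optional[EngineConfig] = None,
    grid: Optional[List[float]] = None,
    trials: int = 5,
    pstar: str = "high",
    rate_rescale: bool = False,
    rescue: bool = True,
) -> ProtocolResult:
    """Clock-period mutant under T = tau_O (rescue) or T = 24 (unrescued).

    With ``rate_rescale`` the hormone production rates a_G, a_L, a_E are
    scaled by 24/T, emulating production adjusting to the environmental
    day length.
    """
    spec = ProtocolSpec(kind="rescue" if rescue else "mutant", scanned_parameter="A",
                        grid=grid or [0.8, 1.2, 2.0], trials=trials,
                        P_star_variant=pstar, mutant_tau_O=mutant_tau_O,
                        T_override=mutant_tau_O if rescue else None,
                        rate_rescale=rate_rescale)
    return run_protocol(spec, base, engine)


def clamp_estradiol_protocol(
    base: Optional[ModelParameters] = None,
    engine: Optional[EngineConfig] = None,
    level: Optional[float] = None,
    trials: int = 1,
) -> ConditionResult:
    """Estradiol held constant (default: exactly at E_star, the inclusive
    activation boundary); with the clamp at or above E_star, GnRH and LH
    surges recur once per environmental cycle."""
    base = default_parameters() if base is None else base
    engine = EngineConfig() if engine is None else engine
    spec = ProtocolSpec(kind="clamp", trials=trials, clamp_level=level)
    return run_condition(base, spec, engine)


# --------------------------------------------------------------------------
# calibration of the default parameter set
# --------------------------------------------------------------------------

#: calibration anchors (see docs/methods.md): the small-amplitude LH-surge
#: peak, the amplitude at which it is anchored, and the target
#: trough-to-threshold estradiol passage time.
DEFAULT_ANCHORS = {
    "ls_peak_small_A": 0.159,
    "small_A": 0.74,
    "rise_target_h": 71.5,
    "ls_peak_rtol": 0.05,
}


def _measure(params: ModelParameters, A: float, engine: EngineConfig):
    res = integrate(params.replace(scn={"A": A}), engine)
    ev = res.events
    t0 = engine.t_transient
    peaks = [e.peak for e in ev.ls_events if e.onset >= t0]
    Ps = [o.P for o in ev.ovulations
          if not o.excluded and ev.ls_events[o.ls_index].onset >= t0]
    periods = cycle_periods(ev, t0)
    # E2 level at LS onsets (for the rise-time stage)
    E_on = [float(np.interp(e.onset, res.trajectory.t, res.trajectory.E2))
            for e in ev.ls_events if e.onset >= t0]
    return dict(
        ls_peak=float(np.mean(peaks)) if peaks else 0.0,
        P_min=float(np.min(Ps)) if Ps else 0.0,
        P_mean=float(np.mean(Ps)) if Ps else 0.0,
        periods=sorted(set(periods)),
        n_ov=len(periods) + 1 if periods else 0,
        E_on=float(np.mean(E_on)) if E_on else math.nan,
    )


def calibrate_defaults(
    anchors: Optional[dict] = None,
    engine: Optional[EngineConfig] = None,
    seed: int = 1,
) -> Tuple[ModelParameters, dict]:
    """Staged calibration of the default parameter set.

    Stages: (1) set the estradiol synthesis rate from the closed-form
    logistic passage time so the trough-to-threshold rise plus the half-day
    post-surge decay and the wait for the next daily gate fill a 4-day
    cycle; (2) scale the activated LH release rate so the surge peak at the
    small-amplitude anchor matches the target; (3) scale the ovarian
    sensitivity so the ovulatory signal at the small-amplitude anchor sits
    marginally at the high ovulation threshold; (4) verify a sole 4-day
    period at the default amplitude.  Deterministic under ``seed``.

    Returns the calibrated parameters and a report of every stage; raises
    :class:`CalibrationError` with the nearest-miss report if an anchor
    cannot be met.
    """
    a = dict(DEFAULT_ANCHORS)
    if anchors:
        a.update(anchors)
    if engine is None:
        engine = EngineConfig(dt=0.02, t_end=120 * 24.0, t_transient=40 * 24.0,
                              seed=seed)
    base = default_parameters().replace(ovary={"N": 100})
    report: dict = {"anchors": a, "stages": []}

    # stage 1: a_E from the closed-form logistic passage time.  The trough
    # is estimated from the measured E2 at surge onset decayed for tau_LS.
    h = base.hormones
    E_on_est = 0.60
    a_E = h.a_E
    for _ in range(2):
        params = base.replace(hormones={"a_E": round(a_E, 4)})
        m = _measure(params, base.scn.A, engine)
        if math.isfinite(m["E_on"]):
            E_on_est = m["E_on"]
        trough = E_on_est * math.exp(-h.c_E * h.tau_LS)
        probe = params.replace(hormones={"a_E": 1.0})  # rate-free shape factor
        shape = estradiol_rise_time(trough, probe.hormones)  # = a_E * rise time
        a_E = shape / a["rise_target_h"]
    a_E = round(a_E, 4)
    base = base.replace(hormones={"a_E": a_E})
    report["stages"].append({"stage": "a_E", "a_E": a_E, "E_on": E_on_est})

    # stage 2: activated LH release from the small-amplitude surge peak.
    target = a["ls_peak_small_A"]
    R_L_Act = base.hormones.R_L_Act
    for _ in range(2):
        m = _measure(base.replace(hormones={"R_L_Act": round(R_L_Act, 3)}),
                     a["small_A"], engine)
        if m["ls_peak"] <= 0:
            raise CalibrationError("no LH surge at the small-amplitude anchor", report)
        R_L_Act = R_L_Act * target / m["ls_peak"]
    R_L_Act = round(R_L_Act, 3)
    base = base.replace(hormones={"R_L_Act": R_L_Act})
    m2 = _measure(base, a["small_A"], engine)
    report["stages"].append({"stage": "R_L_Act", "R_L_Act": R_L_Act,
                             "ls_peak": m2["ls_peak"]})
    if abs(m2["ls_peak"] - target) > a["ls_peak_rtol"] * target:
        raise CalibrationError(
            f"LH-surge peak {m2['ls_peak']:.4f} misses {target} at the anchor",
            report)

    # stage 3: sensitivity scale from marginal ovulation at the anchor.
    s = base.ovary.a_S
    P_min = m2["P_min"]
    if P_min <= 0:
        raise CalibrationError("no ovulatory signal at the small-amplitude anchor",
                               report)
    s = round(s * base.ovulation.P_star / P_min, 3)
    base = base.replace(ovary={"a_S": s, "b_S": s})
    report["stages"].append({"stage": "sensitivity", "a_S": s, "b_S": s})

    # stage 4: verification at the default amplitude.
    m4 = _measure(base, base.scn.A, engine)
    report["stages"].append({"stage": "verify", **m4})
    if m4["periods"] != [4]:
        raise CalibrationError(
            f"default run is not a sole 4-day cycle (periods {m4['periods']})",
            report)

    calibrated = default_parameters().replace(
        hormones={"a_E": a_E, "R_L_Act": R_L_Act},
        ovary={"a_S": s, "b_S": s},
    )
    report["result"] = {"a_E": a_E, "R_L_Act": R_L_Act, "a_S": s, "b_S": s}
    return calibrated, report
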