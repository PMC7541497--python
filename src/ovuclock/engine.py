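"""Fixed-step integration of the coupled hormone + ovarian-clock system.

The state is (G_Hypo, G_Pit, L_Pit, L_Blood, E2) plus N unwrapped ovarian
phases.  A classical RK4 step advances hormones and phases jointly; the
release switches (estradiol gate on GnRH release, GnRH gate on LH release)
and the estradiol decay branch are evaluated once per step from the
step-start state, and the delayed estradiol E2(t - tau_E) is read from the
stored trajectory with linear interpolation (history pre-filled with the
initial level over [-tau_E, 0]).  LH-surge (LS) onsets are detected online
as upward crossings of L_star with linear-interpolated onset times; each
onset (re)starts the estradiol decay window and snapshots all ovarian
phases for the entrainment assay.

GnRH-surge (GS) and estradiol-surge events, the ovulatory signal
P_i = int L_Blood * S dt over [t_on, t_on + tau_P], and the ovulation
decisions are extracted from the stored full-resolution trajectory after
integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .ovary import OvaryPopulation, sample_periods
from .params import EngineConfig, ModelParameters, OvulationParams
from .scn import schedule_offset

__all__ = [
    "Trajectory",
    "ThresholdEvent",
    "Ovulation",
    "EventLog",
    "SimResult",
    "integrate",
    "ovulatory_signal",
    "decide_ovulation",
    "cycle_periods",
    "ls_intervals",
]

TWO_PI = 2.0 * math.pi


# --------------------------------------------------------------------------
# integration kernel (numba-compiled when available)
# --------------------------------------------------------------------------

def _kernel_impl(
    n_steps, dt,
    A, aC, bC, omC, nuC, psiC, n_exp, psi_off,
    a_G, G_Max, r_G, RG_Act, RG_Rep, E_star, tau_E, c_G,
    a_L, L_Max, r_L, RL_Act, RL_Rep, G_star, c_L, L_star,
    a_E, c_E, E_Max, tau_LS,
    clamp_flag, gamma, a_S, b_S,
    omega, thZ, thS, phi,
    Gh, Gp, Lp, Lb, E2a, Ca, Sa, Ra,
    ls_onsets, ls_snap,
):
    N = omega.size
    delay_steps = tau_E / dt
    in_decay_until = -1.0e30
    n_ls = 0
    max_ev = ls_onsets.size

    # initial derived outputs
    base0 = aC + bC * np.sin(omC * 0.0 - TWO_PI * nuC * (psiC + psi_off[0]) / 24.0)
    Ca[0] = A * base0 ** n_exp
    Sa[0] = a_S + b_S * np.mean(np.sin(phi - thS))
    Ra[0] = math.sqrt(np.mean(np.cos(phi)) ** 2 + np.mean(np.sin(phi)) ** 2)

    for i in range(n_steps):
        t = i * dt
        # frozen per-step switch branches
        pos = i - delay_steps
        if pos <= 0.0:
            E2_del = E2a[0]
        else:
            k = int(pos)
            frac = pos - k
            E2_del = E2a[k] * (1.0 - frac) + E2a[k + 1] * frac
        RG = RG_Act if E2_del >= E_star else RG_Rep
        RL = RL_Act if Gp[i] >= G_star else RL_Rep
        decay = t < in_decay_until
        psi_eff = psiC + psi_off[i]
        phase_term = TWO_PI * nuC * psi_eff / 24.0

        y_Gh = Gh[i]; y_Gp = Gp[i]; y_Lp = Lp[i]; y_Lb = Lb[i]; y_E2 = E2a[i]

        # RK4 stages; C evaluated at the stage times with the step's offset
        kGh = np.empty(4); kGp = np.empty(4); kLp = np.empty(4)
        kLb = np.empty(4); kE2 = np.empty(4)
        kphi = np.empty((4, N))
        for st in range(4):
            if st == 0:
                ts = t
                sGh = y_Gh; sGp = y_Gp; sLp = y_Lp; sLb = y_Lb; sE2 = y_E2
                sphi = phi
            elif st == 1:
                ts = t + 0.5 * dt
                sGh = y_Gh + 0.5 * dt * kGh[0]; sGp = y_Gp + 0.5 * dt * kGp[0]
                sLp = y_Lp + 0.5 * dt * kLp[0]; sLb = y_Lb + 0.5 * dt * kLb[0]
                sE2 = y_E2 + 0.5 * dt * kE2[0]
                sphi = phi + 0.5 * dt * kphi[0]
            elif st == 2:
                ts = t + 0.5 * dt
                sGh = y_Gh + 0.5 * dt * kGh[1]; sGp = y_Gp + 0.5 * dt * kGp[1]
                sLp = y_Lp + 0.5 * dt * kLp[1]; sLb = y_Lb + 0.5 * dt * kLb[1]
                sE2 = y_E2 + 0.5 * dt * kE2[1]
                sphi = phi + 0.5 * dt * kphi[1]
            else:
                ts = t + dt
                sGh = y_Gh + dt * kGh[2]; sGp = y_Gp + dt * kGp[2]
                sLp = y_Lp + dt * kLp[2]; sLb = y_Lb + dt * kLb[2]
                sE2 = y_E2 + dt * kE2[2]
                sphi = phi + dt * kphi[2]

            base = aC + bC * math.sin(omC * ts - phase_term)
            C = A * base ** n_exp
            relG = r_G + RG * C
            relL = r_L + RL
            kGh[st] = a_G * (1.0 - sGh / G_Max) - relG * sGh
            kGp[st] = relG * sGh - c_G * sGp
            kLp[st] = a_L * (1.0 - sLp / L_Max) - relL * sLp
            kLb[st] = relL * sLp - c_L * sLb
            if clamp_flag:
                kE2[st] = 0.0
            elif decay:
                kE2[st] = -c_E * sE2
            else:
                kE2[st] = a_E * sE2 * (1.0 - sE2 / E_Max)
            kphi[st] = omega + gamma * np.sin(sphi - thZ) * sLb

        Gh[i + 1] = y_Gh + dt / 6.0 * (kGh[0] + 2.0 * kGh[1] + 2.0 * kGh[2] + kGh[3])
        Gp[i + 1] = y_Gp + dt / 6.0 * (kGp[0] + 2.0 * kGp[1] + 2.0 * kGp[2] + kGp[3])
        Lp[i + 1] = y_Lp + dt / 6.0 * (kLp[0] + 2.0 * kLp[1] + 2.0 * kLp[2] + kLp[3])
        Lb[i + 1] = y_Lb + dt / 6.0 * (kLb[0] + 2.0 * kLb[1] + 2.0 * kLb[2] + kLb[3])
        E2a[i + 1] = y_E2 + dt / 6.0 * (kE2[0] + 2.0 * kE2[1] + 2.0 * kE2[2] + kE2[3])
        phi = phi + dt / 6.0 * (kphi[0] + 2.0 * kphi[1] + 2.0 * kphi[2] + kphi[3])

        tb = t + dt
        base = aC + bC * math.sin(omC * tb - phase_term)
        Ca[i + 1] = A * base ** n_exp
        Sa[i + 1] = a_S + b_S * np.mean(np.sin(phi - thS))
        Ra[i + 1] = math.sqrt(np.mean(np.cos(phi)) ** 2 + np.mean(np.sin(phi)) ** 2)

        # online LS-onset detection: upward crossing of L_star
        if Lb[i] < L_star <= Lb[i + 1]:
            frac_on = (L_star - Lb[i]) / (Lb[i + 1] - Lb[i])
            t_on = t + dt * frac_on
            in_decay_until = t_on + tau_LS
            if n_ls < max_ev:
                ls_onsets[n_ls] = t_on
                ls_snap[n_ls] = phi
                n_ls += 1

        if i % 1000 == 0:
            if not (math.isfinite(Lb[i + 1]) and math.isfinite(E2a[i + 1])):
                return n_ls, 1, phi
    if not (math.isfinite(Lb[n_steps]) and math.isfinite(E2a[n_steps])):
        return n_ls, 1, phi
    return n_ls, 0, phi


try:  # optional acceleration; the plain-NumPy path is functionally identical
    from numba import njit

    _kernel = njit(cache=True)(_kernel_impl)
except ImportError:  # pragma: no cover - numba present in normal installs
    _kernel = _kernel_impl


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Full-resolution simulated trajectory (native step ``dt``)."""

    dt: float
    t: np.ndarray
    G_Hypo: np.ndarray
    G_Pit: np.ndarray
    L_Pit: np.ndarray
    L_Blood: np.ndarray
    E2: np.ndarray
    C: np.ndarray
    S: np.ndarray
    sync_index: np.ndarray

    def to_frame(self, stride: int = 1):
        import pandas as pd

        sl = slice(None, None, max(1, int(stride)))
        return pd.DataFrame(
            {
                "time_h": self.t[sl],
                "G_Hypo": self.G_Hypo[sl],
                "G_Pit": self.G_Pit[sl],
                "L_Pit": self.L_Pit[sl],
                "L_Blood": self.L_Blood[sl],
                "E2": self.E2[sl],
                "C": self.C[sl],
                "S": self.S[sl],
                "sync_index": self.sync_index[sl],
            }
        )


@dataclass
class ThresholdEvent:
    onset: float
    offset: float
    peak: float


@dataclass
class Ovulation:
    ls_index: int
    P: float
    time: float
    ovulated: bool
    excluded: bool = False   # P-window ran past t_end


@dataclass
class EventLog:
    ls_events: List[ThresholdEvent]
    gs_events: List[ThresholdEvent]
    e2_surges: List[ThresholdEvent]
    ovulations: List[Ovulation]
    ls_phase_snapshots: np.ndarray  # (n_ls, N) unwrapped phases at LS onsets

    @property
    def ls_onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.ls_events])

    def ovulation_times(self, include_excluded: bool = False) -> np.ndarray:
        return np.array(
            [o.time for o in self.ovulations
             if o.ovulated and (include_excluded or not o.excluded)]
        )


@dataclass
class SimResult:
    params: ModelParameters
    engine: EngineConfig
    population: OvaryPopulation
    trajectory: Trajectory
    events: EventLog


# --------------------------------------------------------------------------
# event extraction helpers
# --------------------------------------------------------------------------

def _threshold_events(t: np.ndarray, x: np.ndarray, thr: float) -> List[ThresholdEvent]:
    """Maximal intervals with x >= thr; onset/offset linearly interpolated.

    A new event requires a prior downward crossing, so one surge is never
    double-counted.  An interval still open at the end of the record is
    closed at the final time.
    """
    above = x >= thr
    events: List[ThresholdEvent] = []
    dt = t[1] - t[0] if t.size > 1 else 0.0
    i = 0
    n = x.size
    while i < n:
        if above[i] and (i == 0 or not above[i - 1]):
            if i == 0:
                onset = t[0]
            else:
                frac = (thr - x[i - 1]) / (x[i] - x[i - 1])
                onset = t[i - 1] + frac * dt
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j + 1 < n:
                frac = (x[j] - thr) / (x[j] - x[j + 1])
                offset = t[j] + frac * dt
            else:
                offset = t[-1]
            peak = float(np.max(x[i:j + 1]))
            events.append(ThresholdEvent(float(onset), float(offset), peak))
            i = j + 1
        else:
            i += 1
    return events


def ovulatory_signal(t_on: float, traj: Trajectory, ov: OvulationParams) -> Optional[float]:
    """Trapezoidal quadrature of L_Blood * S over [t_on, t_on + tau_P].

    Sampled at the trajectory's native step; returns None when the window
    extends past the end of the record (the event is excluded from
    statistics and flagged).
    """
    t_off = t_on + ov.tau_P
    if t_off > traj.t[-1] + 1e-9:
        return None
    m = max(1, int(round(ov.tau_P / traj.dt)))
    ts = t_on + (t_off - t_on) * np.arange(m + 1) / m
    integrand = np.interp(ts, traj.t, traj.L_Blood) * np.interp(ts, traj.t, traj.S)
    return float(np.trapezoid(integrand, ts))


def decide_ovulation(P_i: float, t_on: float, ov: OvulationParams):
    """Ovulated iff P_i >= P_star (inclusive); ovulation time is the end of
    the evaluation window, so cycle statistics are onset-locked."""
    return P_i >= ov.P_star, t_on + ov.tau_P


def cycle_periods(events: EventLog, t_transient: float = 0.0) -> List[int]:
    """Integer-day estrous periods: consecutive ovulation-time differences
    after transient discard, / 24 and rounded to the nearest day."""
    times = events.ovulation_times()
    times = times[times >= t_transient]
    if times.size < 2:
        return []
    return [int(round(d / 24.0)) for d in np.diff(times)]


def ls_intervals(events: EventLog, t_transient: float = 0.0) -> List[int]:
    """Integer-day LS intervals after transient discard."""
    on = events.ls_onsets
    on = on[on >= t_transient]
    if on.size < 2:
        return []
    return [int(round(d / 24.0)) for d in np.diff(on)]


# --------------------------------------------------------------------------
# top-level integration
# --------------------------------------------------------------------------

#: deterministic initial hormone levels: nearly full synthesis pools, empty
#: downstream pools, estradiol low on its rising branch.
_E2_INIT = 0.10


def integrate(
    params: ModelParameters,
    engine: EngineConfig,
    population: Optional[OvaryPopulation] = None,
    clamp_E2: Optional[float] = None,
) -> SimResult:
    """Run one trial and return trajectory + event log + population.

    ``clamp_E2`` freezes estradiol at the given constant level (the
    estradiol-clamp protocol); all other dynamics are unchanged.  Fully
    reproducible: identical (params, engine.seed, dt) give bit-identical
    results.
    """
    params.validate()
    engine.validate()
    if population is None:
        population = sample_periods(params.ovary, engine.seed)

    n_steps = int(round(engine.t_end / engine.dt))
    dt = engine.dt
    t = np.arange(n_steps + 1) * dt

    psi_off = np.asarray(
        schedule_offset(t[:-1] if n_steps else t, params.scn.phase_schedule), dtype=float
    )
    if psi_off.ndim == 0:
        psi_off = np.full(max(n_steps, 1), float(psi_off))

    h = params.hormones
    scn = params.scn
    ova = params.ovary

    Gh = np.zeros(n_steps + 1); Gp = np.zeros(n_steps + 1)
    Lp = np.zeros(n_steps + 1); Lb = np.zeros(n_steps + 1)
    E2a = np.zeros(n_steps + 1)
    Ca = np.zeros(n_steps + 1); Sa = np.zeros(n_steps + 1)
    Ra = np.zeros(n_steps + 1)

    Gh[0] = 0.9 * h.G_Max
    Lp[0] = 0.9 * h.L_Max
    E2a[0] = _E2_INIT if clamp_E2 is None else float(clamp_E2)

    max_ev = int(engine.t_end / (0.5 * scn.T)) + 8
    ls_onsets = np.zeros(max_ev)
    ls_snap = np.zeros((max_ev, ova.N))

    thZ = TWO_PI * (population.periods / 24.0) * ova.psi_Z / 24.0
    thS = TWO_PI * (population.periods / 24.0) * ova.psi_S / 24.0

    n_ls, err, phi_final = _kernel(
        n_steps, dt,
        scn.A, scn.a_C, scn.b_C, scn.omega_C, scn.nu_C, scn.psi_C, scn.n, psi_off,
        h.a_G, h.G_Max, h.r_G, h.R_G_Act, h.R_G_Rep, h.E_star, h.tau_E, h.c_G,
        h.a_L, h.L_Max, h.r_L, h.R_L_Act, h.R_L_Rep, h.G_star, h.c_L, h.L_star,
        h.a_E, h.c_E, h.E_Max, h.tau_LS,
        clamp_E2 is not None, ova.gamma, ova.a_S, ova.b_S,
        population.omegas.astype(float), thZ, thS, population.phases.astype(float).copy(),
        Gh, Gp, Lp, Lb, E2a, Ca, Sa, Ra,
        ls_onsets, ls_snap,
    )
    if err:
        raise RuntimeError(
            "integration diverged (non-finite state); check parameter magnitudes"
        )

    traj = Trajectory(dt=dt, t=t, G_Hypo=Gh, G_Pit=Gp, L_Pit=Lp,
                      L_Blood=Lb, E2=E2a, C=Ca, S=Sa, sync_index=Ra)

    ls_events = _threshold_events(t, Lb, h.L_star)
    gs_events = _threshold_events(t, Gp, h.G_star)
    e2_surges = _threshold_events(t, E2a, h.E_star)

    ovulations: List[Ovulation] = []
    for idx, ev in enumerate(ls_events):
        P = ovulatory_signal(ev.onset, traj, params.ovulation)
        if P is None:
            ovulations.append(Ovulation(idx, math.nan, ev.onset + params.ovulation.tau_P,
                                        ovulated=False, excluded=True))
        else:
            ok, when = decide_ovulation(P, ev.onset, params.ovulation)
            ovulations.append(Ovulation(idx, P, when, ovulated=ok))

    events = EventLog(
        ls_events=ls_events,
        gs_events=gs_events,
        e2_surges=e2_surges,
        ovulations=ovulations,
        ls_phase_snapshots=ls_snap[:n_ls].copy(),
    )
    final_pop = OvaryPopulation(periods=population.periods.copy(), phases=phi_final)
    return SimResult(params=params, engine=engine, population=final_pop,
                     trajectory=traj, events=events)
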