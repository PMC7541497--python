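"""Heterogeneous population of uncoupled ovarian circadian phase oscillators.

Each cell ``j`` carries a free-running period ``tau_j`` (drawn normal with
mean ``tau_O`` and 3% relative SD by default), a phase ``phi_j`` obeying

    dphi_j/dt = omega_j + gamma * sin(phi_j - 2 pi nu_Z psi_Z / 24) * L_Blood

with ``omega_j = 2 pi / tau_j`` and ``nu_Z = tau_j / 24``, and a sinusoidal
LH sensitivity

    S_j = a_S + b_S * sin(phi_j - 2 pi nu_S psi_S / 24),  nu_S = tau_j / 24.

The whole-ovary sensitivity ``S`` is the population mean of ``S_j``.
Recurring LH surges act as a periodic kick that can 1:k phase-lock a cell;
entrainment and synchrony metrics operate on phase snapshots taken at
LH-surge onsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ConfigError, OvaryParams

__all__ = [
    "OvaryPopulation",
    "sample_periods",
    "phase_rhs",
    "sensitivity",
    "synchrony_index",
    "entrainment_fraction",
    "entrained_mask",
]

TWO_PI = 2.0 * math.pi


@dataclass
class OvaryPopulation:
    """Sampled free-running periods and (unwrapped) phases of N cells."""

    periods: np.ndarray   # tau_j, hours
    phases: np.ndarray    # phi_j, radians, unwrapped

    @property
    def N(self) -> int:
        return self.periods.size

    @property
    def omegas(self) -> np.ndarray:
        return TWO_PI / self.periods

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"cell": np.arange(self.N), "tau_h": self.periods, "phi0_rad": self.phases}
        )


def sample_periods(p: OvaryParams, seed: int) -> OvaryPopulation:
    """Draw the period/phase realisation of one trial.

    Periods are i.i.d. normal(tau_O, period_cv * tau_O); non-positive draws
    are redrawn (unreachable in practice at 3% CV).  Initial phases are
    uniform on [0, 2 pi).
    """
    p.validate()
    rng = np.random.default_rng(seed)
    periods = rng.normal(p.tau_O, p.period_cv * p.tau_O, size=p.N)
    while np.any(periods <= 0.0):
        bad = periods <= 0.0
        periods[bad] = rng.normal(p.tau_O, p.period_cv * p.tau_O, size=int(bad.sum()))
    phases = rng.uniform(0.0, TWO_PI, size=p.N)
    return OvaryPopulation(periods=periods, phases=phases)


def _theta(periods: np.ndarray, psi: float) -> np.ndarray:
    # per-cell angular offset 2 pi * (tau_j/24) * psi / 24
    return TWO_PI * (periods / 24.0) * psi / 24.0


def phase_rhs(phases: np.ndarray, pop: OvaryPopulation, L_blood: float, p: OvaryParams) -> np.ndarray:
    """dphi_j/dt for the whole population at blood LH level ``L_blood``."""
    theta_Z = _theta(pop.periods, p.psi_Z)
    return pop.omegas + p.gamma * np.sin(phases - theta_Z) * L_blood


def sensitivity(phases: np.ndarray, pop: OvaryPopulation, p: OvaryParams):
    """Per-cell sensitivities S_j and the whole-ovary mean S."""
    theta_S = _theta(pop.periods, p.psi_S)
    S_j = p.a_S + p.b_S * np.sin(phases - theta_S)
    return S_j, float(np.mean(S_j))


def synchrony_index(phases: np.ndarray) -> float:
    """Kuramoto order parameter: modulus of the mean unit phasor, in [0, 1]."""
    z = np.exp(1j * np.asarray(phases, dtype=float))
    return float(abs(z.mean()))


def _circular_sd(angles: np.ndarray) -> float:
    R = abs(np.exp(1j * angles).mean())
    R = min(max(R, 1e-12), 1.0)
    return math.sqrt(-2.0 * math.log(R))


def entrained_mask(
    ls_onsets: np.ndarray,
    phase_snapshots: np.ndarray,
    phase_sd_tol: float = 0.5,
    period_tol: float = 0.1,
    n_last: int = 10,
) -> np.ndarray:
    """Boolean per-cell entrainment classification.

    A cell counts as entrained to the recurring LH surge iff, over the last
    ``n_last`` surge onsets,

    * the circular SD of its (wrapped) phase sampled at onsets is below
      ``phase_sd_tol`` radians, and
    * its mean observed period ``tau_obs = 2 pi (t_m - t_1) / (phi_m - phi_1)``
      is within ``period_tol`` hours of ``T_LS / k``, where ``T_LS`` is the
      mean onset spacing and ``k = round(T_LS / tau_obs)`` is the integer
      number of clock cycles per surge interval (k = 4 for a 24-h clock and
      4-day surges).

    ``phase_snapshots`` has shape (n_onsets, N) and holds *unwrapped*
    phases at each onset.
    """
    ls_onsets = np.asarray(ls_onsets, dtype=float)
    snaps = np.asarray(phase_snapshots, dtype=float)
    if ls_onsets.size < 4:
        raise ValueError("entrainment assay needs at least 4 LH-surge events")
    m = min(n_last, ls_onsets.size)
    t = ls_onsets[-m:]
    ph = snaps[-m:, :]
    T_ls = float(np.mean(np.diff(t)))

    wrapped = np.mod(ph, TWO_PI)
    R = np.abs(np.exp(1j * wrapped).mean(axis=0))
    R = np.clip(R, 1e-12, 1.0)
    circ_sd = np.sqrt(-2.0 * np.log(R))

    dphi = ph[-1, :] - ph[0, :]
    span = t[-1] - t[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_obs = TWO_PI * span / dphi
    ok_period = np.zeros(ph.shape[1], dtype=bool)
    pos = dphi > 0
    k = np.zeros_like(tau_obs)
    k[pos] = np.round(T_ls / tau_obs[pos])
    valid = pos & (k >= 1)
    ok_period[valid] = np.abs(tau_obs[valid] - T_ls / k[valid]) < period_tol
    return (circ_sd < phase_sd_tol) & ok_period


def entrainment_fraction(
    ls_onsets: np.ndarray,
    phase_snapshots: np.ndarray,
    phase_sd_tol: float = 0.5,
    period_tol: float = 0.1,
    n_last: int = 10,
) -> float:
    """Fraction of cells entrained to the recurring LH surge (see
    :func:`entrained_mask` for the operational criterion)."""
    mask = entrained_mask(ls_onsets, phase_snapshots, phase_sd_tol, period_tol, n_last)
    return float(mask.mean())
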