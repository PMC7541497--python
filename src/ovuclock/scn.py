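"""SCN-derived circadian forcing, including jet-lag phase schedules.

The daily gating signal is a sharpened sinusoid

    C(t) = A * ( a_C + b_C * sin(omega_C t - 2 pi nu_C psi_eff / 24) )**n

with ``omega_C = 2 pi / T`` and ``nu_C = T / 24``.  ``psi_eff`` equals
``psi_C`` plus any schedule offset active at ``t``; jet-lag protocols use a
weekly-periodic schedule in which the peak time is advanced (negative
offset) or delayed (positive offset) during a block of consecutive days of
each 7-day week.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .params import ConfigError, SCNConfig

__all__ = ["evaluate_scn", "schedule_offset", "build_jetlag_schedule"]

TWO_PI = 2.0 * math.pi


def schedule_offset(t, phase_schedule: Sequence) -> np.ndarray | float:
    """Offset (h) applied to psi_C at time(s) ``t`` by a list of
    ``(start_h, end_h, offset_h)`` windows (half-open ``[start, end)``)."""
    t = np.asarray(t, dtype=float)
    off = np.zeros_like(t)
    for start, end, shift in phase_schedule:
        off = np.where((t >= start) & (t < end), shift, off)
    return off if off.ndim else float(off)


def evaluate_scn(t, cfg: SCNConfig):
    """Evaluate the forcing C(t) (dimensionless, >= 0) at time(s) ``t`` in h."""
    cfg.validate()
    t = np.asarray(t, dtype=float)
    psi_eff = cfg.psi_C + schedule_offset(t, cfg.phase_schedule)
    base = cfg.a_C + cfg.b_C * np.sin(cfg.omega_C * t - TWO_PI * cfg.nu_C * psi_eff / 24.0)
    out = cfg.A * base ** cfg.n
    return out if out.ndim else float(out)


def build_jetlag_schedule(
    shift_h: float,
    days_per_week: int = 2,
    start: float = 0.0,
    duration: float = 400.0 * 24.0,
    T: float = 24.0,
) -> list:
    """Weekly-periodic jet-lag schedule as ``(start_h, end_h, offset_h)`` windows.

    Within each 7-day block beginning at ``start``, the peak-timing
    parameter ``psi_C`` is offset by ``shift_h`` during the first
    ``days_per_week`` consecutive days and reverts to its default for the
    remainder of the week.  A phase *advance* is a negative ``shift_h``
    (peak occurs earlier), a *delay* is positive.
    """
    if not 1 <= int(days_per_week) <= 7:
        raise ConfigError("days_per_week must be in 1..7")
    if abs(shift_h) >= T:
        raise ConfigError("|shift_h| must be < T (degenerate phase)")
    if duration <= 0:
        raise ConfigError("duration must be positive")
    if shift_h == 0.0:
        return []
    week = 7.0 * 24.0
    block = days_per_week * 24.0
    schedule = []
    t0 = start
    while t0 < start + duration:
        schedule.append((t0, min(t0 + block, start + duration), float(shift_h)))
        t0 += week
    return schedule
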