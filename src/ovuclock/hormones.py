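"""Right-hand sides and switching rules of the hormone subsystem.

Five pools: GnRH in the hypothalamus (``G_Hypo``) and pituitary
(``G_Pit``), LH in the pituitary (``L_Pit``) and blood (``L_Blood``), and
ovarian estradiol (``E2``).  Synthesis of ``G_Hypo`` and ``L_Pit`` is
logistic toward a ceiling; release out of each pool is proportional to the
pool, so the flux leaving the hypothalamus equals the influx into the
pituitary GnRH pool, and likewise for the pituitary-to-blood LH transfer.
Estradiol grows logistically and, for ``tau_LS`` hours after each detected
LH-surge onset, decays exponentially instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import HormoneParams

__all__ = [
    "HormoneState",
    "gnrh_release_rate",
    "lh_release_rate",
    "hormone_rhs",
    "estradiol_rise_time",
]


@dataclass
class HormoneState:
    """Hormone levels plus the bookkeeping the switched dynamics need.

    ``e2_history`` is a callable ``t -> E2(t)`` covering at least the last
    ``tau_E`` hours; ``in_decay_until`` is the absolute time before which
    estradiol follows its post-surge decay branch.
    """

    G_Hypo: float
    G_Pit: float
    L_Pit: float
    L_Blood: float
    E2: float
    e2_history: object = None
    in_decay_until: float = -math.inf


def gnrh_release_rate(E2_delayed: float, C_now: float, p: HormoneParams) -> float:
    """Per-unit GnRH release rate ``r_G + R_G(E2) C`` (1/h).

    The estradiol gate is inclusive: the activated constant applies when
    the delayed estradiol equals or exceeds ``E_star``.
    """
    R_G = p.R_G_Act if E2_delayed >= p.E_star else p.R_G_Rep
    return p.r_G + R_G * C_now


def lh_release_rate(G_Pit: float, p: HormoneParams) -> float:
    """Per-unit LH release rate ``r_L + R_L(G_Pit)`` (1/h), inclusive at G_star."""
    R_L = p.R_L_Act if G_Pit >= p.G_star else p.R_L_Rep
    return p.r_L + R_L


def hormone_rhs(t: float, s: HormoneState, C_now: float, p: HormoneParams):
    """Time derivatives ``(dG_Hypo, dG_Pit, dL_Pit, dL_Blood, dE2)``.

    Requires ``s.e2_history`` to cover ``t - tau_E``; the integrator
    pre-fills the history with the initial estradiol level over
    ``[-tau_E, 0]``.
    """
    if s.e2_history is None:
        raise ValueError("e2_history must cover t - tau_E")
    E2_delayed = float(s.e2_history(t - p.tau_E))

    rel_G = gnrh_release_rate(E2_delayed, C_now, p)
    dG_Hypo = p.a_G * (1.0 - s.G_Hypo / p.G_Max) - rel_G * s.G_Hypo
    dG_Pit = rel_G * s.G_Hypo - p.c_G * s.G_Pit

    rel_L = lh_release_rate(s.G_Pit, p)
    dL_Pit = p.a_L * (1.0 - s.L_Pit / p.L_Max) - rel_L * s.L_Pit
    dL_Blood = rel_L * s.L_Pit - p.c_L * s.L_Blood

    if t < s.in_decay_until:
        dE2 = -p.c_E * s.E2
    else:
        dE2 = p.a_E * s.E2 * (1.0 - s.E2 / p.E_Max)
    return dG_Hypo, dG_Pit, dL_Pit, dL_Blood, dE2


def estradiol_rise_time(E_from: float, p: HormoneParams) -> float:
    """Hours for logistic estradiol growth to pass from ``E_from`` to ``E_star``.

    Closed form of the logistic passage time,

        t = (1/a_E) * ln[ (E*/E_from) * (E_Max - E_from) / (E_Max - E*) ].

    Returns 0 if ``E_from`` already reaches ``E_star``.  Used by the
    calibration stage that sets ``a_E`` from the target trough-to-threshold
    duration.
    """
    if E_from <= 0.0 or p.E_star >= p.E_Max:
        raise ValueError("requires 0 < E_from and E_star < E_Max")
    if E_from >= p.E_star:
        return 0.0
    return (1.0 / p.a_E) * math.log(
        (p.E_star / E_from) * (p.E_Max - E_from) / (p.E_Max - p.E_star)
    )
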