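"""Parameter containers for the circadian-gated estrous-cycle model.

The model couples five hormone pools (hypothalamic and pituitary GnRH,
pituitary and blood LH, ovarian estradiol) to a heterogeneous population of
uncoupled ovarian circadian phase oscillators.  All times are in hours,
all concentrations in dimensionless model units; ``t = 0`` is lights-on of
day 0.

The shipped default values are *calibrated*, not measured: they were fixed
by the staged procedure in :func:`ovuclock.protocols.calibrate_defaults`
so that the wild-type model produces a sole 4-day estrous period under the
default SCN amplitude, an LH-surge peak near 0.159 at low SCN amplitude,
and an estradiol trough-to-threshold passage of about 3 days (so that the
half-day post-surge decay plus the wait for the next daily gate completes
the 4-day cycle).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "SCNConfig",
    "HormoneParams",
    "OvaryParams",
    "OvulationParams",
    "EngineConfig",
    "ModelParameters",
    "ConfigError",
    "P_STAR_HIGH",
    "P_STAR_LOW",
]


class ConfigError(ValueError):
    """Raised when a parameter set violates a structural constraint."""


#: Calibrated ovulation thresholds.  The high variant matches the value the
#: figure-level protocols use (4.5e-2); the low variant is a fixed fraction
#: of it, small enough that every LH surge ovulates.
P_STAR_HIGH = 4.5e-2
P_STAR_LOW = 0.9e-2


@dataclass
class SCNConfig:
    """SCN-derived circadian forcing ``C(t) = A*(a_C + b_C*sin(w_C t - 2 pi nu_C psi_C/24))^n``.

    ``psi_C`` positions the daily peak (for ``T = 24`` the peak falls at
    ``psi_C + 6 (mod 24)`` hours); ``n`` sharpens the waveform so the gate
    is confined to a narrow "critical period" of the day.  ``phase_schedule``
    holds ``(start_h, end_h, offset_h)`` windows during which ``psi_C`` is
    offset, used by the jet-lag protocols.
    """

    A: float = 2.0
    a_C: float = 0.55
    b_C: float = 0.45
    T: float = 24.0
    psi_C: float = 10.0
    n: int = 10
    phase_schedule: list = field(default_factory=list)

    @property
    def omega_C(self) -> float:
        return 2.0 * 3.141592653589793 / self.T

    @property
    def nu_C(self) -> float:
        return self.T / 24.0

    def validate(self) -> None:
        if not (self.a_C > self.b_C >= 0.0):
            raise ConfigError("SCN waveform requires a_C > b_C >= 0")
        if self.A < 0.0:
            raise ConfigError("SCN amplitude A must be >= 0")
        if self.T <= 0.0:
            raise ConfigError("environmental period T must be positive")
        if not isinstance(self.n, (int,)) or isinstance(self.n, bool) or self.n <= 0:
            raise ConfigError("sharpness exponent n must be a positive integer")
        for win in self.phase_schedule:
            if len(win) != 3:
                raise ConfigError("phase_schedule entries are (start_h, end_h, offset_h)")
            start, end, off = win
            if end <= start:
                raise ConfigError("phase_schedule window must have end > start")
            if abs(off) >= self.T:
                raise ConfigError("phase offset magnitude must be < T")


@dataclass
class HormoneParams:
    """Rate constants, thresholds and delays of the hormone subsystem.

    GnRH is synthesised logistically toward ``G_Max`` and released at rate
    ``r_G + R_G(E2) C(t)`` where ``R_G`` switches between an activated and a
    repressed constant depending on whether delayed estradiol exceeds
    ``E_star``.  LH release switches on ``G_Pit >= G_star``; estradiol grows
    logistically and decays exponentially for ``tau_LS`` hours after each
    LH-surge onset.
    """

    # GnRH (hypothalamus -> pituitary)
    a_G: float = 0.3
    G_Max: float = 1.0
    r_G: float = 0.01
    R_G_Act: float = 0.5
    R_G_Rep: float = 0.01
    E_star: float = 0.5
    tau_E: float = 2.0
    c_G: float = 0.5
    # LH (pituitary -> blood)
    a_L: float = 0.1
    L_Max: float = 1.0
    r_L: float = 0.005
    R_L_Act: float = 0.132
    R_L_Rep: float = 0.005
    G_star: float = 0.3
    c_L: float = 0.5
    L_star: float = 0.08
    # estradiol (ovary)
    a_E: float = 0.030
    c_E: float = 0.15
    E_Max: float = 1.0
    tau_LS: float = 12.0

    def validate(self) -> None:
        if not (self.R_G_Act > self.R_G_Rep >= 0.0):
            raise ConfigError("GnRH release requires R_G_Act > R_G_Rep >= 0")
        if not (self.R_L_Act > self.R_L_Rep >= 0.0):
            raise ConfigError("LH release requires R_L_Act > R_L_Rep >= 0")
        positive = {
            "a_G": self.a_G, "G_Max": self.G_Max, "r_G": self.r_G,
            "c_G": self.c_G, "a_L": self.a_L, "L_Max": self.L_Max,
            "r_L": self.r_L, "c_L": self.c_L, "a_E": self.a_E,
            "c_E": self.c_E, "E_Max": self.E_Max, "tau_E": self.tau_E,
            "tau_LS": self.tau_LS, "E_star": self.E_star,
            "G_star": self.G_star, "L_star": self.L_star,
        }
        for name, value in positive.items():
            if value <= 0.0:
                raise ConfigError(f"hormone parameter {name} must be > 0")
        if self.E_star >= self.E_Max:
            raise ConfigError("E_star must lie below the estradiol ceiling E_Max")
        if self.G_star >= self.G_Max:
            raise ConfigError("G_star must lie below the GnRH synthesis scale G_Max")
        if self.L_star >= self.L_Max:
            raise ConfigError("L_star must lie below the LH synthesis scale L_Max")


@dataclass
class OvaryParams:
    """Population of uncoupled ovarian circadian phase oscillators.

    Free-running periods ``tau_j`` are drawn i.i.d. normal with mean
    ``tau_O`` and relative SD ``period_cv``.  Each cell carries a sinusoidal
    LH-sensitivity ``S_j = a_S + b_S sin(phi_j - 2 pi (tau_j/24) psi_S/24)``
    and an LH phase-response curve peaking at ``psi_Z``; ``gamma`` scales the
    phase-shifting action of blood LH.
    """

    N: int = 200
    tau_O: float = 24.0
    period_cv: float = 0.03
    a_S: float = 0.045
    b_S: float = 0.045
    psi_S: float = 8.0
    gamma: float = 1.5
    psi_Z: float = 0.0

    def validate(self) -> None:
        if self.N < 1:
            raise ConfigError("ovary population needs N >= 1")
        if not (self.a_S >= self.b_S >= 0.0):
            raise ConfigError("sensitivity waveform requires a_S >= b_S >= 0")
        if self.tau_O <= 0.0:
            raise ConfigError("mean free-running period tau_O must be positive")
        if self.period_cv < 0.0:
            raise ConfigError("period_cv must be >= 0")
        if self.gamma < 0.0:
            raise ConfigError("coupling strength gamma must be >= 0")


@dataclass
class OvulationParams:
    """Ovulatory decision: ovulate iff the integral of L_Blood*S over the
    ``tau_P`` hours after an LH-surge onset reaches ``P_star``."""

    P_star: float = P_STAR_HIGH
    tau_P: float = 12.0

    def validate(self) -> None:
        if self.P_star <= 0.0:
            raise ConfigError("ovulation threshold P_star must be > 0")
        if self.tau_P <= 0.0:
            raise ConfigError("integration window tau_P must be > 0")

    @classmethod
    def variant(cls, which: str = "high", tau_P: float = 12.0) -> "OvulationParams":
        if which == "high":
            return cls(P_star=P_STAR_HIGH, tau_P=tau_P)
        if which == "low":
            return cls(P_star=P_STAR_LOW, tau_P=tau_P)
        raise ConfigError("P_star variant must be 'high' or 'low'")


@dataclass
class EngineConfig:
    """Fixed-step integration settings (times in hours)."""

    dt: float = 0.01
    t_end: float = 400.0 * 24.0
    t_transient: float = 40.0 * 24.0
    sample_stride: int = 10
    seed: int = 1

    def validate(self) -> None:
        if self.dt <= 0.0:
            raise ConfigError("dt must be positive")
        if self.dt > 0.1:
            raise ConfigError("dt > 0.1 h cannot resolve the release switches")
        if self.t_end <= 0.0:
            raise ConfigError("t_end must be positive")
        if not (0.0 <= self.t_transient < self.t_end):
            raise ConfigError("t_transient must lie in [0, t_end)")
        if self.sample_stride < 1:
            raise ConfigError("sample_stride must be >= 1")


@dataclass
class ModelParameters:
    """Bundle of all model parameter groups."""

    scn: SCNConfig = field(default_factory=SCNConfig)
    hormones: HormoneParams = field(default_factory=HormoneParams)
    ovary: OvaryParams = field(default_factory=OvaryParams)
    ovulation: OvulationParams = field(default_factory=OvulationParams)

    def validate(self) -> None:
        self.scn.validate()
        self.hormones.validate()
        self.ovary.validate()
        self.ovulation.validate()

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        def build(klass, section):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - names
            if unknown:
                raise ConfigError(f"unknown keys in {klass.__name__}: {sorted(unknown)}")
            return klass(**section)

        return cls(
            scn=build(SCNConfig, d.get("scn", {})),
            hormones=build(HormoneParams, d.get("hormones", {})),
            ovary=build(OvaryParams, d.get("ovary", {})),
            ovulation=build(OvulationParams, d.get("ovulation", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def replace(self, **section_updates) -> "ModelParameters":
        """Return a copy with per-section field overrides.

        ``params.replace(scn={"A": 0.8}, hormones={"a_E": 1.3})``
        """
        new = {}
        for name in ("scn", "hormones", "ovary", "ovulation"):
            group = getattr(self, name)
            updates = section_updates.pop(name, None)
            new[name] = dataclasses.replace(group, **updates) if updates else group
        if section_updates:
            raise ConfigError(f"unknown sections: {sorted(section_updates)}")
        return ModelParameters(**new)


def default_parameters(pstar: str = "high") -> ModelParameters:
    """The calibrated wild-type default parameter set."""
    p = ModelParameters(ovulation=OvulationParams.variant(pstar))
    p.validate()
    return p
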