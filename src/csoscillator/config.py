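"""Model parameters and configuration.

Defaults are the published limit-cycle pacemaker values: alpha0 = 0.05,
beta = 0.0075, G = 33.75, p = 0.6, I0 = 9500 (lux/CL_A) or 0.7 (CS mode);
mu = 0.13, q = 0.33, k = 0.55, intrinsic period tau_x = 24.2 h with the
fixed 0.99669 period correction and the 0.4 coefficient in the
(1 - 0.4 x)(1 - 0.4 x_c) sensitivity modulator.  G is treated as a derived
constant of alpha0 and beta and is held fixed during sweeps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .light import Unit
from .phototransduction import CSTransformParams, PHOTOPIC_I0

#: Sweep ranges over which each parameter may be varied (inclusive bounds).
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "alpha0": (0.01, 0.19),
    "beta": (0.0025, 0.0200),
    "p": (0.1, 1.0),
    "mu": (0.01, 0.30),
    "q": (0.15, 1.00),
    "k": (0.15, 0.95),
}


@dataclass(frozen=True)
class ProcessLParams:
    """Dynamic light-processor (Process L) parameters.

    alpha0 : light-activation rate scale, per minute.
    beta : recovery rate, per minute.
    G : drive gain, dimensionless (derived from alpha0 and beta; held
        fixed during parameter sweeps).
    p : light exponent in alpha(I) = alpha0 * (I/I0)^p, in (0, 1].
    I0 : saturation constant in drive units; ``None`` means "resolve from
        the input unit" (9500 for lux/CL_A, the CS asymptote for CS).
    """

    alpha0: float = 0.05
    beta: float = 0.0075
    G: float = 33.75
    p: float = 0.6
    I0: float | None = None

    def __post_init__(self) -> None:
        if min(self.alpha0, self.beta, self.G) <= 0:
            raise ValueError("alpha0, beta, G must be positive")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must be in (0, 1]")
        if self.I0 is not None and self.I0 <= 0:
            raise ValueError("I0 must be positive")


@dataclass(frozen=True)
class ProcessPParams:
    """Limit-cycle oscillator (Process P) parameters.

    mu : van der Pol stiffness.
    q : coupling of the drive into x_c.
    k : drive effect on angular frequency.
    tau_x : intrinsic period, hours.
    period_correction : fixed factor making the simulated free-run period
        equal tau_x.
    modulator_coeff : coefficient of the sensitivity modulator
        (1 - c*x)(1 - c*x_c).
    """

    mu: float = 0.13
    q: float = 0.33
    k: float = 0.55
    tau_x: float = 24.2
    period_correction: float = 0.99669
    modulator_coeff: float = 0.4

    def __post_init__(self) -> None:
        if min(self.mu, self.q, self.k) <= 0:
            raise ValueError("mu, q, k must be positive")
        if not (18.0 < self.tau_x < 30.0):
            raise ValueError("tau_x must be in (18, 30) hours")


@dataclass(frozen=True)
class SolverOptions:
    """Integrator tolerances and step bounds.

    max_step is additionally capped at the light-sampling interval during
    integration so no sample is stepped over; the 0.1 h default keeps the
    output grid at <= 6 min resolution.
    """

    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    max_step: float = 0.1

    def __post_init__(self) -> None:
        if min(self.rel_tol, self.abs_tol, self.max_step) <= 0:
            raise ValueError("tolerances and max_step must be positive")


@dataclass(frozen=True)
class ModelConfig:
    """Full pacemaker configuration: parameters plus toggles.

    process_l : include Process L dynamics; when False the adaptation term
        (1 - n) is frozen at 1 and the light feeds Process P directly as
        B = G * alpha(I).
    modulator : apply the phase-dependent sensitivity modulator.
    input_unit : unit in which the drive enters Process L.
    """

    lp: ProcessLParams = field(default_factory=ProcessLParams)
    pp: ProcessPParams = field(default_factory=ProcessPParams)
    cs: CSTransformParams = field(default_factory=CSTransformParams)
    process_l: bool = True
    modulator: bool = True
    input_unit: Unit = Unit.CS

    @property
    def drive_I0(self) -> float:
        """Saturation constant matching ``input_unit`` (explicit I0 wins)."""
        if self.lp.I0 is not None:
            return self.lp.I0
        return self.cs.asymptote if self.input_unit is Unit.CS else PHOTOPIC_I0

    def replace(self, **kw) -> "ModelConfig":
        """Copy with top-level or parameter fields replaced.

        Parameter names (alpha0, beta, G, p, I0, mu, q, k, tau_x) are
        routed into the nested dataclasses.
        """
        lp_fields = {f.name for f in dataclasses.fields(ProcessLParams)}
        pp_fields = {f.name for f in dataclasses.fields(ProcessPParams)}
        lp_kw = {k: v for k, v in kw.items() if k in lp_fields}
        pp_kw = {k: v for k, v in kw.items() if k in pp_fields}
        top = {k: v for k, v in kw.items() if k not in lp_fields | pp_fields}
        out = self
        if lp_kw:
            out = dataclasses.replace(out, lp=dataclasses.replace(out.lp, **lp_kw))
        if pp_kw:
            out = dataclasses.replace(out, pp=dataclasses.replace(out.pp, **pp_kw))
        if top:
            out = dataclasses.replace(out, **top)
        return out

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha0": self.lp.alpha0,
            "beta": self.lp.beta,
            "G": self.lp.G,
            "p": self.lp.p,
            "I0": self.drive_I0,
            "mu": self.pp.mu,
            "q": self.pp.q,
            "k": self.pp.k,
            "tau_x": self.pp.tau_x,
            "period_correction": self.pp.period_correction,
            "modulator_coeff": self.pp.modulator_coeff,
            "cs_asymptote": self.cs.asymptote,
            "cs_half_saturation": self.cs.half_saturation,
            "cs_steepness": self.cs.steepness,
            "process_l": "on" if self.process_l else "off",
            "modulator": "on" if self.modulator else "off",
            "input_unit": self.input_unit.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        def flag(v):
            if isinstance(v, str):
                return v.lower() in ("on", "true", "yes", "1")
            return bool(v)

        unit = Unit(d.get("input_unit", "cs"))
        asymptote = d.get("cs_asymptote", 0.7)
        i0 = d.get("I0", None)
        # an I0 equal to the unit's default is a derived value, not an
        # override: drop it so later unit switches resolve I0 correctly
        if i0 is not None and i0 == (asymptote if unit is Unit.CS else PHOTOPIC_I0):
            i0 = None
        lp = ProcessLParams(
            alpha0=d.get("alpha0", 0.05),
            beta=d.get("beta", 0.0075),
            G=d.get("G", 33.75),
            p=d.get("p", 0.6),
            I0=i0,
        )
        pp = ProcessPParams(
            mu=d.get("mu", 0.13),
            q=d.get("q", 0.33),
            k=d.get("k", 0.55),
            tau_x=d.get("tau_x", 24.2),
            period_correction=d.get("period_correction", 0.99669),
            modulator_coeff=d.get("modulator_coeff", 0.4),
        )
        cs = CSTransformParams(
            asymptote=d.get("cs_asymptote", 0.7),
            half_saturation=d.get("cs_half_saturation", 355.7),
            steepness=d.get("cs_steepness", 1.1026),
        )
        return cls(
            lp=lp, pp=pp, cs=cs,
            process_l=flag(d.get("process_l", True)),
            modulator=flag(d.get("modulator", True)),
            input_unit=unit,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Load from YAML or JSON (YAML is a JSON superset, so one parser)."""
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
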