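"""Photic-input representations and the circadian stimulus (CS) transform.

CS is a compressive sigmoid of circadian light (CL_A):

    CS = A * [1 - 1 / (1 + (CL_A / c1)^c2)]

with response ceiling (asymptote) A = 0.7, half-saturation c1 = 355.7 and
steepness c2 = 1.1026 by default.  Each drive representation is paired with
the Process L saturation constant I0: 9500 for lux and CL_A, and the CS
asymptote (0.7) when the drive is CS itself, so the ratio I/I0 entering
Process L is bounded in [0, 1) in CS mode.

Lux carries no spectral information, so lux -> CL_A (and lux -> CS) is
rejected as uncomputable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnitConversionError
from .light import LightSeries, Unit

#: Process L saturation constant for photopic lux and CL_A drives.
PHOTOPIC_I0 = 9500.0


@dataclass(frozen=True)
class CSTransformParams:
    """Constants of the CS sigmoid.

    asymptote : dimensionless response ceiling, in (0, 1]; default 0.7.
    half_saturation : CL_A at which the response is half the ceiling.
    steepness : dimensionless exponent.
    """

    asymptote: float = 0.7
    half_saturation: float = 355.7
    steepness: float = 1.1026

    def __post_init__(self) -> None:
        if not (0.0 < self.asymptote <= 1.0):
            raise ValueError("asymptote must be in (0, 1]")
        if self.half_saturation <= 0 or self.steepness <= 0:
            raise ValueError("half_saturation and steepness must be positive")


def cs_from_cla(cla, params: CSTransformParams = CSTransformParams()):
    """Circadian stimulus from circadian light.

    Strictly increasing, continuous, with range [0, asymptote).  Accepts
    scalars or arrays; negative CL_A raises ``ValueError``.
    """
    arr = np.asarray(cla, dtype=float)
    if np.any(arr < 0):
        raise ValueError("CL_A must be nonnegative")
    with np.errstate(divide="ignore"):
        ratio = np.where(arr > 0, (arr / params.half_saturation) ** params.steepness, 0.0)
    out = params.asymptote * (1.0 - 1.0 / (1.0 + ratio))
    return float(out) if np.isscalar(cla) else out


def prepare_drive_series(
    series: LightSeries,
    mode: Unit | str,
    params: CSTransformParams = CSTransformParams(),
) -> tuple[LightSeries, float]:
    """Express a light series in the requested drive unit and pair it with I0.

    Supported conversions: identity for every unit, and CL_A -> CS through
    :func:`cs_from_cla`.  Anything else (lux -> CL_A/CS, CS -> CL_A/lux,
    CL_A -> lux) raises :class:`UnitConversionError`.

    Returns
    -------
    (LightSeries, float)
        The series in drive units and the saturation constant I0 for
        Process L (9500 for lux/CL_A drives, the CS asymptote for CS).
    """
    mode = Unit(mode)
    if series.unit is mode:
        i0 = params.asymptote if mode is Unit.CS else PHOTOPIC_I0
        return series, i0
    if series.unit is Unit.CLA and mode is Unit.CS:
        return series.with_values(cs_from_cla(series.values, params), unit=Unit.CS), params.asymptote
    raise UnitConversionError(
        f"cannot convert {series.unit.value} data to {mode.value}: "
        "no spectral information to move between photopic and circadian "
        "quantities"
    )
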