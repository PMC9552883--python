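"""Exception hierarchy for the pacemaker toolkit."""


class CSOscillatorError(Exception):
    """Base class for all package errors."""


class UnitConversionError(CSOscillatorError):
    """Requested photic-unit conversion is not computable.

    Photopic lux carries no spectral information, so lux -> CL_A (and
    hence lux -> CS) cannot be performed; CS cannot be inverted back to
    CL_A either (the transform is configurable, inversion is out of scope).
    """


class InsufficientSpanError(CSOscillatorError):
    """Trajectory or light series too short for the requested marker."""


class IntegrationError(CSOscillatorError):
    """Numerical integration failed (divergence or non-finite state)."""


class ValidationError(CSOscillatorError):
    """Input data violates a container invariant."""
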