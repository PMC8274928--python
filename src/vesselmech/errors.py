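"""Exception hierarchy shared across the package."""


class VesselMechError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(VesselMechError, ValueError):
    """Arctangent model parameters outside their valid domain (Am <= 0 or P1 <= 0)."""


class ValidationError(VesselMechError, ValueError):
    """Input record or table fails a domain/schema check."""


class InsufficientDataError(VesselMechError, ValueError):
    """Too few distinct pressure points to fit the three-parameter model."""


class DegenerateDataError(VesselMechError, ValueError):
    """Data carry no usable signal (e.g. all areas identical)."""


class ParseError(VesselMechError, ValueError):
    """CSV input malformed; message names the offending row/column."""
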