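"""Exception types shared across the package."""


class CavGateError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CavGateError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(CavGateError, ValueError):
    """A preset override or config file violates a type invariant."""


class ProtocolError(CavGateError, ValueError):
    """A requested voltage or sweep is not part of the stimulation protocol."""


class IncompleteRecordingError(CavGateError, ValueError):
    """A recording lacks the sweeps needed for the requested analysis."""


class DegenerateCurveError(CavGateError, ValueError):
    """An I-V curve is all-zero or otherwise unusable for normalization/fitting."""


class UnreliableMeasurementError(CavGateError, ValueError):
    """The signal is below the noise floor; the measurement would be meaningless."""


class AgeParseError(CavGateError, ValueError):
    """A clinical age string does not match the '<y> yr [<m> mo]' pattern."""


class SequenceParseError(CavGateError, ValueError):
    """A protein sequence contains characters outside the amino-acid alphabet."""
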