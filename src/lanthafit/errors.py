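"""Exception hierarchy shared by all lanthafit modules.

Each class maps to a distinct CLI exit code (see :mod:`lanthafit.cli`).
"""


class LanthafitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(LanthafitError):
    """Invalid or malformed configuration."""

    exit_code = 2


class InputError(LanthafitError):
    """Invalid data or arguments passed to an operation."""

    exit_code = 3


class NumericalError(LanthafitError):
    """A solver or fit failed to converge."""

    exit_code = 4


class ProtocolError(LanthafitError):
    """An invalid titration protocol (e.g. cell overfilled)."""

    exit_code = 5


class CalibrationError(LanthafitError):
    """Concentration calibration violated metal closure beyond tolerance."""

    exit_code = 6
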