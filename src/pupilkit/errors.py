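"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class PupilkitError(Exception):
    """Base class for all pupilkit errors."""


class ConfigError(PupilkitError):
    """Invalid configuration or parameters."""


class ParameterError(ConfigError):
    """Simulation or filter parameters outside their valid domain."""


class DataError(PupilkitError):
    """Invalid, inconsistent, or insufficient input data."""


class TraceFormatError(DataError):
    """A trace or reading file does not follow the CSV dialect."""


class TraceIntegrityError(DataError):
    """A parsed trace violates the trace data-model invariants."""
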