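"""Exception hierarchy shared across the pipeline."""


class DgphysError(Exception):
    """Base class for all package-specific errors."""


class MeasurementError(DgphysError):
    """A measurement could not be computed from the supplied trace."""


class ProtocolError(DgphysError):
    """A protocol step could not be executed (e.g. unreachable holding voltage)."""


class IntegrationError(DgphysError):
    """Numerical divergence during model integration."""


class SamplingError(DgphysError):
    """Population rejection sampling exhausted its attempt budget."""


class FormatError(DgphysError):
    """A trace table or config file failed validation."""


class DegenerateTestError(DgphysError):
    """A hypothesis test was requested on degenerate data (e.g. all-zero diffs)."""
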