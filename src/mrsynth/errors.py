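"""Exception hierarchy shared across the package.

All errors derive from :class:`MRSynthError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
three failure modes of the public contracts (bad physical inputs, bad
configuration, broken call contracts) plus sampling/geometry specifics.
"""


class MRSynthError(Exception):
    """Base class for all mrsynth errors."""


class DomainError(MRSynthError, ValueError):
    """A physical parameter is outside its admissible domain."""


class ConfigurationError(MRSynthError, ValueError):
    """A configuration value is structurally invalid (empty axis, bad rank...)."""


class ContractError(MRSynthError, ValueError):
    """A call violates an interface contract (shape mismatch, unknown label...)."""


class SamplingError(MRSynthError, RuntimeError):
    """A stochastic sampling routine could not satisfy its request."""


class GeometryError(MRSynthError, ValueError):
    """A phantom geometry cannot be realised on the requested grid."""
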