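"""Exception hierarchy shared across the package."""


class CortistimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CortistimError, ValueError):
    """A scalar parameter is out of its admissible range."""


class GeometryError(CortistimError):
    """The requested geometry is degenerate or self-intersecting."""


class PlacementError(CortistimError):
    """Electrode or neuron placement violates a geometric constraint."""


class MeshError(CortistimError):
    """Mesh generation failed or produced an invalid mesh."""


class ConfigurationError(CortistimError):
    """A configuration is internally inconsistent (missing tissue, no ground, ...)."""


class SolverError(CortistimError):
    """The sparse linear solve did not converge to the requested tolerance."""


class SamplingError(CortistimError):
    """A query point lies outside the meshed domain."""


class FormatError(CortistimError):
    """A serialized file (SWC, MSH) violates its format contract."""


class IntegrationError(CortistimError):
    """The cable integration produced non-finite values."""


class InputError(CortistimError, ValueError):
    """Operation inputs have inconsistent shapes or too few samples."""


class EscalationError(CortistimError):
    """Non-monotone firing detected where bisection assumes all-or-none monotonicity."""


class ComparisonError(CortistimError):
    """Two record sets cannot be compared (empty intersection of neuron ids)."""
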