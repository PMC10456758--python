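"""Exception hierarchy shared across the package."""


class NDEntropyError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(NDEntropyError, ValueError):
    """Degenerate or inconsistent geometry (collinear/duplicate points,
    incommensurate lattice requests, masks retaining too few sites)."""


class ConfigurationError(NDEntropyError, ValueError):
    """Invalid parameter combination (e.g. periodic boundary without a box)."""


class EmptyInputError(NDEntropyError, ValueError):
    """An operation received an empty sample or histogram."""


class DomainError(NDEntropyError, ValueError):
    """A quantity is outside the mathematical domain of the requested formula."""


class ConsistencyError(NDEntropyError, ValueError):
    """Two objects that must describe the same configuration do not."""


class FormatError(NDEntropyError, ValueError):
    """A file does not conform to the trajectory CSV dialect."""
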