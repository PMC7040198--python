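"""Exception hierarchy shared across the pipeline stages."""


class MxBrainError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MxBrainError, ValueError):
    """An argument is outside its valid range (e.g. band edge >= Nyquist)."""


class LengthError(MxBrainError, ValueError):
    """A signal or series is too short for the requested operation."""


class StructureError(MxBrainError, ValueError):
    """Shapes, node counts or layer counts are inconsistent."""


class UnknownNameError(MxBrainError, KeyError):
    """A channel label or band name does not exist in the current context."""


class InsufficientDataError(MxBrainError, ValueError):
    """Not enough clean epochs / windows / samples to satisfy a request."""


class DegenerateSignalError(MxBrainError, ValueError):
    """A channel carries no information (constant / zero variance)."""


class EmptyGraphError(MxBrainError, ValueError):
    """A connectivity matrix has no non-zero weights to threshold."""


class LayerCountError(MxBrainError, ValueError):
    """A multiplex metric was asked for with too few layers."""


class EmptySelectionError(MxBrainError, ValueError):
    """Feature selection eliminated every candidate feature."""
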