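"""Exception hierarchy for emonet.

Every error raised by the package derives from :class:`EmonetError` so
pipeline code can catch one type at stage boundaries.
"""


class EmonetError(Exception):
    """Base class for all emonet errors."""


class InvalidDesignError(EmonetError):
    """Task design parameters are inconsistent (durations, balance)."""


class CyclicGraphError(EmonetError):
    """A directed structure that must be acyclic contains a cycle."""


class StabilityError(EmonetError):
    """Simulation parameters define an unstable linear system."""


class MissingModelError(EmonetError):
    """A condition in the design has no generating model."""


class EmptyGroupError(EmonetError):
    """A cohort group was specified with zero subjects."""


class EpochRangeError(EmonetError):
    """A lag-shifted epoch window runs past the end of the series."""


class DegenerateSignalError(EmonetError):
    """A signal is constant (zero variance) where variation is required."""


class CollinearityError(EmonetError):
    """Regressor matrix is singular for a node's parent set."""


class NoTriangleFreeGraphError(EmonetError):
    """Penalty grid exhausted without producing a triangle-free skeleton."""

    def __init__(self, message, last_graph=None):
        super().__init__(message)
        self.last_graph = last_graph


class LayerMappingError(EmonetError):
    """A graph node has no prefrontal/limbic layer assignment."""


class MissingDataError(EmonetError):
    """A subject x condition cell required by a stage is absent."""


class ParseError(EmonetError):
    """A time-series or graph file could not be parsed."""
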