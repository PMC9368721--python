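"""Exception hierarchy for the mediacite toolkit."""


class MediaCiteError(Exception):
    """Base class for all mediacite errors."""


class ConfigurationError(MediaCiteError):
    """A configuration field is missing or out of range."""


class GenerationError(MediaCiteError):
    """A requested synthetic structure is infeasible."""


class IngestError(MediaCiteError):
    """A citation record or node table cannot be resolved."""


class DegenerateFitError(MediaCiteError):
    """Too few distinct degree values to fit a power law."""


class ConvergenceError(MediaCiteError):
    """Power iteration failed to converge.

    Carries the last L1 residual in :attr:`residual`.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual
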