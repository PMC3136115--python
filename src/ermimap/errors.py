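"""Exception hierarchy shared across the pipeline stages."""


class ErmimapError(Exception):
    """Base class for all package-specific errors."""


class PanelIntegrityError(ErmimapError):
    """Packaged species panel or result-table fixture is malformed."""


class ConfigError(ErmimapError, ValueError):
    """Invalid user-supplied configuration (bounds, grids, names)."""


class InputError(ErmimapError, ValueError):
    """Invalid data passed to an analysis step."""


class AlignmentError(ErmimapError):
    """Columns of a matrix do not line up with the species panel or clusters."""


class InsufficientDataError(ErmimapError):
    """Too few observations for the requested operation."""


class CollinearityError(ErmimapError):
    """Regression design matrix is singular."""


class IterationLimitError(ErmimapError):
    """Iterative procedure failed to converge within its sweep cap."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial
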