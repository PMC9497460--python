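"""Exception types shared across the pipeline."""


class PsmasegError(Exception):
    """Base class for all package errors."""


class AlignmentError(PsmasegError):
    """Volumes that must share a grid (shape/spacing/origin) do not."""


class ValidationError(PsmasegError):
    """Input data violates a documented contract (codes, ranges, files)."""


class ConfigurationError(PsmasegError):
    """A configuration value is inconsistent (e.g. patch size vs depth)."""


class PlacementError(PsmasegError):
    """Phantom lesion placement failed after bounded retries."""


class TrainingDivergedError(PsmasegError):
    """Training loss became non-finite; carries a path to a state dump."""

    def __init__(self, message: str, dump_path: str | None = None):
        super().__init__(message)
        self.dump_path = dump_path
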