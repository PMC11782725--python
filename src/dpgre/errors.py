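"""Package-wide exception types.

Exit-code mapping used by the CLI: ``ConfigurationError`` (and plain
``ValueError``) are validation failures; everything else raised by the
pipeline is a runtime failure.
"""


class ConfigurationError(ValueError):
    """A configuration or geometry request that cannot be satisfied."""


class AssemblyError(RuntimeError):
    """K-space assembly failed (e.g. missing partition encodings)."""

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class SignalError(RuntimeError):
    """A data-dependent failure (empty ROI, degenerate navigator, ...)."""


class NumericalError(RuntimeError):
    """An iterative computation failed to converge."""
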