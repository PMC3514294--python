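"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when user input (graph, query, criterion, CLI flags) is invalid."""


class NumericalError(RuntimeError):
    """Raised when a linear solve or root search fails to produce a result."""
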