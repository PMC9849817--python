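"""Shared exception types."""


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


class InvalidConfigError(ValueError):
    """Raised when a configuration object is inconsistent."""


class ContractViolationError(RuntimeError):
    """Raised when a backend emits shapes that break its declared contract."""


class BackendNotInstalledError(RuntimeError):
    """Raised when an optional encoder backend is requested but not available."""


class ManifestParseError(ValueError):
    """Raised on malformed manifest lines; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number
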