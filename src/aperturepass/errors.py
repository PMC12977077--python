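"""Exception types shared across the pipeline."""


class AperturePassError(Exception):
    """Base class for all package-specific errors."""


class DesignError(AperturePassError, ValueError):
    """Invalid or unknown experimental design request."""


class MarkerError(AperturePassError, ValueError):
    """A required marker is missing or carries non-finite coordinates."""


class GeometryError(AperturePassError, ValueError):
    """Degenerate segment geometry (zero-length support vector, bad heights)."""


class PassDetectionError(AperturePassError, ValueError):
    """Number of detected aperture passes differs from the expected count."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(
            f"detected {found} aperture passes, expected {expected} "
            "(corrupt or truncated recording?)"
        )


class SchemaError(AperturePassError, ValueError):
    """A file does not match the declared CSV dialect."""


class ConvergenceError(AperturePassError, RuntimeError):
    """Model fitting failed to converge."""
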