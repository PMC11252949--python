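"""Package-specific error types.

Invalid arguments raise plain :class:`ValueError` throughout; the classes
here cover numerical and fitting failures that carry diagnostics.
"""

from __future__ import annotations


class NumericalError(RuntimeError):
    """A series or quadrature did not converge to the requested tolerance."""


class FitFailureError(RuntimeError):
    """All optimizer starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class TableFormatError(ValueError):
    """A delimited attenuation table violated the canonical schema."""
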