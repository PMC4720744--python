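"""Validation errors carrying short machine-readable codes.

Every rejection of user input raises :class:`ValidationError` with a
stable ``code`` string (e.g. ``"phase-empty"``) so callers — including the
command-line interface — can branch on the failure mode without parsing
the human-readable message.
"""

from __future__ import annotations


class ValidationError(ValueError):
    """Invalid input to a scedan operation.

    Parameters
    ----------
    code:
        Short stable identifier of the failure mode.
    message:
        Human-readable explanation; defaults to the code itself.
    """

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(message or code)
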