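"""Exception hierarchy.

:class:`DcvError` is the base for everything the library raises on purpose;
:class:`DcvValidationError` marks problems with user-supplied inputs (bad
files, inconsistent records, unknown codes) and maps to exit code 2 in the
CLI, while any other failure maps to exit code 1.
"""


class DcvError(Exception):
    """Base class for dcvkit errors."""


class DcvValidationError(DcvError, ValueError):
    """Invalid input data or configuration."""
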