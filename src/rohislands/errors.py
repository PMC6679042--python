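"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2, IntegrityError -> 3.
"""


class RohislandsError(Exception):
    """Base class for all package errors."""


class PanelFormatError(RohislandsError):
    """Malformed PLINK triplet, dimension mismatch or bad breed table."""


class ValidationError(RohislandsError):
    """Invalid user-supplied parameter or design (CLI exit code 2)."""


class IntegrityError(RohislandsError):
    """Internally inconsistent inputs, e.g. island/region cross-references (exit code 3)."""
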