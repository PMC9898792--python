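"""Exception hierarchy shared across the package."""


class CellFieError(Exception):
    """Base class for all package errors."""


class FormatError(CellFieError):
    """Malformed input file (ragged rows, unparsable cells, bad columns)."""


class ValidationError(CellFieError):
    """Well-formed input violating a domain invariant (negative expression,
    duplicate sample ids, dangling references)."""


class GPRSyntaxError(CellFieError):
    """Malformed gene-protein-reaction rule text."""
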