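"""Exception hierarchy.

``ValidationError`` marks precondition / input-contract violations (CLI exit
code 2); anything else propagating out of the library is a runtime error
(exit code 1).
"""


class CellScreenError(Exception):
    """Base class for all library errors."""


class ValidationError(CellScreenError, ValueError):
    """Invalid input or violated precondition."""


class ParseError(ValidationError):
    """Malformed input file; message names the offending coordinate."""
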