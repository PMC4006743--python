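"""Exception types shared across the package."""


class QtnvarError(Exception):
    """Base class for package errors."""


class InvalidInputError(QtnvarError, ValueError):
    """An input violates a documented precondition (bad labels, shapes, codes)."""


class DegenerateInputError(QtnvarError, ValueError):
    """An input is formally valid but the requested quantity is undefined on it.

    Examples: no gene with strictly positive counts in every sample (size
    factors), a filter quantile that removes every gene, a zero total sum of
    squares when variance fractions are requested.
    """


class ParseError(InvalidInputError):
    """A table file failed validation; carries file/line/field context."""

    def __init__(self, message, *, path=None, line=None, field=None):
        self.path = path
        self.line = line
        self.field = field
        where = []
        if path is not None:
            where.append(str(path))
        if line is not None:
            where.append(f"line {line}")
        if field is not None:
            where.append(f"field {field!r}")
        prefix = ": ".join(where)
        super().__init__(f"{prefix}: {message}" if prefix else message)
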