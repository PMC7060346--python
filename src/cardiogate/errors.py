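"""Exception types shared across the package."""


class CardiogateError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CardiogateError, ValueError):
    """A parameter violates its documented domain."""


class InvalidInputError(CardiogateError, ValueError):
    """Input data violate a documented precondition (non-finite, out of range...)."""


class InsufficientDataError(CardiogateError, ValueError):
    """Not enough observations for the requested computation."""


class SchemaError(CardiogateError, ValueError):
    """A data file violates its documented schema.

    Carries enough context (file, row, column) to locate the offending value.
    """

    def __init__(self, message, *, path=None, row=None, column=None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        prefix = ": ".join([", ".join(loc)] if loc else [])
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path, self.row, self.column = path, row, column
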