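"""Exception hierarchy for the assay-analysis pipeline.

Every stage raises a subclass of :class:`RespsensError` so the pipeline
driver can attach stage names when propagating.
"""


class RespsensError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RespsensError):
    """A simulation or pipeline configuration violates its invariants."""


class SchemaError(RespsensError):
    """A tabular input file is malformed.

    Carries enough context (file, row, column) to locate the offending cell.
    """

    def __init__(self, message: str, *, path=None, row=None, column=None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
        self.path = path
        self.row = row
        self.column = column


class DegenerateControlError(RespsensError):
    """Vehicle-control fluorescence does not exceed the blank; viability undefined."""


class StructuralError(RespsensError):
    """Readings are incomplete: missing compartment, mismatched dose grids, ..."""


class DoseRangeError(RespsensError):
    """The tested dose range cannot bracket the 75% viability crossing."""


class GatingError(RespsensError):
    """Dead-cell gating left no viable events."""
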