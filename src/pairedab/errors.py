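"""Exception hierarchy shared across the package."""


class PairedAbError(Exception):
    """Base class for all package-specific errors."""


class GeneLabelError(PairedAbError, ValueError):
    """An immunoglobulin gene call could not be parsed."""


class SchemaError(PairedAbError, ValueError):
    """An input table is missing mandatory columns."""


class EmptyResultError(PairedAbError, ValueError):
    """An operation produced no usable data (empty dataset, table, distribution)."""


class ConfigError(PairedAbError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class DataError(PairedAbError, ValueError):
    """A record is inconsistent with what an operation requires."""


class TestNotApplicableError(PairedAbError, ValueError):
    """A statistical test cannot be run on a degenerate table."""

    __test__ = False  # keep pytest from collecting this as a test class
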