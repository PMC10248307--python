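"""Exception hierarchy.

All errors raised by dwitr derive from :class:`DwitrError` so callers can
catch the package's failures with a single except clause.
"""


class DwitrError(Exception):
    """Base class for all dwitr errors."""


class PanelSchemaError(DwitrError):
    """A panel violates the long-format schema or its invariants."""


class InvalidArgumentError(DwitrError, ValueError):
    """An argument is outside its documented domain."""


class FitError(DwitrError):
    """A model fit failed (separation, rank deficiency, non-convergence)."""


class PositivityError(FitError):
    """A fitted treatment probability reached 0 or 1, violating positivity."""


class UnderDeterminedError(FitError):
    """Fewer analysis rows than free parameters."""
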