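"""Exception types shared across the pipeline stages."""

from __future__ import annotations


class SchemaError(KeyError):
    """A required column (or covariate level) is absent from the input table."""


class SingleClassError(ValueError):
    """An outcome or treatment column contains only one class."""


class ModelConvergenceError(RuntimeError):
    """A likelihood fit did not converge (e.g. complete separation)."""


class PositivityError(ValueError):
    """A fitted propensity of exactly 0 or 1 makes weighting undefined."""


class UnseenLevelError(ValueError):
    """A categorical level appears at prediction time that was absent at fit time."""
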