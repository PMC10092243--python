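"""Exception hierarchy for addpheno.

All package-specific failures derive from :class:`AddPhenoError` so callers
can catch one base class at CLI boundaries.
"""


class AddPhenoError(Exception):
    """Base class for all addpheno errors."""


class FormatError(AddPhenoError):
    """A file does not have the expected structure (missing column, unmatched pair)."""


class ParseError(AddPhenoError):
    """A cell could not be parsed as the expected type."""


class IntegrityError(AddPhenoError):
    """Data violates an invariant (duplicate ids, overlapping splits, length mismatch)."""


class ConfigError(AddPhenoError):
    """An invalid configuration value; the message names the offending field."""


class InputError(AddPhenoError):
    """Numerically or structurally invalid input to an algorithm."""


class DegenerateLabelsError(InputError):
    """Training labels contain a single class; a classifier cannot be fitted."""


class DegenerateStructureError(AddPhenoError):
    """Clustering collapsed: the data does not support the requested structure."""


class UndefinedScoreError(AddPhenoError):
    """A score (silhouette, ROC-AUC, ...) is undefined for the given labels."""


class AmbiguityError(AddPhenoError):
    """Cluster roles cannot be assigned because the centroids tie on every dimension."""


class NumericError(AddPhenoError):
    """A numerical failure (singular covariance, non-convergence) despite safeguards."""
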