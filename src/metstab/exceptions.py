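"""Exception hierarchy for metstab.

All package errors derive from :class:`MetstabError` so callers can catch one
base class; subclasses distinguish I/O-schema problems from statistical
degeneracies.
"""


class MetstabError(Exception):
    """Base class for all metstab errors."""


class SchemaError(MetstabError):
    """A required column is missing or an input file is malformed."""


class DuplicateRecordError(MetstabError):
    """The same (genotype, environment, replicate, trait) cell appears twice."""


class ValueParseError(MetstabError):
    """A value field could not be parsed as a finite number."""


class MissingCellError(MetstabError):
    """A genotype x environment cell has no observations."""


class UnbalancedDesignError(MetstabError):
    """An operation that requires a balanced design received unbalanced data."""


class InsufficientDataError(MetstabError):
    """Too few observations / environments / replicates for the statistic."""


class DegenerateDataError(MetstabError):
    """Zero variance, identical environments, collinear markers, etc."""
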