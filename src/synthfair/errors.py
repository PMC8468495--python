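"""Exception hierarchy for synthfair.

Every error raised by the library derives from :class:`SynthfairError`, so
callers (including the CLI) can catch one base class. Subclasses separate
configuration problems from data problems from mathematically degenerate
inputs, because the appropriate reaction differs: fix the schema, fix the
file, or flag the subgroup and move on.
"""


class SynthfairError(Exception):
    """Base class for all synthfair errors."""


class SchemaError(SynthfairError):
    """The schema is internally inconsistent or a required column is absent."""


class LevelError(SynthfairError):
    """A protected-attribute cell holds a value outside the declared levels."""


class ParseError(SynthfairError):
    """A temporal cell could not be parsed as a finite number."""


class ConfigurationError(SynthfairError):
    """Invalid combination of run options (roles, hierarchies, flags)."""


class DegenerateSubgroupError(SynthfairError):
    """A subgroup covers an entire dataset; odds are undefined (p = 1)."""


class ReferenceGroupError(SynthfairError):
    """The subgroup is absent from the real data; disparity is not evaluable."""


class EmptySubgroupError(SynthfairError):
    """No rows match the subgroup in the dataset being aggregated."""


class DegenerateTestError(SynthfairError):
    """A significance test is undefined (pooled proportion 0 or 1)."""


class DegeneratePopulationError(SynthfairError):
    """A conditional frequency needed by the disparate-impact oracle is zero."""


class UndefinedResemblanceError(SynthfairError):
    """A resemblance statistic is undefined for the given series.

    Carries a machine-readable ``reason`` (e.g. ``"zero_variance_real"``) so
    batch evaluation can flag the row instead of aborting.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class BiasSpecError(SynthfairError):
    """A simulation spec is invalid (non-normalizable weights, bad ranges)."""
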