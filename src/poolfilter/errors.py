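"""Exception hierarchy shared by all pipeline stages."""


class PoolFilterError(Exception):
    """Base class for all poolfilter errors."""


class SchemaError(PoolFilterError):
    """An input table is missing a required column or is otherwise malformed."""


class ValidationError(PoolFilterError):
    """A value violates a type invariant (range, integrality, uniqueness)."""


class ConfigurationError(PoolFilterError):
    """An option combination is not meaningful (e.g. summing an ordinal scale)."""


class NotTestableError(PoolFilterError):
    """A statistic is undefined for the available sample size.

    Raised by :func:`poolfilter.nullmodels.trait_statistic` and propagated by
    the null-model battery as an explicit ``not_testable`` outcome rather than
    a numeric result.
    """
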