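"""Exception hierarchy for the lungdce pipeline.

Every stage raises a subclass of :class:`LungDceError` so that the pipeline
driver can attach stage labels without string-matching arbitrary exceptions.
"""


class LungDceError(Exception):
    """Base class for all lungdce errors."""


class InvalidConfigError(LungDceError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(LungDceError, ValueError):
    """Input data violates a precondition (shape, emptiness, degeneracy)."""


class UnsupportedAifError(LungDceError, KeyError):
    """Requested arterial input function is not one of the supported forms."""


class NoBolusError(LungDceError, ValueError):
    """A time-signal curve shows no discernible contrast arrival."""


class UndefinedStatisticError(LungDceError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
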