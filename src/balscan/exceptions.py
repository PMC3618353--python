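"""Exception hierarchy for balscan."""


class BalscanError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(BalscanError):
    """Malformed input alignment (unequal lengths, missing records, ...)."""


class CurationError(BalscanError):
    """Curation could not produce a usable alignment."""


class ConfigurationError(BalscanError):
    """Invalid or incomplete configuration (missing seed, bad table, ...)."""


class UndefinedStatisticError(BalscanError):
    """A statistic is undefined for the given input (e.g. NI with Ps*Dn = 0).

    Raised instead of returning 0 or NaN so callers cannot silently
    mistake 'no information' for 'no signal'.
    """
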