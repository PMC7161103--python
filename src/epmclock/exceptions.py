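"""Exception hierarchy for model and data errors."""


class EPMError(Exception):
    """Base class for all package-specific errors."""


class DataError(EPMError):
    """Malformed input data: missing cells, duplicate ids, non-numeric values."""


class DegenerateAgesError(EPMError):
    """All ages identical: the site-step normal equations are singular."""


class ZeroRatesError(EPMError):
    """All site rates are zero: epigenetic ages are unidentifiable."""


class NestingViolationError(EPMError):
    """The alternative-model RSS exceeds the null-model RSS beyond tolerance."""
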