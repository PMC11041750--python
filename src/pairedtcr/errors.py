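"""Exception hierarchy for the paired-repertoire pipeline."""


class PairedTCRError(Exception):
    """Base class for all package errors."""


class FormatError(PairedTCRError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(PairedTCRError):
    """Parsed content violates a domain invariant (e.g. a non-positive count)."""


class ConfigurationError(PairedTCRError):
    """A parameter set or requested label is unusable (missing feature, bad range)."""


class ContrastError(PairedTCRError):
    """A differential-expression contrast cannot be formed (e.g. empty group)."""
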