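"""Exception hierarchy for the codec.

Every failure mode a caller is expected to handle has its own class so
that query engines and the CLI can discriminate between "no such value"
(an empty result, not an error), a corrupt frame, and a genuinely
unencodable input.
"""


class CodecError(Exception):
    """Base class for all codec failures."""


class DnaAlphabetError(CodecError, ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


class EmptySequenceError(CodecError, ValueError):
    """An operation that needs at least one base received an empty sequence."""


class ConfigError(CodecError, ValueError):
    """Inconsistent codec configuration (lengths, reserves, LSH shape...)."""


class CorruptFrameError(CodecError):
    """A padded frame cannot be parsed (missing delimiter or bad marker)."""


class CbbOverflowError(CodecError):
    """The converted attribute/value does not fit into L_CBB; raise L_CBB."""


class SegmentationRequiredError(CodecError):
    """A body is too long to pad into a single target length."""


class UnencodableError(CodecError):
    """The packet filter hit its generation cap without finding enough
    constraint-satisfying repair packets."""


class InsufficientPacketsError(CodecError):
    """Fewer than k usable packets survived; the message cannot be decoded."""


class DecodeError(CodecError):
    """The payload failed structural or checksum validation on decode."""


class IncompleteSegmentSetError(CodecError):
    """A segmented payload is missing segments that cannot be compensated.

    ``missing`` carries the 1-based indices of the absent segments.
    """

    def __init__(self, missing, message=None):
        self.missing = tuple(sorted(missing))
        super().__init__(message or f"missing segment indices: {self.missing}")


class DuplicateKeyError(CodecError, ValueError):
    """A designated unique attribute holds a repeated value."""
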