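"""Exception hierarchy."""


class TfrewireError(Exception):
    """Base class for all package errors."""


class ParseError(TfrewireError):
    """A text input could not be parsed; the message carries the line number."""


class ValidationError(TfrewireError):
    """An input violates a documented invariant."""


class UndefinedSkewError(TfrewireError):
    """A gene has no present ortholog on one side of the branch partition,
    so its skew is undefined for that branch."""


class SignShortageError(TfrewireError):
    """Fewer transcription factors with positive (or negative) skew than the
    team sizes require; the ping-pong run terminates."""


class DegenerateBlockError(TfrewireError):
    """Importance ratios are undefined because a class denominator has the
    wrong sign (e.g. no positively skewed factor left in T)."""


class AttritionStopSignal(TfrewireError):
    """Deleting the least-important element would empty one of the three
    block classes; attrition must stop at the current block."""


class EnumerationTooLargeError(TfrewireError):
    """The brute-force oracle refuses instances above its enumeration cap."""
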