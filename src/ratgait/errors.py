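"""Exception hierarchy for ratgait."""


class RatGaitError(Exception):
    """Base class for all ratgait errors."""


class InvalidParameterError(RatGaitError, ValueError):
    """A model or configuration parameter violates its constraints."""


class UnknownPresetError(RatGaitError, KeyError):
    """Requested lesion group or assessment day is not defined."""


class TrialFormatError(RatGaitError, ValueError):
    """An on-disk trial or track does not conform to the file format."""


class InsufficientDataError(RatGaitError, ValueError):
    """Not enough observations to compute the requested quantity."""
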