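"""Exception hierarchy for the peri-saccadic LFP analysis pipeline."""


class PerisaccError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PerisaccError, ValueError):
    """A configuration value is out of its legal range or inconsistent."""


class InvalidInputError(PerisaccError, ValueError):
    """An input array has the wrong shape, dtype, or non-finite entries."""


class InsufficientDataError(PerisaccError, ValueError):
    """Too few samples or trials for the requested operation."""


class InsufficientClassError(InsufficientDataError):
    """A classification class has too few examples."""


class NoSaccadeError(PerisaccError, RuntimeError):
    """The eye-speed trace never exceeded the detection threshold."""


class UnterminatedSaccadeError(PerisaccError, RuntimeError):
    """Speed crossed the detection threshold but never fell back below it."""


class UnsupportedRateError(InvalidConfigError):
    """Input rate is not an integer multiple of the output rate."""


class DeadChannelError(PerisaccError, ValueError):
    """A channel has zero variance and cannot be normalized."""


class EpochOutOfBoundsError(PerisaccError, IndexError):
    """The requested analysis window falls outside the recorded trial span."""


class MisalignedChannelsError(PerisaccError, ValueError):
    """Per-channel score tables do not share the same trial set."""


class StratificationError(PerisaccError, ValueError):
    """A cross-validation fold is missing one of the classes."""


class UndefinedMeanError(PerisaccError, ValueError):
    """Circular mean undefined: the resultant vector has (near-)zero length."""


class DegenerateEpochError(PerisaccError, ValueError):
    """An epoch has zero variance; Pearson correlation is undefined."""


class FormatError(PerisaccError, IOError):
    """A trial container file is malformed or missing required groups."""
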