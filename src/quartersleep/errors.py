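"""Exception hierarchy for the quartersleep pipeline."""


class QuarterSleepError(Exception):
    """Base class for all package-specific errors."""


class HypnogramFormatError(QuarterSleepError):
    """A stage label could not be mapped onto the {W, N1, N2, N3, R} alphabet."""


class EmptyInputError(QuarterSleepError):
    """An input file or sequence contained no epochs."""


class NoSleepOnsetError(QuarterSleepError):
    """No run of continuous sleep long enough to qualify as persistent sleep onset."""


class TooShortPeriodError(QuarterSleepError):
    """Sleep period too short to partition into quarters."""


class DegenerateRangeError(QuarterSleepError):
    """Epoch range too short for the requested computation (e.g. < 2 epochs for transitions)."""


class UndefinedPowerError(QuarterSleepError):
    """Spectral power undefined (all-zero window)."""


class AlignmentError(QuarterSleepError):
    """Two per-epoch structures (hypnogram / hypnodensity / EEG) disagree in length."""


class EmptyClassError(QuarterSleepError):
    """A classification task references a group with zero subjects."""


class SplitError(QuarterSleepError):
    """A class is too small to stratify into train and held-out sets."""


class CannotAugmentError(QuarterSleepError):
    """SMOTE cannot run (minority class has fewer than two members)."""


class MetricError(QuarterSleepError):
    """Performance metrics undefined (e.g. single-class held-out set)."""
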