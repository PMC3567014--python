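"""Exception hierarchy for snosite."""


class SnositeError(Exception):
    """Base class for all snosite errors."""


class InvalidSequenceError(SnositeError):
    """A protein sequence is empty or unusable after sanitization."""


class ParameterError(SnositeError):
    """A parameter is outside its admissible range (e.g. xi < 1)."""


class BoundsError(SnositeError):
    """A 1-based site lies outside its parent sequence."""


class NotACysteineError(SnositeError):
    """A window was requested at a position whose residue is not C."""


class EmptyTrainingSetError(SnositeError):
    """A frequency matrix was requested for an empty window set."""


class ShapeError(SnositeError):
    """Window half-widths or matrix shapes are inconsistent."""


class FormatError(SnositeError):
    """A file (FASTA, benchmark TSV, PSAAP TSV, model archive) is malformed."""


class TrainingError(SnositeError):
    """The training set is degenerate (e.g. one class is empty)."""


class ThresholdError(SnositeError):
    """Threshold tuning needs at least one score per class."""


class UndefinedMetricError(SnositeError):
    """Sn/Sp are undefined when a class has zero members."""


class SplitError(SnositeError):
    """Cross-validation folds cannot be formed (class smaller than k)."""


class SyntheticSpecError(SnositeError):
    """A synthetic-data specification is infeasible."""
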