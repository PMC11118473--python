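"""Typed exceptions.

Every failure mode raises a subclass of :class:`VepevalError` so callers can
distinguish bad input files from undefined statistics without string matching.
Undefined metrics raise rather than return NaN: a silent NaN would corrupt
rank aggregation downstream.
"""


class VepevalError(Exception):
    """Base class for all package errors."""


class FormatError(VepevalError):
    """A file does not conform to the expected tabular schema."""


class IntegrityError(VepevalError):
    """Input data violates an internal consistency requirement (e.g. duplicate ids)."""


class AlignmentError(VepevalError):
    """A prediction table shares no variants with the target dataset."""


class NormalizationError(VepevalError):
    """Imputation or score normalization cannot proceed (all-missing, constant feature)."""


class UndefinedMetricError(VepevalError):
    """A metric is mathematically undefined on the given input (zero variance, one class)."""


class ParameterError(VepevalError):
    """An out-of-range configuration parameter."""


class PairingError(VepevalError):
    """Bootstrap distributions are not paired (different seed, B or sample size)."""


class ConfidenceIntervalError(VepevalError):
    """Too few defined bootstrap estimates to form an interval."""


class PoolError(VepevalError):
    """No predictor qualifies for the difficult-variant pool."""


class SimulationError(VepevalError):
    """Infeasible synthetic-data specification or failed noise calibration."""


class StageError(VepevalError):
    """Failure inside the end-to-end pipeline, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
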