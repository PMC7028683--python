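"""Exception hierarchy.

All package errors derive from :class:`PrefallError` so callers (and the CLI)
can map them to exit codes without catching bare ``Exception``.
"""


class PrefallError(Exception):
    """Base class for all package errors."""


class ConfigError(PrefallError):
    """Invalid configuration value or unknown identifier."""


class ParseError(PrefallError):
    """Malformed trial file content."""


class MetadataError(PrefallError):
    """Filename does not follow the SisFall naming convention."""


class AnnotationError(PrefallError):
    """Stage annotation inconsistent with the trial it describes."""


class ArchitectureError(PrefallError):
    """Model configuration whose layer arithmetic is infeasible."""


class TrainingDataError(PrefallError):
    """Training set unusable (e.g. a class entirely absent)."""


class DivergenceError(PrefallError):
    """Loss became non-finite during training."""


class SelectionError(PrefallError):
    """Epoch selection requested on an empty history."""


class DataError(PrefallError):
    """Label vectors or datasets violate their contracts."""


class UndefinedMetricError(PrefallError):
    """A sensitivity/specificity/accuracy ratio has a zero denominator."""


class SplitError(PrefallError):
    """Subject-wise fold construction impossible for the given cohort."""


class MeasurementError(PrefallError):
    """Latency measurement on an empty or too-small instance set."""
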