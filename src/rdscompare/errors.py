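"""Exception hierarchy.

All package errors derive from :class:`RDSCompareError` so callers can catch
one base class; subclasses distinguish input problems (bad tables, bad
configs) from structural problems (cycles, dangling links) and statistical
degeneracies (non-ergodic chains, single-cluster designs).
"""


class RDSCompareError(Exception):
    """Base class for all rdscompare errors."""


class InputError(RDSCompareError):
    """Invalid argument values or malformed input data."""


class SchemaError(InputError):
    """A participant table or config does not match the expected schema."""


class ConfigError(InputError):
    """Inconsistent or invalid simulation configuration."""


class LinkError(RDSCompareError):
    """A recruiter reference points at a participant that does not exist."""


class StructureError(RDSCompareError):
    """Recruitment edges do not form a forest (cycle, self-loop, ...)."""


class DegenerateAttributeError(RDSCompareError):
    """Attribute has fewer than two observed categories."""


class NonErgodicError(RDSCompareError):
    """Recruitment transition matrix is reducible or periodic."""


class WeightError(RDSCompareError):
    """Missing or invalid degree/weight for a participant."""


class CompletenessError(RDSCompareError):
    """A weighted participant lacks a value for the analysed variable."""


class ClusteringError(RDSCompareError):
    """Too few recruitment chains (clusters) for a clustered variance."""


class VarianceEstimationError(RDSCompareError):
    """Design-effect or variance estimate is non-positive or undefined."""


class ConvergenceError(RDSCompareError):
    """Iterative fit failed to converge within the iteration budget."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class SamplingError(RDSCompareError):
    """Requested sample exceeds the available frame."""
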