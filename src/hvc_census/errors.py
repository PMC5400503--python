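"""Exception hierarchy for skeleton and census errors."""


class HVCCensusError(Exception):
    """Base class for all package errors."""


class SkeletonParseError(HVCCensusError):
    """A skeleton file could not be parsed (names the offending line)."""


class SkeletonStructureError(HVCCensusError):
    """A skeleton violates a structural invariant (dangling parent, cycle)."""


class ValidationError(HVCCensusError):
    """A record failed closed-vocabulary or range validation."""


class ParameterError(HVCCensusError):
    """An operation received an out-of-range parameter."""


class FitError(HVCCensusError):
    """A model fit failed to converge from all starting points."""


class ConfigError(HVCCensusError):
    """A circuit or pipeline configuration is infeasible or inconsistent."""
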