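"""Exception hierarchy shared across the package."""


class WfmrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WfmrError, ValueError):
    """A file does not conform to the expected tabular/VCF layout."""


class ValidationError(WfmrError, ValueError):
    """Data violate a documented invariant (range, uniqueness, schema)."""


class SeparationError(WfmrError, RuntimeError):
    """Complete or quasi-complete separation: the MLE diverges."""


class ConvergenceError(WfmrError, RuntimeError):
    """An iterative fit failed to converge without evidence of separation."""


class ConfigError(WfmrError, ValueError):
    """A scenario/pipeline configuration failed schema validation."""
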