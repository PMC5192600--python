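"""Exception types shared across the package."""


class PLSNetError(Exception):
    """Base class for package-specific errors."""


class DegenerateInputError(PLSNetError, ValueError):
    """Raised when a fit cannot proceed: the design carries no covariance
    with the response (all-zero design, constant response, ...)."""


class DimensionError(PLSNetError, ValueError):
    """Raised when array shapes are mutually inconsistent."""


class UndefinedMetricError(PLSNetError, ValueError):
    """Raised when a ranking metric has no defined value, e.g. AUROC with
    zero positives or zero negatives."""


class ValidationError(PLSNetError, ValueError):
    """Raised when an input file or in-memory structure violates its
    documented invariants."""
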