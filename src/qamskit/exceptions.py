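"""Exception hierarchy shared across the package."""


class QamsKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(QamsKitError, ValueError):
    """A file does not conform to the expected layout (missing columns, bad header)."""


class ValidationError(QamsKitError, ValueError):
    """Input data violates a domain invariant (duplicate peaks, tied retention times...)."""


class ConfigurationError(QamsKitError, ValueError):
    """A design, scheme or pipeline configuration is unusable as given."""


class FitError(QamsKitError, RuntimeError):
    """A least-squares fit cannot be carried out (rank deficiency, too few runs)."""


class ComponentLookupError(QamsKitError, KeyError):
    """A requested component is not present in a run, model or standard set."""
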