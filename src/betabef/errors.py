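"""Exception hierarchy shared across the package."""


class BetaBefError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BetaBefError):
    """An input object violates a structural invariant."""


class CrossReferenceError(BetaBefError):
    """Linked tables disagree (e.g. a counts site missing from metadata)."""


class DegenerateNullError(BetaBefError):
    """A null distribution has zero spread, so no z-score can be formed."""


class FitError(BetaBefError):
    """A regression could not be fitted (degenerate design, too few rows)."""


class ConfigError(BetaBefError):
    """A run configuration is internally inconsistent."""
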