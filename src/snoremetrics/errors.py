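"""Exception hierarchy for snoremetrics."""


class SnoreMetricsError(Exception):
    """Base class for all snoremetrics errors."""


class ConfigError(SnoreMetricsError, ValueError):
    """Invalid analysis or synthesis configuration."""


class FormatError(SnoreMetricsError, ValueError):
    """Malformed or unsupported audio file format."""


class DegenerateInputError(SnoreMetricsError, ValueError):
    """Input too short or otherwise degenerate for the requested operation."""


class ConsistencyError(SnoreMetricsError, ValueError):
    """Inputs that violate a cross-object contract (ordering, bounds)."""


class AlignmentError(SnoreMetricsError, ValueError):
    """Two series that cannot be aligned on their identifiers."""


class FeasibilityError(SnoreMetricsError, ValueError):
    """A synthesis configuration whose constraints cannot be satisfied."""
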