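"""Exception hierarchy shared by all analysis modules."""


class PortalwatchError(Exception):
    """Base class for all package errors."""


class FormatError(PortalwatchError):
    """Malformed input text (PDB records, CSV tables, config files)."""


class EmptyInputError(FormatError):
    """Input parsed cleanly but contained no usable records."""


class TopologyError(PortalwatchError):
    """Atom identity mismatch between models or frames."""


class SelectionError(PortalwatchError):
    """A selection resolved to an unusable (usually empty) atom set."""


class DegenerateGeometryError(PortalwatchError):
    """Point set too small or rank-deficient for a rigid superposition."""


class InsufficientFramesError(PortalwatchError):
    """Fewer frames than the statistic requires."""


class ParameterError(PortalwatchError):
    """Parameter combination outside the operation's domain."""


class ConfigError(PortalwatchError):
    """Unknown segment names, unknown config keys, or bad config values."""


class DegenerateDataError(PortalwatchError):
    """Data carry no signal for the requested computation."""


class ConvergenceError(PortalwatchError):
    """Iterative fit failed to converge within its iteration budget."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class ComparisonError(PortalwatchError):
    """Two reports cannot be compared (mismatched pairs, disjoint nodes)."""


class ConnectivityError(PortalwatchError):
    """Elastic network is disconnected at the given cutoff."""


class NumericError(PortalwatchError):
    """Numerical precondition violated (e.g. covariance not PSD)."""
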